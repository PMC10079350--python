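"""Smith-Waterman protein similarity and its normalization.

Raw local-alignment scores are computed with BLOSUM62 and affine gaps
(open 10, extend 4: a gap of length L costs 10 + 4*(L-1)).  Within each
mini-batch the raw scores are log-transformed (with an additive offset if
zeros occur) and z-scored; the standardized values are the similarity S
the quadratic model predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DegenerateDataError, IsofuncError

LOG_OFFSET_EPS = 1e-6


@dataclass(frozen=True)
class AlignmentParams:
    substitution: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 4.0


@dataclass(frozen=True)
class NormalizationMeta:
    """Parameters of the log + z-score transform applied to a score batch."""

    offset: float
    log_base: float
    mean: float
    sd: float


@dataclass
class PairScoreTable:
    """Similarity scores for a batch of unordered isoform pairs."""

    pairs: list[tuple[str, str]]
    raw: np.ndarray
    std: np.ndarray
    meta: NormalizationMeta | None = None

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.raw) or len(self.pairs) != len(self.std):
            raise ValueError("pairs, raw and std must have equal length")
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {a})")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise ValueError(f"pair {key} listed twice")
            seen.add(key)
        if not np.all(np.isfinite(self.std)):
            raise ValueError("non-finite standardized score")

    def __len__(self) -> int:
        return len(self.pairs)


@lru_cache(maxsize=8)
def _aligner(substitution: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(substitution)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_score(
    seq_a: str,
    seq_b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 4.0,
) -> float:
    """Maximal Smith-Waterman local alignment score (symmetric, >= 0).

    Selenocysteine (U) is scored as X since BLOSUM62 has no U column.
    """
    if not seq_a or not seq_b:
        raise DegenerateDataError("cannot align an empty sequence")
    a = seq_a.upper().replace("U", "X")
    b = seq_b.upper().replace("U", "X")
    try:
        score = _aligner(substitution, gap_open, gap_extend).score(a, b)
    except ValueError as exc:
        raise IsofuncError(f"alignment failed: {exc}") from exc
    return float(max(score, 0.0))


def normalize_scores(raw: Sequence[float]) -> tuple[np.ndarray, NormalizationMeta]:
    """Log10-transform then z-score a batch of raw alignment scores.

    The additive offset is 0 when all scores are positive, otherwise
    ``eps - min`` so the smallest score maps to log10(eps).  The z-score
    uses the sample standard deviation; rank order is preserved.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("need >=2 scores to standardize")
    offset = 0.0 if x.min() > 0 else LOG_OFFSET_EPS - float(x.min())
    y = np.log10(x + offset)
    sd = float(np.std(y, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateDataError("scores have zero variance after transform")
    mean = float(np.mean(y))
    z = (y - mean) / sd
    return z, NormalizationMeta(offset=offset, log_base=10.0, mean=mean, sd=sd)


def score_subset(
    subset: Sequence[str],
    sequences: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    cache: dict[tuple[str, str], float] | None = None,
) -> PairScoreTable:
    """Align the eligible pairs of one mini-batch and standardize in-batch.

    Raw scores are cached by unordered pair so that re-partitions across EM
    iterations never recompute an alignment.
    """
    subset_set = set(subset)
    raws = []
    for a, b in pairs:
        if a not in subset_set or b not in subset_set:
            raise ValueError(f"pair ({a}, {b}) not within the subset")
        for iso in (a, b):
            if iso not in sequences:
                raise DegenerateDataError(f"no sequence for isoform {iso}")
        key = (a, b) if a <= b else (b, a)
        if cache is not None and key in cache:
            raws.append(cache[key])
        else:
            s = sw_score(
                sequences[a],
                sequences[b],
                substitution=params.substitution,
                gap_open=params.gap_open,
                gap_extend=params.gap_extend,
            )
            if cache is not None:
                cache[key] = s
            raws.append(s)
    raw_arr = np.asarray(raws, dtype=float)
    std, meta = normalize_scores(raw_arr)
    return PairScoreTable(pairs=list(pairs), raw=raw_arr, std=std, meta=meta)


class SequenceScoreProvider:
    """Score provider backed by pairwise alignment of real sequences.

    Standardization happens per requested batch (scores are only ever
    compared within one mini-batch in the objective); raw scores are cached
    across batches.
    """

    def __init__(
        self, sequences: Mapping[str, str], params: AlignmentParams = AlignmentParams()
    ) -> None:
        self.sequences = sequences
        self.params = params
        self.cache: dict[tuple[str, str], float] = {}

    def scores(self, pairs: Sequence[tuple[str, str]]) -> PairScoreTable:
        subset = sorted({i for p in pairs for i in p})
        return score_subset(subset, self.sequences, pairs, self.params, self.cache)
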