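"""Mini-batch EM orchestration.

One E-step iteration partitions the isoforms uniformly at random into K
subsets, aligns and standardizes the eligible pairs inside each subset
(pairs whose genes share at least one GO term of the active subontology),
runs the GA on each subset's mutable bits, and accumulates

    sigma_i = sum over subsets of (subset log-likelihood / subset pair count)

The E-phase stops when the cumulative change of sigma over a sliding
window of iterations drops below a threshold (default: 25 iterations,
1/3).  The M-step then refits the quadratic coefficients on the pairs of
the final E pass, and the outer loop alternates E and M phases until the
coefficients stop moving.  The three subontologies run in the order MF,
BP, CC; the CC run can carry the finished BP assignment as frozen
"surrogate" bits that raise shared-term counts without being searched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as iomod
from .alignment import AlignmentParams, PairScoreTable, SequenceScoreProvider
from .annotations import (
    NAMESPACES,
    AssignmentMatrix,
    GeneAnnotationMap,
    GeneRecord,
    augment_gene_annotations,
    build_candidates,
    filter_specific_terms,
)
from .emcore import QuadraticModel, fit_quadratic, initialize_beta, log_likelihood
from .errors import DegenerateDataError, RankDeficiencyError
from .ga import GAParams, SubsetProblem, decode, encode, evolve


@dataclass(frozen=True)
class BatchPartition:
    """Uniform random isoform -> subset-label map (sizes not equalized)."""

    labels: dict[str, int]
    k: int
    seed: int | None

    def subsets(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for iso in sorted(self.labels):
            out.setdefault(self.labels[iso], []).append(iso)
        return out


def partition(isoform_ids: Sequence[str], k: int = 200, seed: int | None = None) -> BatchPartition:
    """Assign each isoform an i.i.d. uniform label in 1..k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = sorted(isoform_ids)
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, k + 1, size=len(ids))
    return BatchPartition(labels=dict(zip(ids, labels.tolist())), k=k, seed=seed)


def eligible_pairs(
    subset_ids: Sequence[str],
    isoform_gene: Mapping[str, str],
    gene_terms: Mapping[str, set[str]],
) -> list[tuple[str, str]]:
    """Unordered within-subset pairs whose genes share >= 1 GO term.

    Same-gene pairs qualify whenever the gene has at least one term.
    """
    ids = sorted(subset_ids)
    for iso in ids:
        if iso not in isoform_gene:
            raise DegenerateDataError(f"isoform {iso} has no known gene")
    pairs = []
    for x in range(len(ids)):
        ta = gene_terms.get(isoform_gene[ids[x]], set())
        if not ta:
            continue
        for y in range(x + 1, len(ids)):
            tb = gene_terms.get(isoform_gene[ids[y]], set())
            if ta & tb:
                pairs.append((ids[x], ids[y]))
    return pairs


@dataclass
class EMConfig:
    n_subsets: int = 200
    window: int = 25
    threshold: float = 1.0 / 3.0
    max_e_iterations: int = 100
    max_cycles: int = 10
    beta_tol: float = 1e-4
    ga: GAParams = field(default_factory=GAParams)
    seed: int = 0
    init_subset_size: int | None = None
    specific_threshold: float = 0.10
    convergence_mode: str = "signed"  # or "abs"
    use_bp_surrogates: bool = True
    alignment: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.convergence_mode not in ("signed", "abs"):
            raise ValueError("convergence_mode must be 'signed' or 'abs'")


@dataclass
class EMState:
    """Mutable EM state: assignment, model, sigma trace and RNG."""

    assignment: AssignmentMatrix
    model: QuadraticModel
    gene_terms: dict[str, set[str]]
    provider: object
    rng: np.random.Generator
    sigma_trace: list[float] = field(default_factory=list)
    iteration: int = 0
    last_pass: list[tuple[PairScoreTable, np.ndarray]] = field(default_factory=list)
    phase_start: int = 0
    init_seed_used: int | None = None


def check_convergence(
    trace: Sequence[float],
    window: int = 25,
    threshold: float = 1.0 / 3.0,
    mode: str = "signed",
) -> bool:
    """True once the cumulative sigma change over the last ``window``
    iterations (telescoped: last minus the value ``window`` back) is below
    ``threshold``.  Needs at least window+1 trace entries."""
    if len(trace) < window + 1:
        return False
    delta = trace[-1] - trace[-1 - window]
    if mode == "abs":
        delta = abs(delta)
    return delta < threshold


def estep_iteration(state: EMState, config: EMConfig, ga_search: bool = True) -> float:
    """One pass: fresh partition, per-subset GA update, sigma accumulation.

    With ``ga_search=False`` the pass only evaluates the current assignment
    (used for the sigma_0 baseline).  Subsets with fewer than two isoforms,
    no eligible pairs, or score batches that cannot be standardized are
    skipped and contribute 0.
    """
    am = state.assignment
    pseed = int(state.rng.integers(2**31))
    part = partition(am.isoform_ids, config.n_subsets, pseed)
    sigma = 0.0
    n_pairs_total = 0
    last_pass: list[tuple[PairScoreTable, np.ndarray]] = []
    for _, ids in sorted(part.subsets().items()):
        if len(ids) < 2:
            continue
        pairs = eligible_pairs(ids, am.isoform_gene, state.gene_terms)
        if not pairs:
            continue
        try:
            table = state.provider.scores(pairs)
        except DegenerateDataError:
            continue
        problem = SubsetProblem(ids, table.pairs, table.std, am, state.model)
        if ga_search and problem.n_bits > 0:
            params = replace(config.ga, seed=int(state.rng.integers(2**31)))
            result = evolve(problem, params, encode(am, problem))
            decode(result.bits, am, problem)
        taus = problem.taus_population(encode(am, problem))[0]
        ll, n = log_likelihood(table, taus, state.model)
        if n:
            sigma += ll / n
            n_pairs_total += n
        last_pass.append((table, taus))
    state.sigma_trace.append(sigma)
    state.iteration += 1
    state.last_pass = last_pass
    state._last_pair_count = n_pairs_total  # type: ignore[attr-defined]
    return sigma


def _mstep(state: EMState) -> QuadraticModel:
    """Refit the coefficients on the union of last-E-pass pairs; on a
    rank-deficient design keep the previous coefficients."""
    if not state.last_pass:
        return state.model
    scores = np.concatenate([t.std for t, _ in state.last_pass])
    taus = np.concatenate([tau for _, tau in state.last_pass])
    try:
        return fit_quadratic(scores, taus)
    except RankDeficiencyError:
        return state.model


@dataclass
class CorpusInputs:
    """Everything a per-subontology run needs, already parsed."""

    genes: list[GeneRecord]
    tg: GeneAnnotationMap
    domains: Mapping[str, frozenset[str]]
    ipr2go: Mapping[str, set[str]]
    term_namespaces: Mapping[str, str]
    sequences: Mapping[str, str] | None = None

    @classmethod
    def from_files(
        cls,
        gaf: str | Path,
        obo: str | Path,
        fasta: str | Path,
        domains: str | Path,
        ipr2go: str | Path,
    ) -> "CorpusInputs":
        tg = iomod.read_gene_annotations(gaf)
        ontology = iomod.read_ontology(obo)
        sequences = iomod.read_protein_fasta(fasta)
        gene_map = iomod.read_gene_map_from_fasta(fasta)
        dom = iomod.read_isoform_domains(domains)
        i2g = iomod.read_interpro2go(ipr2go)
        by_gene: dict[str, list[str]] = {}
        for iso in sorted(sequences):
            by_gene.setdefault(gene_map[iso], []).append(iso)
        genes = [
            GeneRecord(gene_id=g, isoform_ids=tuple(isos))
            for g, isos in sorted(by_gene.items())
        ]
        tns = {t: data.namespace for t, data in ontology.items()}
        return cls(
            genes=genes,
            tg=tg,
            domains=dom,
            ipr2go=i2g,
            term_namespaces=tns,
            sequences=sequences,
        )


def _corpus_has_pairs(genes: Sequence[GeneRecord], gene_terms: Mapping[str, set[str]]) -> bool:
    annotated = [g for g in genes if gene_terms.get(g.gene_id)]
    if any(len(g.isoform_ids) >= 2 for g in annotated):
        return True
    term_owner: dict[str, str] = {}
    for g in annotated:
        for t in gene_terms[g.gene_id]:
            if term_owner.get(t, g.gene_id) != g.gene_id:
                return True
            term_owner[t] = g.gene_id
    return False


def _attach_frozen(
    am: AssignmentMatrix,
    frozen_bits: Sequence[tuple[str, str]],
    term_namespaces: Mapping[str, str],
) -> AssignmentMatrix:
    """Append frozen surrogate bits (e.g. a finished BP assignment) to a
    matrix: they enter shared-term counts but the GA never touches them."""
    extra_terms = sorted({t for _, t in frozen_bits if t not in am.term_index})
    p = len(am.isoform_ids)
    if extra_terms:
        zeros = np.zeros((p, len(extra_terms)), dtype=np.uint8)
        new = AssignmentMatrix(
            isoform_ids=list(am.isoform_ids),
            term_ids=list(am.term_ids) + extra_terms,
            bits=np.hstack([am.bits, zeros.copy()]),
            candidate_mask=np.hstack([am.candidate_mask, zeros.copy()]),
            isoform_gene=dict(am.isoform_gene),
            term_namespace={
                **am.term_namespace,
                **{t: term_namespaces.get(t, "") for t in extra_terms},
            },
            seed_mask=np.hstack([am.seed_mask, zeros.copy()]),
            frozen_mask=np.hstack([am.frozen_mask, zeros.copy()]),
        )
    else:
        new = am.copy()
    for iso, term in frozen_bits:
        i = new.iso_index.get(iso)
        j = new.term_index.get(term)
        if i is None or j is None:
            continue
        new.candidate_mask[i, j] = 1
        new.bits[i, j] = 1
        new.frozen_mask[i, j] = 1
    return new


def run_subontology(
    inputs: CorpusInputs,
    namespace: str,
    config: EMConfig | None = None,
    frozen_seed_bits: Sequence[tuple[str, str]] | None = None,
    provider=None,
) -> tuple[AssignmentMatrix, EMState]:
    """Full EM on one subontology: seed, initialize beta, cycle E/M.

    Returns the final assignment (surrogate columns included; callers strip
    them) and the EM state with the sigma trace and fitted coefficients.
    """
    config = config or EMConfig()
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown subontology {namespace!r}")

    tg = augment_gene_annotations(
        inputs.tg, inputs.genes, inputs.domains, inputs.ipr2go, inputs.term_namespaces
    )
    specific = filter_specific_terms(tg, config.specific_threshold)
    am = build_candidates(
        inputs.genes, tg, inputs.domains, inputs.ipr2go, specific, namespace,
        inputs.term_namespaces,
    )
    if frozen_seed_bits:
        am = _attach_frozen(am, frozen_seed_bits, inputs.term_namespaces)

    gene_terms = {g: set(tg.terms(g, namespace)) for g in tg.genes}
    if not _corpus_has_pairs(inputs.genes, gene_terms):
        raise DegenerateDataError(
            f"no eligible isoform pairs anywhere in the corpus for {namespace}"
        )
    if provider is None:
        if inputs.sequences is None:
            raise DegenerateDataError("no sequences and no score provider given")
        provider = SequenceScoreProvider(inputs.sequences, config.alignment)

    rng = np.random.default_rng(config.seed)

    # initial coefficients from one random subset scored under the seed bits
    def pair_builder(subset: list[str]) -> list[tuple[str, str]]:
        return eligible_pairs(subset, am.isoform_gene, gene_terms)

    def tau_of_pairs(pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        b = am.bits.astype(np.int64)
        return np.asarray(
            [int(b[am.iso_index[a]] @ b[am.iso_index[c]]) for a, c in pairs]
        )

    p = len(am.isoform_ids)
    size = config.init_subset_size or max(math.ceil(p / 200), min(p, 20))
    model, used_seed = initialize_beta(
        am.isoform_ids, size, pair_builder, provider.scores, tau_of_pairs,
        seed=int(rng.integers(2**31)),
    )

    state = EMState(
        assignment=am,
        model=model,
        gene_terms=gene_terms,
        provider=provider,
        rng=rng,
        init_seed_used=used_seed,
    )
    # sigma_0 baseline on the seed assignment, no GA search
    estep_iteration(state, config, ga_search=False)
    state.iteration = 0

    for _ in range(config.max_cycles):
        state.phase_start = len(state.sigma_trace)
        while True:
            estep_iteration(state, config)
            phase = state.sigma_trace[state.phase_start - 1 :]
            if check_convergence(
                phase, config.window, config.threshold, config.convergence_mode
            ):
                break
            if len(state.sigma_trace) - state.phase_start >= config.max_e_iterations:
                break
        new_model = _mstep(state)
        change = new_model.rel_change(state.model)
        state.model = new_model
        if change < config.beta_tol:
            break
    return state.assignment, state


def run_full(
    inputs: CorpusInputs,
    config: EMConfig | None = None,
    namespaces: Sequence[str] = NAMESPACES,
    providers: Mapping[str, object] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, tuple[AssignmentMatrix | None, EMState | None]]:
    """Run MF, then BP, then CC; CC optionally reuses the BP assignment as
    frozen surrogate bits (stripped from the CC output).

    A subontology with no usable candidates yields (None, None).  With
    ``out_dir`` set, per-subontology annotation TSVs, sigma traces and an
    uncovered-gene-term report are written.
    """
    config = config or EMConfig()
    order = [ns for ns in NAMESPACES if ns in set(namespaces)]
    results: dict[str, tuple[AssignmentMatrix | None, EMState | None]] = {}
    for ns in order:
        frozen: list[tuple[str, str]] | None = None
        if ns == "CC" and config.use_bp_surrogates:
            bp = results.get("BP", (None, None))[0]
            if bp is not None:
                frozen = [
                    (iso, t)
                    for iso in bp.isoform_ids
                    for t in bp.terms_of(iso)
                ]
        provider = providers.get(ns) if providers else None
        try:
            am, state = run_subontology(
                inputs, ns, config, frozen_seed_bits=frozen, provider=provider
            )
        except DegenerateDataError:
            results[ns] = (None, None)
            continue
        ns_terms = [t for t in am.term_ids if am.term_namespace.get(t) == ns]
        results[ns] = (am.restrict_terms(ns_terms), state)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ns in order:
            am, state = results[ns]
            if am is None:
                pd.DataFrame(columns=iomod.ANNOTATION_COLUMNS).to_csv(
                    out / f"isoform_annotations_{ns}.tsv", sep="\t", index=False
                )
                continue
            iomod.write_isoform_annotations(am, out / f"isoform_annotations_{ns}.tsv")
            pd.DataFrame(
                {
                    "iteration": range(len(state.sigma_trace)),
                    "sigma": state.sigma_trace,
                }
            ).to_csv(out / f"sigma_trace_{ns}.tsv", sep="\t", index=False)
            coverage_report(am).to_csv(
                out / f"uncovered_terms_{ns}.tsv", sep="\t", index=False
            )
    return results


def coverage_report(am: AssignmentMatrix) -> pd.DataFrame:
    """Gene terms in the candidate universe that no isoform of the gene
    carries in the final assignment.  The coverage assumption (every gene
    function realized by at least one isoform) is reported, not enforced.
    """
    rows = []
    genes: dict[str, list[int]] = {}
    for iso, g in am.isoform_gene.items():
        if iso in am.iso_index:
            genes.setdefault(g, []).append(am.iso_index[iso])
    for g, idxs in sorted(genes.items()):
        cand = am.candidate_mask[idxs].max(axis=0)
        got = am.bits[idxs].max(axis=0)
        for j in np.flatnonzero(cand & ~got & 1):
            rows.append((g, am.term_ids[j]))
    return pd.DataFrame(rows, columns=["gene_id", "go_id"])
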