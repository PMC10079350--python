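"""Evaluation of inferred isoform annotations.

Three independent lines of evidence: agreement with literature-curated
isoform-function labels (confusion rates), specificity of the assigned
terms (information content), and the external consistency checks —
expression correlation and protein-domain sharing as functions of the
number of shared GO terms, each contrasted between isoform-level and
gene-level annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AssignmentMatrix, GeneAnnotationMap
from .errors import DegenerateDataError
from .io import CurationRecord, OntologyTerm


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts of predicted vs curated isoform functions."""

    tp: int
    fp: int
    tn: int
    fn: int
    skipped: tuple[CurationRecord, ...] = ()

    @property
    def tp_rate(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fp_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_vs_curation(
    assignment: AssignmentMatrix, records: Sequence[CurationRecord]
) -> ConfusionSummary:
    """Score predictions against curated labels: a prediction is positive
    iff the assignment bit is set.  Records whose isoform is absent from
    the matrix are skipped and reported."""
    tp = fp = tn = fn = 0
    skipped: list[CurationRecord] = []
    for rec in records:
        if rec.isoform_id not in assignment.iso_index:
            skipped.append(rec)
            continue
        predicted = assignment.has(rec.isoform_id, rec.go_id)
        if rec.label and predicted:
            tp += 1
        elif rec.label and not predicted:
            fn += 1
        elif not rec.label and predicted:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, skipped=tuple(skipped))


def _annotating_genes(
    term: str,
    gene_terms: Mapping[str, set[str]],
    ontology: Mapping[str, OntologyTerm] | None,
) -> int:
    if ontology is None:
        return sum(1 for terms in gene_terms.values() if term in terms)
    # propagate: a gene counts if any of its terms has `term` among its
    # reflexive is_a ancestors
    cache: dict[str, bool] = {}

    def reaches(t: str) -> bool:
        if t == term:
            return True
        if t in cache:
            return cache[t]
        cache[t] = False  # cycle guard
        parents = ontology[t].parents if t in ontology else ()
        cache[t] = any(reaches(p) for p in parents)
        return cache[t]

    return sum(1 for terms in gene_terms.values() if any(reaches(t) for t in terms))


def information_content(
    term: str,
    tg: GeneAnnotationMap | Mapping[str, set[str]],
    ontology: Mapping[str, OntologyTerm] | None = None,
) -> float:
    """IC of a term in nats: -ln(annotating genes / total genes).

    Annotation frequency is gene-level and, by default, unpropagated;
    passing an ontology counts genes through is_a ancestor propagation.
    """
    gene_terms = tg.flat() if isinstance(tg, GeneAnnotationMap) else dict(tg)
    n_genes = len(gene_terms)
    if n_genes == 0:
        raise DegenerateDataError("empty gene annotation map")
    n_t = _annotating_genes(term, gene_terms, ontology)
    if n_t == 0:
        raise DegenerateDataError(f"term {term} annotates no gene")
    return -math.log(n_t / n_genes)


def mean_information_content(
    term_usage: Mapping[str, int],
    tg: GeneAnnotationMap | Mapping[str, set[str]],
    weighted: bool = False,
    ontology: Mapping[str, OntologyTerm] | None = None,
) -> float:
    """Mean IC over distinct terms, or annotation-count-weighted mean."""
    if not term_usage:
        raise DegenerateDataError("no terms given")
    ics = {t: information_content(t, tg, ontology) for t in term_usage}
    if not weighted:
        return float(np.mean(list(ics.values())))
    total = sum(term_usage.values())
    return float(sum(ics[t] * c for t, c in term_usage.items()) / total)


@dataclass
class CorrelationResult:
    """Per-shared-count expression-correlation distributions."""

    isoform_bins: dict[int, np.ndarray]
    gene_bins: dict[int, np.ndarray]
    mannwhitney_p: dict[int, float]
    n_pairs: int
    census: dict[int, int]


def _capped_shared(counts: int, cap: int = 10) -> int:
    return min(counts, cap)


def correlation_by_shared_terms(
    expr: pd.DataFrame,
    assignment: AssignmentMatrix,
    tg: GeneAnnotationMap,
    n_pairs: int = 1000,
    seed: int = 0,
    cap: int = 10,
) -> CorrelationResult:
    """Expression correlation stratified by shared GO-term count.

    Isoforms must be expressed (nonzero) in more than half the samples and
    have a standard deviation at or above the 90th percentile of the
    filtered sd distribution.  Pairs are sampled so each shared-count bin
    1..cap holds at least 10% of the pairs; per pair, the Pearson
    correlation of the expression rows is recorded twice — binned by the
    isoform-level shared count and by the gene-level shared count — and a
    two-sided Mann-Whitney U test compares the two distributions per bin.
    """
    if expr.shape[1] < 4:
        raise DegenerateDataError("need at least 4 expression samples")
    rng = np.random.default_rng(seed)

    x = expr.to_numpy(dtype=float)
    nonzero_ok = (x != 0).sum(axis=1) > x.shape[1] / 2
    keep = expr.index[nonzero_ok]
    keep = [i for i in keep if i in assignment.iso_index]
    if len(keep) < 2:
        raise DegenerateDataError("too few expressed isoforms in the assignment")
    sds = expr.loc[keep].std(axis=1, ddof=1)
    cutoff = float(np.percentile(sds.to_numpy(), 90))
    eligible = sorted(i for i in keep if sds[i] >= cutoff)
    if len(eligible) < 2:
        raise DegenerateDataError("standard-deviation filter left <2 isoforms")

    b = assignment.bits.astype(np.int64)
    gene_terms = tg.flat()

    def iso_shared(a: str, c: str) -> int:
        return int(b[assignment.iso_index[a]] @ b[assignment.iso_index[c]])

    def gene_shared(a: str, c: str) -> int:
        ga = gene_terms.get(assignment.isoform_gene.get(a, ""), set())
        gc = gene_terms.get(assignment.isoform_gene.get(c, ""), set())
        return len(ga & gc)

    pools: dict[int, list[tuple[str, str]]] = {i: [] for i in range(cap + 1)}
    for a, c in combinations(eligible, 2):
        pools[_capped_shared(iso_shared(a, c), cap)].append((a, c))
    census = {i: len(p) for i, p in pools.items()}

    per_bin = max(n_pairs // cap, 1)
    chosen: list[tuple[str, str]] = []
    short = {i: n for i, n in census.items() if i >= 1 and n < per_bin}
    if short:
        raise DegenerateDataError(
            f"cannot fill shared-count bins with {per_bin} pairs each; "
            f"bin census: {census}"
        )
    for i in range(1, cap + 1):
        idx = rng.choice(len(pools[i]), size=per_bin, replace=False)
        chosen.extend(pools[i][k] for k in idx)

    iso_bins: dict[int, list[float]] = {}
    gene_bins: dict[int, list[float]] = {}
    for a, c in chosen:
        r = float(np.corrcoef(expr.loc[a].to_numpy(), expr.loc[c].to_numpy())[0, 1])
        if not np.isfinite(r):
            continue
        iso_bins.setdefault(_capped_shared(iso_shared(a, c), cap), []).append(r)
        gene_bins.setdefault(_capped_shared(gene_shared(a, c), cap), []).append(r)

    pvals: dict[int, float] = {}
    for i in range(cap + 1):
        u = iso_bins.get(i, [])
        v = gene_bins.get(i, [])
        if len(u) >= 1 and len(v) >= 1:
            pvals[i] = float(stats.mannwhitneyu(u, v, alternative="two-sided").pvalue)
        else:
            pvals[i] = float("nan")
    return CorrelationResult(
        isoform_bins={i: np.asarray(v) for i, v in iso_bins.items()},
        gene_bins={i: np.asarray(v) for i, v in gene_bins.items()},
        mannwhitney_p=pvals,
        n_pairs=len(chosen),
        census=census,
    )


@dataclass
class DomainSharingResult:
    """Shared-domain counts stratified by shared GO-term count, with the
    rank correlation between the two quantities."""

    isoform_bins: dict[int, list[int]]
    gene_bins: dict[int, list[int]]
    tau_isoform: float
    tau_gene: float
    degenerate: bool = False


def domain_sharing_by_shared_terms(
    domains: Mapping[str, frozenset[str] | set[str]],
    assignment: AssignmentMatrix,
    tg: GeneAnnotationMap,
    cap: int = 10,
) -> DomainSharingResult:
    """Among isoform pairs sharing at least one protein domain, how the
    shared-domain count varies with the shared GO-term count (0..cap),
    for isoform-level vs gene-level term assignment; Kendall's tau
    summarizes each trend (0 with a degenerate flag when undefined)."""
    b = assignment.bits.astype(np.int64)
    gene_terms = tg.flat()
    ids = [i for i in assignment.isoform_ids if domains.get(i)]

    iso_bins: dict[int, list[int]] = {}
    gene_bins: dict[int, list[int]] = {}
    iso_xy: list[tuple[int, int]] = []
    gene_xy: list[tuple[int, int]] = []
    for a, c in combinations(ids, 2):
        shared_dom = len(set(domains[a]) & set(domains[c]))
        if shared_dom == 0:
            continue
        s_iso = _capped_shared(
            int(b[assignment.iso_index[a]] @ b[assignment.iso_index[c]]), cap
        )
        ga = gene_terms.get(assignment.isoform_gene.get(a, ""), set())
        gc = gene_terms.get(assignment.isoform_gene.get(c, ""), set())
        s_gene = _capped_shared(len(ga & gc), cap)
        iso_bins.setdefault(s_iso, []).append(shared_dom)
        gene_bins.setdefault(s_gene, []).append(shared_dom)
        iso_xy.append((s_iso, shared_dom))
        gene_xy.append((s_gene, shared_dom))

    def tau_of(xy: list[tuple[int, int]]) -> tuple[float, bool]:
        if len(xy) < 2:
            return 0.0, True
        xs = np.asarray([p[0] for p in xy])
        ys = np.asarray([p[1] for p in xy])
        if np.unique(xs).size < 2 or np.unique(ys).size < 2:
            return 0.0, True
        tau = stats.kendalltau(xs, ys).statistic
        return (float(tau), False) if np.isfinite(tau) else (0.0, True)

    t_iso, d1 = tau_of(iso_xy)
    t_gene, d2 = tau_of(gene_xy)
    return DomainSharingResult(
        isoform_bins=iso_bins,
        gene_bins=gene_bins,
        tau_isoform=t_iso,
        tau_gene=t_gene,
        degenerate=d1 or d2,
    )
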