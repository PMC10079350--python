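"""Core annotation containers: genes, gene-level term sets, and the binary
isoform-by-term assignment matrix.

The gene-level map ``GeneAnnotationMap`` holds, per subontology, the set of
GO terms annotating each gene (the function :math:`\\psi` mapping genes to
term sets).  The ``AssignmentMatrix`` is the binary isoform x term matrix
(:math:`\\phi`) the EM procedure optimizes, together with the masks that
say which cells are assignable at all (``candidate_mask``), which were
seeded from protein-domain evidence (``seed_mask``) and which are held
fixed during the E-step (``frozen_mask``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParseError

NAMESPACES = ("MF", "BP", "CC")
GO_RE = re.compile(r"^GO:\d{7}$")
IPR_RE = re.compile(r"^IPR\d{6}$")


@dataclass(frozen=True)
class GeneRecord:
    """A gene and the ordered list of its protein-coding isoforms."""

    gene_id: str
    isoform_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.isoform_ids) == 0:
            raise ValueError(f"gene {self.gene_id} has no isoforms")
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValueError(f"gene {self.gene_id} lists duplicate isoforms")


class GeneAnnotationMap:
    """Gene -> GO term sets, partitioned by subontology (MF/BP/CC)."""

    def __init__(self) -> None:
        self._data: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}

    def add(self, gene_id: str, go_id: str, namespace: str) -> None:
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown subontology {namespace!r}")
        if not GO_RE.match(go_id):
            raise ParseError(f"malformed GO accession {go_id!r}")
        self._data[namespace].setdefault(gene_id, set()).add(go_id)

    def ensure_gene(self, gene_id: str) -> None:
        """Register a gene even if it has no terms yet (it still counts in
        the specific-term denominator)."""
        for ns in NAMESPACES:
            self._data[ns].setdefault(gene_id, set())

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for ns in NAMESPACES:
            out.update(self._data[ns])
        return out

    def __len__(self) -> int:
        return len(self.genes)

    def terms(self, gene_id: str, namespace: str | None = None) -> frozenset[str]:
        if namespace is not None:
            return frozenset(self._data[namespace].get(gene_id, ()))
        out: set[str] = set()
        for ns in NAMESPACES:
            out.update(self._data[ns].get(gene_id, ()))
        return frozenset(out)

    def namespace_of(self, go_id: str) -> str | None:
        for ns in NAMESPACES:
            for terms in self._data[ns].values():
                if go_id in terms:
                    return ns
        return None

    def all_terms(self, namespace: str | None = None) -> set[str]:
        spaces = [namespace] if namespace else NAMESPACES
        out: set[str] = set()
        for ns in spaces:
            for terms in self._data[ns].values():
                out.update(terms)
        return out

    def flat(self) -> dict[str, set[str]]:
        """Merged gene -> term set across subontologies."""
        out: dict[str, set[str]] = {}
        for g in self.genes:
            out[g] = set(self.terms(g))
        return out

    def copy(self) -> "GeneAnnotationMap":
        new = GeneAnnotationMap()
        for ns in NAMESPACES:
            new._data[ns] = {g: set(t) for g, t in self._data[ns].items()}
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneAnnotationMap):
            return NotImplemented
        a = {ns: {g: t for g, t in d.items() if t} for ns, d in self._data.items()}
        b = {ns: {g: t for g, t in d.items() if t} for ns, d in other._data.items()}
        return a == b


def filter_specific_terms(
    tg: GeneAnnotationMap | Mapping[str, set[str]], threshold: float = 0.10
) -> set[str]:
    """Terms annotating strictly fewer than ``threshold`` of all genes.

    Only such "specific" terms are assignable to isoforms; broad terms
    carry little information about individual isoforms.  The inequality is
    strict: a term on exactly ``threshold`` of the genes is excluded.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    gene_terms = tg.flat() if isinstance(tg, GeneAnnotationMap) else dict(tg)
    n_genes = len(gene_terms)
    if n_genes == 0:
        raise DegenerateDataError("empty gene annotation map")
    counts: dict[str, int] = {}
    for terms in gene_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t for t, c in counts.items() if c / n_genes < threshold}


@dataclass
class AssignmentMatrix:
    """Binary isoform x GO-term assignment with candidate/seed/frozen masks.

    ``bits`` must stay inside ``candidate_mask`` elementwise; cells with
    ``frozen_mask`` set keep their bit value through every E-step.
    """

    isoform_ids: list[str]
    term_ids: list[str]
    bits: np.ndarray
    candidate_mask: np.ndarray
    isoform_gene: dict[str, str]
    term_namespace: dict[str, str] = field(default_factory=dict)
    seed_mask: np.ndarray | None = None
    frozen_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        p, m = len(self.isoform_ids), len(self.term_ids)
        for name in ("bits", "candidate_mask"):
            arr = getattr(self, name)
            if arr.shape != (p, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(p, m)}")
        if self.seed_mask is None:
            self.seed_mask = np.zeros((p, m), dtype=np.uint8)
        if self.frozen_mask is None:
            self.frozen_mask = np.zeros((p, m), dtype=np.uint8)
        self.bits = self.bits.astype(np.uint8)
        self.candidate_mask = self.candidate_mask.astype(np.uint8)
        if np.any(self.bits & ~self.candidate_mask & 1):
            raise ValueError("set bits outside candidate_mask")
        self._iso_index = {i: k for k, i in enumerate(self.isoform_ids)}
        self._term_index = {t: k for k, t in enumerate(self.term_ids)}

    # -- indexing helpers -------------------------------------------------
    @property
    def iso_index(self) -> dict[str, int]:
        return self._iso_index

    @property
    def term_index(self) -> dict[str, int]:
        return self._term_index

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def has(self, isoform_id: str, go_id: str) -> bool:
        i = self._iso_index.get(isoform_id)
        j = self._term_index.get(go_id)
        if i is None or j is None:
            return False
        return bool(self.bits[i, j])

    def terms_of(self, isoform_id: str) -> list[str]:
        i = self._iso_index[isoform_id]
        return [self.term_ids[j] for j in np.flatnonzero(self.bits[i])]

    def mutable_mask(self) -> np.ndarray:
        return (self.candidate_mask & ~self.frozen_mask).astype(np.uint8) & 1

    def copy(self) -> "AssignmentMatrix":
        return AssignmentMatrix(
            isoform_ids=list(self.isoform_ids),
            term_ids=list(self.term_ids),
            bits=self.bits.copy(),
            candidate_mask=self.candidate_mask.copy(),
            isoform_gene=dict(self.isoform_gene),
            term_namespace=dict(self.term_namespace),
            seed_mask=self.seed_mask.copy(),
            frozen_mask=self.frozen_mask.copy(),
        )

    def restrict_terms(self, keep: Iterable[str]) -> "AssignmentMatrix":
        """New matrix keeping only the given term columns (used to strip
        surrogate columns of another subontology from a finished run)."""
        keep_set = set(keep)
        cols = [j for j, t in enumerate(self.term_ids) if t in keep_set]
        idx = np.asarray(cols, dtype=int)
        return AssignmentMatrix(
            isoform_ids=list(self.isoform_ids),
            term_ids=[self.term_ids[j] for j in cols],
            bits=self.bits[:, idx].copy(),
            candidate_mask=self.candidate_mask[:, idx].copy(),
            isoform_gene=dict(self.isoform_gene),
            term_namespace={t: ns for t, ns in self.term_namespace.items() if t in keep_set},
            seed_mask=self.seed_mask[:, idx].copy(),
            frozen_mask=self.frozen_mask[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per set bit, sorted by (isoform, term)."""
        rows = []
        for i in range(self.shape[0]):
            iso = self.isoform_ids[i]
            for j in np.flatnonzero(self.bits[i]):
                t = self.term_ids[j]
                rows.append(
                    (
                        iso,
                        self.isoform_gene.get(iso, ""),
                        t,
                        self.term_namespace.get(t, ""),
                        "interpro_seed" if self.seed_mask[i, j] else "em_assigned",
                    )
                )
        df = pd.DataFrame(
            rows, columns=["isoform_id", "gene_id", "go_id", "subontology", "origin"]
        )
        return df.sort_values(["isoform_id", "go_id"], kind="mergesort").reset_index(drop=True)

    def with_bits_from(self, df: pd.DataFrame) -> "AssignmentMatrix":
        """Same structure, bits replaced by the (isoform_id, go_id) rows of
        ``df`` (the inverse of :meth:`to_frame` given the template)."""
        new = self.copy()
        new.bits = np.zeros_like(self.bits)
        new.seed_mask = np.zeros_like(self.seed_mask)
        for row in df.itertuples(index=False):
            i = self._iso_index[row.isoform_id]
            j = self._term_index[row.go_id]
            new.bits[i, j] = 1
            if getattr(row, "origin", "em_assigned") == "interpro_seed":
                new.seed_mask[i, j] = 1
        if np.any(new.bits & ~new.candidate_mask & 1):
            raise ValueError("annotation rows outside candidate_mask")
        return new


def augment_gene_annotations(
    tg: GeneAnnotationMap,
    genes: Iterable[GeneRecord],
    domains: Mapping[str, frozenset[str] | set[str]],
    ipr2go: Mapping[str, set[str]],
    term_namespaces: Mapping[str, str],
) -> GeneAnnotationMap:
    """Merge domain-derived GO terms into the gene-level map.

    Gene-level curation and domain-to-GO predictions are combined before the
    specific-term filter: a term predicted for any isoform of a gene via its
    protein domains becomes part of that gene's term set.  Returns a new map.
    """
    out = tg.copy()
    for gene in genes:
        out.ensure_gene(gene.gene_id)
        for iso in gene.isoform_ids:
            for d in domains.get(iso, ()):
                for t in ipr2go.get(d, ()):
                    ns = term_namespaces.get(t)
                    if ns is None:
                        raise ParseError(
                            f"domain-derived term {t} has no known subontology"
                        )
                    out.add(gene.gene_id, t, ns)
    return out


def build_candidates(
    genes: list[GeneRecord],
    tg: GeneAnnotationMap,
    domains: Mapping[str, frozenset[str] | set[str]],
    ipr2go: Mapping[str, set[str]],
    specific: set[str],
    subontology: str,
    term_namespaces: Mapping[str, str] | None = None,
) -> AssignmentMatrix:
    """Build the assignable-cell mask and the domain-seeded initial bits.

    A cell (isoform, term) is a candidate iff the term belongs to the
    isoform's gene, survives the specific-term filter, and lies in the
    active subontology.  The seed sets a candidate bit when one of the
    isoform's protein domains maps to that term.  A domain-derived term not
    yet on the gene is first added to the gene's term set (``tg`` is
    mutated), so the candidate universe always contains the seed.
    """
    if subontology not in NAMESPACES:
        raise ValueError(f"unknown subontology {subontology!r}")
    term_namespaces = term_namespaces or {}

    iso_gene: dict[str, str] = {}
    for gene in genes:
        for iso in gene.isoform_ids:
            if iso in iso_gene:
                raise ValueError(f"isoform {iso} assigned to multiple genes")
            iso_gene[iso] = gene.gene_id

    # fold domain terms into the gene map first (idempotent if already done)
    for gene in genes:
        tg.ensure_gene(gene.gene_id)
        for iso in gene.isoform_ids:
            for d in domains.get(iso, ()):
                for t in ipr2go.get(d, ()):
                    ns = term_namespaces.get(t) or tg.namespace_of(t)
                    if ns is None:
                        raise ParseError(
                            f"domain-derived term {t} has no known subontology"
                        )
                    tg.add(gene.gene_id, t, ns)

    isoform_ids = [iso for gene in genes for iso in gene.isoform_ids]
    iso_pos = {iso: i for i, iso in enumerate(isoform_ids)}
    universe: set[str] = set()
    for gene in genes:
        universe |= set(tg.terms(gene.gene_id, subontology)) & specific
    term_ids = sorted(universe)
    term_index = {t: j for j, t in enumerate(term_ids)}

    p, m = len(isoform_ids), len(term_ids)
    cand = np.zeros((p, m), dtype=np.uint8)
    seed = np.zeros((p, m), dtype=np.uint8)
    for gene in genes:
        gene_terms = set(tg.terms(gene.gene_id, subontology)) & specific
        cols = [term_index[t] for t in gene_terms]
        for iso in gene.isoform_ids:
            i = iso_pos[iso]
            cand[i, cols] = 1
            dom_terms: set[str] = set()
            for d in domains.get(iso, ()):
                dom_terms |= set(ipr2go.get(d, ()))
            for t in gene_terms & dom_terms:
                seed[i, term_index[t]] = 1

    tns = {t: subontology for t in term_ids}
    return AssignmentMatrix(
        isoform_ids=isoform_ids,
        term_ids=term_ids,
        bits=seed.copy(),
        candidate_mask=cand,
        isoform_gene=iso_gene,
        term_namespace=tns,
        seed_mask=seed.copy(),
    )


def shared_term_counts(ti: AssignmentMatrix) -> np.ndarray:
    """Isoform-by-isoform matrix of shared annotation counts.

    The product of the binary assignment matrix with its transpose: entry
    (i, j) counts GO terms annotating both isoforms; the diagonal holds
    each isoform's annotation count.
    """
    b = ti.bits.astype(np.int64)
    return b @ b.T


def combine_assignments(matrices: Iterable[AssignmentMatrix]) -> pd.DataFrame:
    """Concatenate the long-format annotation rows of several matrices
    (one per subontology) into a single frame."""
    frames = [m.to_frame() for m in matrices]
    if not frames:
        return pd.DataFrame(
            columns=["isoform_id", "gene_id", "go_id", "subontology", "origin"]
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["isoform_id", "go_id"], kind="mergesort").reset_index(drop=True)
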