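"""Synthetic corpora with planted ground truth.

Every pipeline stage is testable offline: ``simulate_universe`` plants a
gene/isoform/term universe with a known isoform-level assignment,
``simulate_scores`` draws pair similarities straight from the quadratic
model (optionally noiseless), ``simulate_sequences`` realizes the
sequence-similarity assumption by concatenating per-term motifs, and
``emit_corpus`` writes the whole thing in the exact formats the readers
parse.  Two independent score pathways (model-derived vs sequence-derived)
let the EM machinery and the alignment stack be validated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment import PairScoreTable
from .annotations import AssignmentMatrix, GeneAnnotationMap, GeneRecord
from .driver import eligible_pairs
from .emcore import QuadraticModel

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NS_LONG = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}


@dataclass
class SyntheticTruth:
    """A planted corpus: genes, gene-level terms, true isoform assignment."""

    genes: list[GeneRecord]
    tg: GeneAnnotationMap
    assignment: AssignmentMatrix  # planted truth; candidate_mask = gene terms
    beta: tuple[float, float, float]
    namespace: str
    seed: int
    motifs: dict[str, str] = field(default_factory=dict)

    @property
    def term_namespaces(self) -> dict[str, str]:
        return {t: self.namespace for t in self.assignment.term_ids}

    def gene_terms(self) -> dict[str, set[str]]:
        return {g.gene_id: set(self.tg.terms(g.gene_id, self.namespace)) for g in self.genes}

    def tau(self, iso_a: str, iso_b: str) -> int:
        am = self.assignment
        a, b = am.iso_index[iso_a], am.iso_index[iso_b]
        return int(am.bits[a].astype(np.int64) @ am.bits[b].astype(np.int64))


def simulate_universe(
    n_genes: int = 20,
    isoforms_per_gene: int = 4,
    n_terms: int = 30,
    terms_per_gene: int = 3,
    assign_prob: float = 0.5,
    seed: int = 0,
    beta: tuple[float, float, float] = (0.5, 0.2, 0.05),
    namespace: str = "MF",
) -> SyntheticTruth:
    """Plant a corpus.

    Each gene draws ``terms_per_gene`` terms uniformly from the universe;
    each gene term lands on each isoform with probability ``assign_prob``,
    then coverage is repaired so every gene term annotates at least one
    isoform (the truth satisfies the coverage assumption by construction).
    """
    if min(n_genes, isoforms_per_gene, n_terms, terms_per_gene) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 < assign_prob <= 1:
        raise ValueError("assign_prob must be in (0, 1]")
    if terms_per_gene > n_terms:
        raise ValueError("terms_per_gene cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    term_ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]

    genes: list[GeneRecord] = []
    tg = GeneAnnotationMap()
    iso_gene: dict[str, str] = {}
    iso_counter = 0
    for g in range(1, n_genes + 1):
        gid = f"SYNG{g:04d}"
        isos = []
        for _ in range(isoforms_per_gene):
            iso_counter += 1
            iso = f"SYNT{iso_counter:05d}"
            isos.append(iso)
            iso_gene[iso] = gid
        genes.append(GeneRecord(gene_id=gid, isoform_ids=tuple(isos)))
        for t in rng.choice(term_ids, size=terms_per_gene, replace=False):
            tg.add(gid, str(t), namespace)

    isoform_ids = [iso for g in genes for iso in g.isoform_ids]
    term_index = {t: j for j, t in enumerate(term_ids)}
    p, m = len(isoform_ids), len(term_ids)
    bits = np.zeros((p, m), dtype=np.uint8)
    cand = np.zeros((p, m), dtype=np.uint8)
    pos = {iso: i for i, iso in enumerate(isoform_ids)}
    for gene in genes:
        gterms = sorted(tg.terms(gene.gene_id, namespace))
        cols = [term_index[t] for t in gterms]
        rows = [pos[iso] for iso in gene.isoform_ids]
        for i in rows:
            cand[i, cols] = 1
            bits[i, cols] = rng.random(len(cols)) < assign_prob
        # repair: every gene term covered by >= 1 isoform
        for j in cols:
            if not bits[rows, j].any():
                bits[rows[int(rng.integers(len(rows)))], j] = 1

    assignment = AssignmentMatrix(
        isoform_ids=isoform_ids,
        term_ids=term_ids,
        bits=bits,
        candidate_mask=cand,
        isoform_gene=iso_gene,
        term_namespace={t: namespace for t in term_ids},
    )
    return SyntheticTruth(
        genes=genes, tg=tg, assignment=assignment, beta=beta,
        namespace=namespace, seed=seed,
    )


class PlantedScoreProvider:
    """Score provider drawing similarities from the quadratic model of the
    planted shared-term counts: S = b2*tau^2 + b1*tau + b0 + N(0, noise_sd).

    The noise of each unordered pair is sampled once and cached, so
    repeated requests across EM iterations see the same observation.
    ``noise_sd=0`` gives the noiseless pathway.
    """

    def __init__(
        self,
        truth: SyntheticTruth,
        beta: tuple[float, float, float] | None = None,
        noise_sd: float = 1.0,
        seed: int = 0,
    ) -> None:
        self.truth = truth
        b = beta if beta is not None else truth.beta
        self.model = QuadraticModel(beta0=b[0], beta1=b[1], beta2=b[2])
        self.noise_sd = float(noise_sd)
        self._rng = np.random.default_rng(seed)
        self._noise: dict[tuple[str, str], float] = {}

    def _noise_of(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._noise:
            self._noise[key] = (
                float(self._rng.standard_normal()) * self.noise_sd
                if self.noise_sd > 0
                else 0.0
            )
        return self._noise[key]

    def scores(self, pairs: Sequence[tuple[str, str]]) -> PairScoreTable:
        vals = np.asarray(
            [
                float(self.model.predict(self.truth.tau(a, b))) + self._noise_of(a, b)
                for a, b in pairs
            ]
        )
        return PairScoreTable(pairs=list(pairs), raw=vals.copy(), std=vals, meta=None)


def simulate_scores(
    truth: SyntheticTruth,
    beta: tuple[float, float, float] | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> PairScoreTable:
    """Standardized-scale similarities for the corpus' eligible pairs."""
    if pairs is None:
        pairs = eligible_pairs(
            truth.assignment.isoform_ids,
            truth.assignment.isoform_gene,
            truth.gene_terms(),
        )
    provider = PlantedScoreProvider(truth, beta=beta, noise_sd=noise_sd, seed=seed)
    return provider.scores(pairs)


def simulate_sequences(
    truth: SyntheticTruth,
    motif_len: int = 12,
    filler_len: int = 8,
    seed: int = 0,
) -> dict[str, str]:
    """Protein sequences realizing the similarity assumption: each term has
    a fixed random motif and an isoform concatenates the motifs of its
    planted terms (GO order) interleaved with per-isoform random filler, so
    the local-alignment score grows with the shared-term count."""
    if motif_len < 5:
        raise ValueError("motif_len must be >= 5")
    rng = np.random.default_rng(seed)
    motifs = {
        t: "".join(rng.choice(list(_AA), size=motif_len))
        for t in truth.assignment.term_ids
    }
    truth.motifs = motifs
    out: dict[str, str] = {}
    for iso in truth.assignment.isoform_ids:
        parts: list[str] = []

        def filler() -> str:
            return "".join(rng.choice(list(_AA), size=filler_len))

        parts.append(filler())
        for t in sorted(truth.assignment.terms_of(iso)):
            parts.append(motifs[t])
            parts.append(filler())
        seq = "".join(parts)
        out[iso] = seq if seq else "".join(rng.choice(list(_AA), size=5))
    return out


def domain_seed(
    truth: SyntheticTruth, seed_fraction: float = 0.3, seed: int = 0
) -> tuple[dict[str, frozenset[str]], dict[str, set[str]]]:
    """Domain table and domain->GO mapping marking a random fraction of
    planted bits: each term gets its own synthetic InterPro accession, and
    a sampled planted (isoform, term) bit gives the isoform that domain."""
    if not 0 <= seed_fraction <= 1:
        raise ValueError("seed_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    am = truth.assignment
    ipr_of = {t: f"IPR{j + 1:06d}" for j, t in enumerate(am.term_ids)}
    ipr2go = {ipr: {t} for t, ipr in ipr_of.items()}
    domains: dict[str, set[str]] = {}
    for i, iso in enumerate(am.isoform_ids):
        for j in np.flatnonzero(am.bits[i]):
            if rng.random() < seed_fraction:
                domains.setdefault(iso, set()).add(ipr_of[am.term_ids[int(j)]])
    return {k: frozenset(v) for k, v in domains.items()}, ipr2go


def emit_corpus(
    truth: SyntheticTruth,
    out_dir: str | Path,
    seed_fraction: float = 0.3,
    seed: int = 0,
    sequences: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write the corpus as GAF / OBO stub / FASTA / domain TSV / domain-GO
    mapping text, exactly the formats the IO module reads back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ns = truth.namespace
    aspect = {"MF": "F", "BP": "P", "CC": "C"}[ns]

    gaf = out / "annotations.gaf"
    with open(gaf, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in truth.genes:
            for t in sorted(truth.tg.terms(gene.gene_id, ns)):
                fields = [
                    "SYNDB", gene.gene_id, gene.gene_id, "enables", t,
                    "SYN_REF:0000001", "IEA", "", aspect, gene.gene_id, "",
                    "protein", "taxon:9606", "20240101", "SYN", "", "",
                ]
                fh.write("\t".join(fields) + "\n")

    obo = out / "ontology.obo"
    with open(obo, "w") as fh:
        fh.write("format-version: 1.2\nontology: syn\n")
        for t in truth.assignment.term_ids:
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            fh.write(f"namespace: {_NS_LONG[ns]}\n")

    if sequences is None:
        sequences = simulate_sequences(truth, seed=seed)
    fasta = out / "isoforms.fasta"
    with open(fasta, "w") as fh:
        for iso in truth.assignment.isoform_ids:
            gene = truth.assignment.isoform_gene[iso]
            fh.write(f">{iso} pep gene:{gene}\n{sequences[iso]}\n")

    dom_map, ipr2go = domain_seed(truth, seed_fraction=seed_fraction, seed=seed)
    dom_path = out / "isoform_domains.tsv"
    with open(dom_path, "w") as fh:
        fh.write("isoform_id\tdomain\n")
        for iso in sorted(dom_map):
            for d in sorted(dom_map[iso]):
                fh.write(f"{iso}\t{d}\n")

    i2g_path = out / "interpro2go.txt"
    with open(i2g_path, "w") as fh:
        fh.write("!synthetic domain to GO mapping\n")
        for ipr in sorted(ipr2go):
            for t in sorted(ipr2go[ipr]):
                fh.write(f"InterPro:{ipr} synthetic domain > GO:synthetic ; {t}\n")

    return {
        "gaf": gaf, "obo": obo, "fasta": fasta,
        "domains": dom_path, "ipr2go": i2g_path,
    }


def curation_from_truth(
    truth: SyntheticTruth, n_records: int = 50, seed: int = 0
) -> list[tuple[str, str, bool]]:
    """Sample (isoform, term, label) triples from the planted truth:
    positives from set candidate bits, negatives from unset candidate bits."""
    rng = np.random.default_rng(seed)
    am = truth.assignment
    pos = np.argwhere((am.bits & am.candidate_mask) == 1)
    neg = np.argwhere((am.candidate_mask & ~am.bits) == 1)
    records: list[tuple[str, str, bool]] = []
    n_pos = min(n_records // 2, len(pos))
    n_neg = min(n_records - n_pos, len(neg))
    for idx in rng.choice(len(pos), size=n_pos, replace=False):
        i, j = pos[idx]
        records.append((am.isoform_ids[int(i)], am.term_ids[int(j)], True))
    for idx in rng.choice(len(neg), size=n_neg, replace=False):
        i, j = neg[idx]
        records.append((am.isoform_ids[int(i)], am.term_ids[int(j)], False))
    return records
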