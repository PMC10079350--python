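"""Readers and writers for every file format the tool touches.

Standard formats (GAF 2.x, OBO 1.2, protein FASTA, the external2go mapping
text) plus the bespoke TSVs this package defines: the isoform->InterPro
domain table, the curated isoform-function labels, the output annotation
table and an isoform-by-sample expression matrix.  No algorithmic logic
lives here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import obonet
import pandas as pd
from Bio import SeqIO

from .annotations import GO_RE, IPR_RE, AssignmentMatrix, GeneAnnotationMap
from .errors import DuplicateRecordError, ParseError

_ASPECT_TO_NS = {"F": "MF", "P": "BP", "C": "CC"}
_OBO_NS = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
_VERSION_RE = re.compile(r"\.\d+$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXU*]*$")
_I2G_RE = re.compile(
    r"^InterPro:(IPR\d{6})\s+.*?>\s*GO:.*?;\s*(GO:\d{7})\s*$"
)
_TRUE_TOKENS = {"1", "true", "t", "yes"}
_FALSE_TOKENS = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class CurationRecord:
    """One literature-curated (isoform, GO term) association or exclusion."""

    isoform_id: str
    go_id: str
    label: bool
    source: str = ""

    def __post_init__(self) -> None:
        if not GO_RE.match(self.go_id):
            raise ParseError(f"malformed GO accession {self.go_id!r}")


class OntologyTerm(NamedTuple):
    namespace: str
    parents: tuple[str, ...]


def strip_version(accession: str) -> str:
    """Drop a trailing transcript/gene version suffix (``.N``)."""
    return _VERSION_RE.sub("", accession)


def read_gene_annotations(gaf_path: str | Path) -> GeneAnnotationMap:
    """Parse a GAF 2.x file into a gene -> GO-term map per subontology.

    Rows with a ``NOT`` qualifier are excluded; duplicate (gene, term)
    rows collapse.  Gene identity is the DB object ID (column 2).
    """
    tg = GeneAnnotationMap()
    with open(gaf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if not 15 <= len(fields) <= 17:
                raise ParseError(
                    f"{gaf_path}:{lineno}: expected 15-17 tab-separated "
                    f"columns, got {len(fields)}"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            gene_id = fields[1]
            go_id = fields[4]
            aspect = fields[8]
            ns = _ASPECT_TO_NS.get(aspect)
            if ns is None:
                raise ParseError(
                    f"{gaf_path}:{lineno}: unknown aspect code {aspect!r}"
                )
            if not GO_RE.match(go_id):
                raise ParseError(
                    f"{gaf_path}:{lineno}: malformed GO accession {go_id!r}"
                )
            tg.add(gene_id, go_id, ns)
    return tg


def read_ontology(obo_path: str | Path) -> dict[str, OntologyTerm]:
    """Parse an OBO 1.2 file into term -> (subontology, is_a parents).

    Obsolete terms are excluded; namespaces map onto MF/BP/CC.
    """
    try:
        graph = obonet.read_obo(str(obo_path))
    except Exception as exc:  # noqa: BLE001 - wrap parser internals
        raise ParseError(f"cannot parse OBO file {obo_path}: {exc}") from exc
    out: dict[str, OntologyTerm] = {}
    for term, data in graph.nodes(data=True):
        ns_name = data.get("namespace")
        ns = _OBO_NS.get(ns_name or "")
        if ns is None:
            raise ParseError(
                f"term {term} has unknown namespace {ns_name!r}"
            )
        parents = tuple(data.get("is_a", ()))
        out[term] = OntologyTerm(namespace=ns, parents=parents)
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> isoform accession (version-stripped) -> sequence.

    Sequences are uppercased; a trailing stop ``*`` is removed; only the 20
    standard residues plus X, U and internal ``*`` are accepted.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = strip_version(record.id)
        if acc in out:
            raise DuplicateRecordError(f"duplicate accession {acc} in {path}")
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not _AA_RE.match(seq):
            bad = sorted(set(seq) - set("ACDEFGHIKLMNPQRSTVWYXU*"))
            raise ParseError(
                f"record {record.id} in {path} contains illegal residue(s) {bad}"
            )
        out[acc] = seq
    return out


def read_gene_map_from_fasta(path: str | Path) -> dict[str, str]:
    """Isoform -> gene mapping from ``gene:<accession>`` tokens in FASTA
    description lines (the convention of Ensembl peptide FASTA headers).

    Records lacking a ``gene:`` token raise a parse error; accessions are
    version-stripped.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = strip_version(record.id)
        gene = None
        for token in record.description.split():
            if token.startswith("gene:"):
                gene = strip_version(token[len("gene:"):])
                break
        if gene is None:
            raise ParseError(
                f"record {record.id} in {path} has no 'gene:' header token"
            )
        out[acc] = gene
    return out


def read_interpro2go(path: str | Path) -> dict[str, set[str]]:
    """external2go mapping text -> InterPro accession -> set of GO terms."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            m = _I2G_RE.match(line.rstrip("\n"))
            if not m:
                raise ParseError(f"{path}:{lineno}: unparseable mapping line")
            ipr, go = m.groups()
            out.setdefault(ipr, set()).add(go)
    return out


def _looks_like_header(fields: list[str]) -> bool:
    return fields[0].strip().lower() in {"isoform_id", "isoform", "transcript_id"}


def read_isoform_domains(path: str | Path) -> dict[str, frozenset[str]]:
    """Two-column TSV (isoform_id, InterPro accession) -> per-isoform
    domain sets.  Header row optional.  Isoforms absent from the file have
    no entry (treated as empty domain sets downstream)."""
    grouped: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            iso = strip_version(fields[0].strip())
            ipr = fields[1].strip()
            if not IPR_RE.match(ipr):
                raise ParseError(
                    f"{path}:{lineno}: malformed InterPro accession {ipr!r}"
                )
            grouped.setdefault(iso, set()).add(ipr)
    return {iso: frozenset(d) for iso, d in grouped.items()}


def read_curation(path: str | Path) -> list[CurationRecord]:
    """Curated isoform-function TSV (isoform_id, go_id, label[, source])."""
    records: list[CurationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            token = fields[2].strip().lower()
            if token in _TRUE_TOKENS:
                label = True
            elif token in _FALSE_TOKENS:
                label = False
            else:
                raise ParseError(
                    f"{path}:{lineno}: label {fields[2]!r} not recognized; "
                    f"accepted tokens: {sorted(_TRUE_TOKENS | _FALSE_TOKENS)}"
                )
            source = fields[3].strip() if len(fields) > 3 else ""
            records.append(
                CurationRecord(
                    isoform_id=strip_version(fields[0].strip()),
                    go_id=fields[1].strip(),
                    label=label,
                    source=source,
                )
            )
    return records


ANNOTATION_COLUMNS = ["isoform_id", "gene_id", "go_id", "subontology", "origin"]


def write_isoform_annotations(assignment: AssignmentMatrix, path: str | Path) -> None:
    """Write one TSV row per set bit, sorted by (isoform, GO id)."""
    df = assignment.to_frame()
    df.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def read_isoform_annotations(path: str | Path) -> pd.DataFrame:
    """Read back an annotation TSV written by :func:`write_isoform_annotations`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        df = pd.DataFrame(columns=ANNOTATION_COLUMNS)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Isoform-by-sample expression TSV (first column = isoform id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [strip_version(str(i)) for i in df.index]
    return df
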