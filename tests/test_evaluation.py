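"""Evaluation: curation confusion, information content, and the
expression / domain consistency checks."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from isofunc.annotations import AssignmentMatrix, GeneAnnotationMap
from isofunc.errors import DegenerateDataError
from isofunc.evaluation import (
    confusion_vs_curation,
    correlation_by_shared_terms,
    domain_sharing_by_shared_terms,
    information_content,
    mean_information_content,
)
from isofunc.io import CurationRecord, OntologyTerm


def make_assignment(bits: np.ndarray, genes: dict[str, str], terms=None):
    n, m = bits.shape
    term_ids = terms or [f"GO:{j:07d}" for j in range(1, m + 1)]
    return AssignmentMatrix(
        isoform_ids=[f"T{k}" for k in range(n)],
        term_ids=term_ids,
        bits=bits.astype(np.uint8),
        candidate_mask=np.ones((n, m), dtype=np.uint8),
        isoform_gene=genes,
    )


class TestConfusion:
    @staticmethod
    def _records():
        return [
            CurationRecord("T0", "GO:0000001", True, ""),   # predicted 1 -> TP
            CurationRecord("T0", "GO:0000002", True, ""),   # predicted 0 -> FN
            CurationRecord("T1", "GO:0000001", False, ""),  # predicted 1 -> FP
            CurationRecord("T1", "GO:0000002", False, ""),  # predicted 0 -> TN
            CurationRecord("T9", "GO:0000001", True, ""),   # unknown isoform
        ]

    def _assignment(self):
        bits = np.array([[1, 0], [1, 0]])
        return make_assignment(bits, {"T0": "G", "T1": "G"})

    def test_hand_counts(self):
        s = confusion_vs_curation(self._assignment(), self._records())
        assert (s.tp, s.fn, s.fp, s.tn) == (1, 1, 1, 1)
        assert s.tp_rate == 0.5 and s.fp_rate == 0.5
        assert [r.isoform_id for r in s.skipped] == ["T9"]
        assert s.n_evaluated == 4

    def test_order_invariant(self):
        recs = self._records()
        s1 = confusion_vs_curation(self._assignment(), recs)
        s2 = confusion_vs_curation(self._assignment(), list(reversed(recs)))
        assert (s1.tp, s1.fp, s1.tn, s1.fn) == (s2.tp, s2.fp, s2.tn, s2.fn)

    def test_empty_rates_are_nan(self):
        s = confusion_vs_curation(self._assignment(), [])
        assert np.isnan(s.tp_rate) and np.isnan(s.fp_rate)


class TestInformationContent:
    @staticmethod
    def _tg(n_genes: int, annotate: dict[str, list[int]]) -> GeneAnnotationMap:
        tg = GeneAnnotationMap()
        for g in range(n_genes):
            tg.ensure_gene(f"G{g}")
        for term, gs in annotate.items():
            for g in gs:
                tg.add(f"G{g}", term, "MF")
        return tg

    def test_universal_term_zero(self):
        tg = self._tg(5, {"GO:0000001": [0, 1, 2, 3, 4]})
        assert information_content("GO:0000001", tg) == pytest.approx(0.0)

    def test_rare_term_log_value(self):
        tg = self._tg(100, {"GO:0000001": [0]})
        assert information_content("GO:0000001", tg) == pytest.approx(
            4.605170185988091, abs=1e-9
        )

    def test_rarer_is_more_informative(self):
        tg = self._tg(50, {"GO:0000001": [0, 1], "GO:0000002": list(range(20))})
        assert information_content("GO:0000001", tg) > information_content(
            "GO:0000002", tg
        )

    def test_unknown_term_errors(self):
        with pytest.raises(DegenerateDataError):
            information_content("GO:0000009", self._tg(5, {"GO:0000001": [0]}))

    def test_propagation_counts_descendants(self):
        tg = self._tg(10, {"GO:0000002": [0, 1, 2]})
        onto = {
            "GO:0000001": OntologyTerm("MF", ()),
            "GO:0000002": OntologyTerm("MF", ("GO:0000001",)),
        }
        # unpropagated, the parent annotates nothing; propagated it inherits
        # the child's three genes
        with pytest.raises(DegenerateDataError):
            information_content("GO:0000001", tg)
        assert information_content("GO:0000001", tg, onto) == pytest.approx(
            -np.log(3 / 10)
        )
        assert information_content("GO:0000002", tg, onto) == pytest.approx(
            -np.log(3 / 10)
        )

    def test_mean_matches_loop_oracle(self):
        tg = self._tg(40, {"GO:0000001": [0], "GO:0000002": list(range(10)),
                           "GO:0000003": list(range(25))})
        usage = {"GO:0000001": 1, "GO:0000002": 5, "GO:0000003": 4}
        ics = [information_content(t, tg) for t in usage]
        assert mean_information_content(usage, tg) == pytest.approx(np.mean(ics))
        weighted = sum(
            information_content(t, tg) * c for t, c in usage.items()
        ) / sum(usage.values())
        assert mean_information_content(usage, tg, weighted=True) == pytest.approx(
            weighted
        )


def _two_group_world():
    """10 isoforms with terms {1,2} plus one with {1}: pair shared counts
    are 2 within the big group and 1 across."""
    bits = np.vstack([np.tile([1, 1, 0], (10, 1)), [[1, 0, 0]]])
    genes = {f"T{k}": "G1" for k in range(10)}
    genes["T10"] = "G2"
    am = make_assignment(bits, genes)
    tg = GeneAnnotationMap()
    for t in ("GO:0000001", "GO:0000002"):
        tg.add("G1", t, "MF")
    tg.add("G2", "GO:0000001", "MF")
    return am, tg


class TestExpressionCorrelation:
    P = np.arange(1.0, 9.0)

    def test_identical_rows_correlate_perfectly(self):
        am, tg = _two_group_world()
        expr = pd.DataFrame([self.P] * 11, index=am.isoform_ids)
        res = correlation_by_shared_terms(expr, am, tg, n_pairs=20, seed=0, cap=2)
        for vals in res.isoform_bins.values():
            assert np.allclose(vals, 1.0)
        assert res.n_pairs == 20

    def test_constructed_bins_separate(self):
        am, tg = _two_group_world()
        rows = [self.P] * 10 + [self.P[::-1]]  # T10 anti-correlated
        expr = pd.DataFrame(rows, index=am.isoform_ids)
        res = correlation_by_shared_terms(expr, am, tg, n_pairs=20, seed=1, cap=2)
        # shared-count-2 pairs are within the identical group; shared-count-1
        # pairs all involve the reversed profile
        assert np.median(res.isoform_bins[2]) == pytest.approx(1.0)
        assert np.median(res.isoform_bins[1]) == pytest.approx(-1.0)
        assert res.mannwhitney_p[1] <= 1.0

    def test_independent_rows_mean_near_zero(self):
        n = 30
        bits = np.ones((n, 1))
        am = make_assignment(bits, {f"T{k}": "G1" for k in range(n)})
        tg = GeneAnnotationMap()
        tg.add("G1", "GO:0000001", "MF")
        rng = np.random.default_rng(5)
        base = np.arange(1.0, 21.0)
        rows = [rng.permutation(base) for _ in range(n)]  # equal sds, independent
        expr = pd.DataFrame(rows, index=am.isoform_ids)
        res = correlation_by_shared_terms(expr, am, tg, n_pairs=100, seed=2, cap=1)
        assert abs(np.mean(res.isoform_bins[1])) < 0.1

    def test_unfillable_bin_reports_census(self):
        am, tg = _two_group_world()
        expr = pd.DataFrame([self.P] * 11, index=am.isoform_ids)
        with pytest.raises(DegenerateDataError, match="census"):
            correlation_by_shared_terms(expr, am, tg, n_pairs=5000, seed=0, cap=2)

    def test_too_few_samples(self):
        am, tg = _two_group_world()
        expr = pd.DataFrame([[1.0, 2.0, 3.0]] * 11, index=am.isoform_ids)
        with pytest.raises(DegenerateDataError):
            correlation_by_shared_terms(expr, am, tg)


class TestDomainSharing:
    def test_mirrored_domains_give_perfect_isoform_tau(self):
        # two genes; every isoform carries one domain per planted term, so
        # shared domains equal the isoform-level shared-term count exactly
        bits = np.array([[1, 1], [1, 0], [1, 1], [1, 1]])
        genes = {"T0": "G1", "T1": "G1", "T2": "G2", "T3": "G2"}
        am = make_assignment(bits, genes)
        tg = GeneAnnotationMap()
        tg.add("G1", "GO:0000001", "MF")
        tg.add("G1", "GO:0000002", "MF")
        tg.add("G2", "GO:0000001", "MF")
        dom = {
            iso: frozenset(
                f"IPR{j + 1:06d}" for j in np.flatnonzero(bits[am.iso_index[iso]])
            )
            for iso in am.isoform_ids
        }
        res = domain_sharing_by_shared_terms(dom, am, tg)
        assert res.tau_isoform == pytest.approx(1.0)
        assert not res.degenerate
        assert res.tau_isoform > res.tau_gene

    def test_degenerate_flagged_as_zero(self):
        bits = np.array([[1, 0], [1, 0]])
        am = make_assignment(bits, {"T0": "G1", "T1": "G1"})
        tg = GeneAnnotationMap()
        tg.add("G1", "GO:0000001", "MF")
        dom = {"T0": frozenset({"IPR000001"}), "T1": frozenset({"IPR000001"})}
        res = domain_sharing_by_shared_terms(dom, am, tg)
        assert res.degenerate
        assert res.tau_isoform == 0.0 and res.tau_gene == 0.0

    def test_bins_match_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        n, m = 12, 5
        bits = (rng.random((n, m)) < 0.5).astype(np.uint8)
        genes = {f"T{k}": f"G{k % 3}" for k in range(n)}
        am = make_assignment(bits, genes)
        tg = GeneAnnotationMap()
        for g in range(3):
            for j in range(m):
                if rng.random() < 0.6:
                    tg.add(f"G{g}", f"GO:{j + 1:07d}", "MF")
        pool = [f"IPR{j:06d}" for j in range(1, 7)]
        dom = {
            f"T{k}": frozenset(
                rng.choice(pool, size=int(rng.integers(0, 4)), replace=False)
            )
            for k in range(n)
        }
        res = domain_sharing_by_shared_terms(dom, am, tg)
        expected: dict[int, list[int]] = {}
        ids = [i for i in am.isoform_ids if dom.get(i)]
        for a, c in combinations(ids, 2):
            nshared = len(set(dom[a]) & set(dom[c]))
            if nshared == 0:
                continue
            tau = int(
                bits[am.iso_index[a]].astype(int) @ bits[am.iso_index[c]].astype(int)
            )
            expected.setdefault(min(tau, 10), []).append(nshared)
        assert {k: sorted(v) for k, v in res.isoform_bins.items()} == {
            k: sorted(v) for k, v in expected.items()
        }
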