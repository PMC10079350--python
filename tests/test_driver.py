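"""Mini-batch EM orchestration: partitioning, pair eligibility, the
convergence rule, sigma accumulation and the subontology schedule."""

from __future__ import annotations

import math
import zlib

import numpy as np
import pytest
from scipy import stats

from isofunc.alignment import PairScoreTable
from isofunc.annotations import (
    GeneAnnotationMap,
    GeneRecord,
    shared_term_counts,
)
from isofunc.driver import (
    CorpusInputs,
    EMConfig,
    EMState,
    _attach_frozen,
    check_convergence,
    coverage_report,
    eligible_pairs,
    estep_iteration,
    partition,
    run_full,
    run_subontology,
)
from isofunc.emcore import QuadraticModel, log_likelihood
from isofunc.errors import DegenerateDataError
from isofunc.ga import GAParams
from isofunc.synthetic import PlantedScoreProvider

LOG_2PI_HALF = math.log(2 * math.pi) / 2


class TestPartition:
    def test_deterministic_and_in_range(self):
        ids = [f"I{k}" for k in range(200)]
        p1 = partition(ids, k=7, seed=3)
        p2 = partition(ids, k=7, seed=3)
        assert p1.labels == p2.labels
        assert set(p1.labels) == set(ids)
        assert all(1 <= v <= 7 for v in p1.labels.values())

    def test_k_one_single_subset(self):
        ids = ["A", "B", "C"]
        subsets = partition(ids, k=1, seed=0).subsets()
        assert subsets == {1: ["A", "B", "C"]}

    def test_uniformity_chi_square(self):
        ids = [f"I{k:05d}" for k in range(10000)]
        labels = list(partition(ids, k=10, seed=42).labels.values())
        counts = np.bincount(labels, minlength=11)[1:]
        assert counts.sum() == 10000
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            partition(["A"], k=0)


class TestEligiblePairs:
    GENE = {"A": "G1", "B": "G1", "C": "G2", "D": "G3"}
    TERMS = {"G1": {"t1"}, "G2": {"t1", "t2"}, "G3": {"t3"}}

    def test_hand_example(self):
        got = eligible_pairs(["D", "C", "B", "A"], self.GENE, self.TERMS)
        assert got == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_same_gene_needs_a_term(self):
        assert eligible_pairs(["A", "B"], {"A": "G9", "B": "G9"}, {"G9": set()}) == []

    def test_unknown_gene_errors(self):
        with pytest.raises(DegenerateDataError, match="Z"):
            eligible_pairs(["A", "Z"], self.GENE, self.TERMS)

    def test_matches_set_oracle_on_synthetic(self, tiny_truth):
        ids = tiny_truth.assignment.isoform_ids[:12]
        gene_of = tiny_truth.assignment.isoform_gene
        gterms = tiny_truth.gene_terms()
        got = set(eligible_pairs(ids, gene_of, gterms))
        want = {
            (a, b)
            for a in ids
            for b in ids
            if a < b and gterms[gene_of[a]] & gterms[gene_of[b]]
        }
        assert got == want


class TestConvergence:
    def test_needs_window_plus_one(self):
        assert not check_convergence([0.0] * 10, window=25)
        assert not check_convergence([0.0] * 25, window=25)
        assert check_convergence([0.0] * 26, window=25)

    def test_small_rise_converges(self):
        trace = list(np.linspace(0.0, 0.25, 26))  # total rise 0.25 < 1/3
        assert check_convergence(trace, window=25, threshold=1 / 3)

    def test_large_rise_does_not(self):
        trace = list(np.linspace(0.0, 0.5, 26))
        assert not check_convergence(trace, window=25, threshold=1 / 3)

    def test_signed_accepts_any_drop(self):
        trace = [0.0] * 3 + [-5.0]
        assert check_convergence(trace, window=3, threshold=1 / 3, mode="signed")
        assert not check_convergence(trace, window=3, threshold=1 / 3, mode="abs")

    def test_uses_only_last_window(self):
        # a huge old rise followed by a flat window still converges
        trace = [0.0, 100.0] + [100.0] * 25
        assert check_convergence(trace, window=25, threshold=1 / 3)


class TestEstep:
    def test_noiseless_truth_hits_likelihood_ceiling(self, tiny_truth, noiseless_provider):
        am = tiny_truth.assignment.copy()
        state = EMState(
            assignment=am,
            model=QuadraticModel(*tiny_truth.beta),
            gene_terms=tiny_truth.gene_terms(),
            provider=noiseless_provider,
            rng=np.random.default_rng(1),
        )
        sigma = estep_iteration(state, EMConfig(n_subsets=1), ga_search=False)
        # one subset, zero residuals: sigma = -log(2*pi)/2 exactly
        assert sigma == pytest.approx(-LOG_2PI_HALF, abs=1e-9)
        assert state.sigma_trace == [sigma]
        assert state.iteration == 1

    def test_sigma_matches_hand_accumulation(self, tiny_truth):
        provider = PlantedScoreProvider(tiny_truth, noise_sd=1.0, seed=9)
        am = tiny_truth.assignment.copy()
        model = QuadraticModel(*tiny_truth.beta)
        state = EMState(
            assignment=am,
            model=model,
            gene_terms=tiny_truth.gene_terms(),
            provider=provider,
            rng=np.random.default_rng(7),
        )
        # replay the partition seed the E-step will draw
        pseed = int(np.random.default_rng(7).integers(2**31))
        part = partition(am.isoform_ids, 5, pseed)
        expected = 0.0
        taus_all = shared_term_counts(am)
        for _, ids in sorted(part.subsets().items()):
            pairs = eligible_pairs(ids, am.isoform_gene, state.gene_terms)
            if not pairs:
                continue
            table = provider.scores(pairs)
            taus = [
                taus_all[am.iso_index[a], am.iso_index[b]] for a, b in table.pairs
            ]
            ll, n = log_likelihood(table, np.asarray(taus), model)
            expected += ll / n
        sigma = estep_iteration(state, EMConfig(n_subsets=5), ga_search=False)
        assert sigma == pytest.approx(expected, abs=1e-9)

    def test_ga_search_never_lowers_sigma_noiseless(self, tiny_truth, noiseless_provider):
        # starting from the truth, the GA cannot beat zero residuals,
        # and elitism keeps it from losing them within a subset
        am = tiny_truth.assignment.copy()
        state = EMState(
            assignment=am,
            model=QuadraticModel(*tiny_truth.beta),
            gene_terms=tiny_truth.gene_terms(),
            provider=noiseless_provider,
            rng=np.random.default_rng(2),
        )
        cfg = EMConfig(n_subsets=10, ga=GAParams(population_size=10, generations=5))
        sigma = estep_iteration(state, cfg, ga_search=True)
        # each contributing subset stays at its per-pair ceiling -log(2*pi)/2
        assert len(state.last_pass) >= 1
        assert sigma == pytest.approx(-LOG_2PI_HALF * len(state.last_pass), abs=1e-9)


def _two_namespace_inputs() -> CorpusInputs:
    """Two genes, isoforms T1..T4 / T5..T8; BP and CC gene terms."""
    tg = GeneAnnotationMap()
    for t in ("GO:0000011", "GO:0000012"):
        tg.add("G1", t, "BP")
    tg.add("G2", "GO:0000013", "BP")
    tg.add("G1", "GO:0000021", "CC")
    tg.add("G2", "GO:0000022", "CC")
    genes = [
        GeneRecord("G1", ("T1", "T2", "T3", "T4")),
        GeneRecord("G2", ("T5", "T6", "T7", "T8")),
    ]
    tns = {
        "GO:0000011": "BP", "GO:0000012": "BP", "GO:0000013": "BP",
        "GO:0000021": "CC", "GO:0000022": "CC",
    }
    return CorpusInputs(
        genes=genes, tg=tg, domains={}, ipr2go={}, term_namespaces=tns
    )


class HashScoreProvider:
    """Deterministic pseudo-random pair scores from a CRC32 of the ids."""

    def scores(self, pairs):
        vals = []
        for a, b in pairs:
            key = f"{min(a, b)}|{max(a, b)}"
            vals.append(
                float(np.random.default_rng(zlib.crc32(key.encode())).normal())
            )
        v = np.asarray(vals)
        return PairScoreTable(pairs=list(pairs), raw=v.copy(), std=v, meta=None)


def _cheap_config(**kw) -> EMConfig:
    base = dict(
        n_subsets=2,
        window=2,
        max_e_iterations=4,
        max_cycles=1,
        ga=GAParams(population_size=6, generations=4),
        seed=5,
        specific_threshold=1.0,
    )
    base.update(kw)
    return EMConfig(**base)


class TestSchedule:
    def test_cc_reuses_bp_bits_as_frozen_surrogates(self):
        inputs = _two_namespace_inputs()
        prov = HashScoreProvider()
        results = run_full(
            inputs,
            _cheap_config(),
            namespaces=["BP", "CC"],
            providers={"BP": prov, "CC": prov},
        )
        bp_am, _ = results["BP"]
        cc_am, cc_state = results["CC"]
        assert bp_am is not None and cc_am is not None
        # the delivered CC matrix is pure CC
        assert all(cc_am.term_namespace[t] == "CC" for t in cc_am.term_ids)
        # the CC working matrix carried the BP bits, frozen
        full = cc_state.assignment
        bp_assigned = {
            (iso, t) for iso in bp_am.isoform_ids for t in bp_am.terms_of(iso)
        }
        frozen_cells = {
            (full.isoform_ids[i], full.term_ids[j])
            for i, j in zip(*np.nonzero(full.frozen_mask))
        }
        assert frozen_cells == bp_assigned
        for iso, t in bp_assigned:
            assert full.bits[full.iso_index[iso], full.term_index[t]] == 1

    def test_surrogates_off_keeps_cc_pure(self):
        inputs = _two_namespace_inputs()
        prov = HashScoreProvider()
        results = run_full(
            inputs,
            _cheap_config(use_bp_surrogates=False),
            namespaces=["BP", "CC"],
            providers={"BP": prov, "CC": prov},
        )
        _, cc_state = results["CC"]
        assert not cc_state.assignment.frozen_mask.any()
        assert all(
            cc_state.assignment.term_namespace[t] == "CC"
            for t in cc_state.assignment.term_ids
        )

    def test_missing_namespace_yields_none_and_empty_file(self, tmp_path):
        inputs = _two_namespace_inputs()  # no MF terms anywhere
        prov = HashScoreProvider()
        results = run_full(
            inputs,
            _cheap_config(),
            namespaces=["MF", "BP"],
            providers={"MF": prov, "BP": prov},
            out_dir=tmp_path,
        )
        assert results["MF"] == (None, None)
        assert results["BP"][0] is not None
        mf_out = tmp_path / "isoform_annotations_MF.tsv"
        assert mf_out.exists()
        from isofunc import io as iomod

        assert iomod.read_isoform_annotations(mf_out).empty
        assert (tmp_path / "isoform_annotations_BP.tsv").exists()
        assert (tmp_path / "sigma_trace_BP.tsv").exists()


class TestRunSubontology:
    def test_zero_cycles_returns_seed_assignment(self):
        inputs = _two_namespace_inputs()
        am, state = run_subontology(
            inputs, "BP", _cheap_config(max_cycles=0), provider=HashScoreProvider()
        )
        assert np.array_equal(am.bits, am.seed_mask)
        assert len(state.sigma_trace) == 1  # the sigma_0 baseline only

    def test_fixed_seed_bitwise_deterministic(self):
        inputs = _two_namespace_inputs()
        runs = []
        for _ in range(2):
            am, state = run_subontology(
                inputs, "BP", _cheap_config(), provider=HashScoreProvider()
            )
            runs.append((am.bits.copy(), list(state.sigma_trace), state.model))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]
        assert runs[0][2].coefficients == runs[1][2].coefficients

    def test_unknown_namespace(self):
        with pytest.raises(ValueError):
            run_subontology(_two_namespace_inputs(), "XX")


class TestAttachFrozen:
    def test_appends_and_freezes(self):
        inputs = _two_namespace_inputs()
        am, _ = run_subontology(
            inputs, "CC", _cheap_config(max_cycles=0), provider=HashScoreProvider()
        )
        before = shared_term_counts(am)
        frozen = [("T1", "GO:0000011"), ("T2", "GO:0000011")]
        out = _attach_frozen(am, frozen, inputs.term_namespaces)
        assert "GO:0000011" in out.term_index
        i1, i2 = out.iso_index["T1"], out.iso_index["T2"]
        j = out.term_index["GO:0000011"]
        assert out.bits[i1, j] == 1 and out.frozen_mask[i2, j] == 1
        assert not out.mutable_mask()[i1, j]
        after = shared_term_counts(out)
        assert after[i1, i2] == before[i1, i2] + 1
        # original untouched
        assert "GO:0000011" not in am.term_index


class TestCoverageReport:
    def test_uncovered_candidate_terms_listed(self, tiny_truth):
        am = tiny_truth.assignment.copy()
        report = coverage_report(am)
        # the planted truth satisfies coverage by construction
        assert report.empty
        # knock out one gene term everywhere
        gene = tiny_truth.genes[0]
        rows = [am.iso_index[iso] for iso in gene.isoform_ids]
        j = next(
            int(jj)
            for jj in np.flatnonzero(am.candidate_mask[rows[0]])
        )
        am.bits[rows, j] = 0
        report = coverage_report(am)
        assert (gene.gene_id, am.term_ids[j]) in set(
            map(tuple, report.itertuples(index=False))
        )
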