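"""Shared fixtures: planted synthetic corpora and alignment helpers."""

from __future__ import annotations

import numpy as np
import pytest

from isofunc.annotations import AssignmentMatrix
from isofunc.synthetic import PlantedScoreProvider, SyntheticTruth, simulate_universe


@pytest.fixture(scope="session")
def tiny_truth() -> SyntheticTruth:
    """20 genes x 4 isoforms, 30 terms, 3 terms/gene: the desk-scale corpus."""
    return simulate_universe(
        n_genes=20, isoforms_per_gene=4, n_terms=30, terms_per_gene=3,
        assign_prob=0.5, seed=11,
    )


@pytest.fixture()
def noiseless_provider(tiny_truth) -> PlantedScoreProvider:
    return PlantedScoreProvider(tiny_truth, noise_sd=0.0, seed=5)


def aligned_truth_bits(am: AssignmentMatrix, truth: SyntheticTruth) -> np.ndarray:
    """Planted truth bits re-indexed to another matrix's row/column order."""
    out = np.zeros(am.shape, dtype=np.uint8)
    for i, iso in enumerate(am.isoform_ids):
        ti = truth.assignment.iso_index[iso]
        for j, term in enumerate(am.term_ids):
            tj = truth.assignment.term_index.get(term)
            if tj is not None:
                out[i, j] = truth.assignment.bits[ti, tj]
    return out


def hamming_accuracy(am: AssignmentMatrix, truth: SyntheticTruth) -> float:
    """Fraction of candidate cells whose bit matches the planted truth."""
    tb = aligned_truth_bits(am, truth)
    mask = am.candidate_mask.astype(bool)
    return float((am.bits[mask] == tb[mask]).mean())


def seed_accuracy(am: AssignmentMatrix, truth: SyntheticTruth) -> float:
    tb = aligned_truth_bits(am, truth)
    mask = am.candidate_mask.astype(bool)
    return float((am.seed_mask[mask] == tb[mask]).mean())
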