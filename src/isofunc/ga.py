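"""Genetic-algorithm E-step: optimize the mutable assignment bits of one
mini-batch subset for fixed regression coefficients.

Finding the assignment minimizing the sum of squared residuals is
NP-complete, so the E-step searches with a GA: rank-proportional selection,
uniform crossover (probability 0.8), per-bit mutation (probability 0.1) and
single-individual elitism, which makes the best fitness per generation
non-decreasing.  ``brute_force_min_ssr`` is the exhaustive oracle used to
certify the GA on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import AssignmentMatrix
from .emcore import QuadraticModel
from .errors import EnumerationGuardError


@dataclass(frozen=True)
class GAParams:
    population_size: int = 50
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_count: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class SubsetProblem:
    """One mini-batch subset as a fitness landscape over its mutable bits.

    The chromosome enumerates the subset's mutable (candidate, not frozen)
    cells: isoforms in sorted-id order, each contributing its candidate
    terms in GO-id order.  Frozen set bits contribute to shared-term counts
    but are not searchable.
    """

    def __init__(
        self,
        subset_ids: Sequence[str],
        pairs: Sequence[tuple[str, str]],
        std_scores: np.ndarray,
        assignment: AssignmentMatrix,
        model: QuadraticModel,
    ) -> None:
        self.subset_ids = sorted(subset_ids)
        self.pairs = list(pairs)
        self.std_scores = np.asarray(std_scores, dtype=float)
        if len(self.pairs) != self.std_scores.size:
            raise ValueError("one score per pair required")
        subset_set = set(self.subset_ids)
        for a, b in self.pairs:
            if a not in subset_set or b not in subset_set:
                raise ValueError(f"pair ({a}, {b}) outside the subset")
        self.assignment = assignment
        self.model = model
        self._build_layout()
        self._build_pair_terms()

    # -- chromosome layout ------------------------------------------------
    def _build_layout(self) -> None:
        am = self.assignment
        mutable = am.mutable_mask()
        go_order = np.argsort(np.asarray(am.term_ids, dtype=object), kind="stable")
        self.positions: list[tuple[int, int]] = []  # (row, col) in the matrix
        self._pos_by_cell: dict[tuple[int, int], int] = {}
        for iso in self.subset_ids:
            i = am.iso_index[iso]
            for j in go_order:
                if mutable[i, j]:
                    self._pos_by_cell[(i, int(j))] = len(self.positions)
                    self.positions.append((i, int(j)))
        # fixed bit value of every non-mutable cell (frozen or non-candidate)
        self._fixed_bits = (am.bits & ~mutable & 1).astype(np.uint8)

    @property
    def n_bits(self) -> int:
        return len(self.positions)

    def _build_pair_terms(self) -> None:
        """Per pair: constant tau from fixed bits, chromosome positions whose
        activation adds 1 (mutable-vs-fixed), and position pairs whose joint
        activation adds 1 (mutable-vs-mutable on the same term)."""
        am = self.assignment
        self._pair_const = np.zeros(len(self.pairs), dtype=np.int64)
        self._pair_lin: list[np.ndarray] = []
        self._pair_qa: list[np.ndarray] = []
        self._pair_qb: list[np.ndarray] = []
        mutable = am.mutable_mask()
        for p, (a, b) in enumerate(self.pairs):
            ia, ib = am.iso_index[a], am.iso_index[b]
            lin: list[int] = []
            qa: list[int] = []
            qb: list[int] = []
            const = 0
            cols = np.flatnonzero(
                (mutable[ia] | self._fixed_bits[ia])
                & (mutable[ib] | self._fixed_bits[ib])
            )
            for j in cols:
                j = int(j)
                ma, mb = bool(mutable[ia, j]), bool(mutable[ib, j])
                if ma and mb:
                    qa.append(self._pos_by_cell[(ia, j)])
                    qb.append(self._pos_by_cell[(ib, j)])
                elif ma and self._fixed_bits[ib, j]:
                    lin.append(self._pos_by_cell[(ia, j)])
                elif mb and self._fixed_bits[ia, j]:
                    lin.append(self._pos_by_cell[(ib, j)])
                elif self._fixed_bits[ia, j] and self._fixed_bits[ib, j]:
                    const += 1
            self._pair_const[p] = const
            self._pair_lin.append(np.asarray(lin, dtype=np.int64))
            self._pair_qa.append(np.asarray(qa, dtype=np.int64))
            self._pair_qb.append(np.asarray(qb, dtype=np.int64))

    # -- evaluation -------------------------------------------------------
    def taus_population(
        self, pop: np.ndarray, pair_indices: Sequence[int] | None = None
    ) -> np.ndarray:
        """Shared-term counts per pair for a (n_individuals, n_bits) population."""
        pop = np.atleast_2d(pop).astype(np.int64)
        n = pop.shape[0]
        which = range(len(self.pairs)) if pair_indices is None else pair_indices
        taus = np.empty((n, len(list(which))), dtype=np.int64)
        for col, p in enumerate(which):
            t = np.full(n, self._pair_const[p])
            if self._pair_lin[p].size:
                t = t + pop[:, self._pair_lin[p]].sum(axis=1)
            if self._pair_qa[p].size:
                t = t + (pop[:, self._pair_qa[p]] * pop[:, self._pair_qb[p]]).sum(axis=1)
            taus[:, col] = t
        return taus

    def ssr_population(self, pop: np.ndarray) -> np.ndarray:
        taus = self.taus_population(pop).astype(float)
        mu = self.model.predict(taus)
        resid = mu - self.std_scores[None, :]
        return np.einsum("ij,ij->i", resid, resid)

    def pair_positions(self, p: int) -> np.ndarray:
        """All chromosome positions the p-th pair's tau depends on."""
        return np.unique(
            np.concatenate([self._pair_lin[p], self._pair_qa[p], self._pair_qb[p]])
        )


def encode(assignment: AssignmentMatrix, problem: SubsetProblem) -> np.ndarray:
    """Current mutable bits of the subset as a chromosome."""
    bits = np.empty(problem.n_bits, dtype=np.uint8)
    for k, (i, j) in enumerate(problem.positions):
        bits[k] = assignment.bits[i, j]
    return bits


def decode(bits: np.ndarray, assignment: AssignmentMatrix, problem: SubsetProblem) -> None:
    """Write a chromosome back into the assignment matrix (in place)."""
    if bits.size != problem.n_bits:
        raise ValueError("chromosome length mismatch")
    for k, (i, j) in enumerate(problem.positions):
        assignment.bits[i, j] = bits[k]


def fitness(bits: np.ndarray, problem: SubsetProblem) -> float:
    """Negated subset SSR, so that maximizing fitness minimizes the residuals."""
    return -float(problem.ssr_population(np.atleast_2d(bits))[0])


@dataclass
class GAResult:
    bits: np.ndarray
    fitness: float
    trace: list[float] = field(default_factory=list)


def evolve(problem: SubsetProblem, params: GAParams, init: np.ndarray) -> GAResult:
    """Run the GA from the current assignment's encoding.

    The initial population is the current chromosome plus mutated copies;
    selection probability is proportional to fitness rank (1 = worst);
    uniform crossover with probability ``crossover_prob``; per-bit mutation
    afterwards; the elite individual survives unchanged each generation, so
    the elite fitness trace never decreases and the returned fitness is at
    least the initial one.
    """
    init = np.asarray(init, dtype=np.uint8)
    if init.size != problem.n_bits:
        raise ValueError("init chromosome length mismatch")
    if problem.n_bits == 0:
        f = -float(problem.ssr_population(np.zeros((1, 0)))[0])
        return GAResult(bits=init.copy(), fitness=f, trace=[f])

    rng = np.random.default_rng(params.seed)
    P, k = params.population_size, problem.n_bits
    pop = np.tile(init, (P, 1))
    flips = rng.random((P - 1, k)) < params.mutation_prob
    pop[1:] ^= flips.astype(np.uint8)

    trace: list[float] = []
    for _ in range(params.generations):
        fit = -problem.ssr_population(pop)
        elite_idx = int(np.argmax(fit))
        trace.append(float(fit[elite_idx]))
        # rank-proportional selection: worst gets rank 1
        order = np.argsort(fit, kind="stable")
        ranks = np.empty(P, dtype=float)
        ranks[order] = np.arange(1, P + 1)
        probs = ranks / ranks.sum()
        p1 = rng.choice(P, size=P - 1, p=probs)
        p2 = rng.choice(P, size=P - 1, p=probs)
        children = pop[p1].copy()
        crossed = rng.random(P - 1) < params.crossover_prob
        if k > 0 and crossed.any():
            take_b = rng.integers(0, 2, size=(P - 1, k)).astype(bool)
            mixed = np.where(take_b, pop[p2], pop[p1])
            children[crossed] = mixed[crossed]
        flips = rng.random((P - 1, k)) < params.mutation_prob
        children ^= flips.astype(np.uint8)
        pop = np.vstack([pop[elite_idx][None, :], children])

    fit = -problem.ssr_population(pop)
    elite_idx = int(np.argmax(fit))
    trace.append(float(fit[elite_idx]))
    return GAResult(bits=pop[elite_idx].copy(), fitness=float(fit[elite_idx]), trace=trace)


def brute_force_min_ssr(
    problem: SubsetProblem, max_bits: int = 20
) -> tuple[np.ndarray, float]:
    """Exhaustive global minimum of the subset SSR (the E-step oracle).

    Enumerates every assignment of the mutable bits; ties resolve to the
    lexicographically smallest chromosome.  Because the SSR is additive
    over pairs and every pair's positions lie in one connected component of
    the position-coupling graph, enumeration proceeds per component (the
    result is identical to flat 2^k enumeration); components larger than
    ``max_bits`` raise :class:`EnumerationGuardError`.  Positions no pair
    depends on are set to 0 by the tie-break.
    """
    k = problem.n_bits
    best = np.zeros(k, dtype=np.uint8)
    # union-find over positions
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    pair_root: list[int | None] = []
    for p in range(len(problem.pairs)):
        pos = problem.pair_positions(p)
        for a, b in zip(pos[:-1], pos[1:]):
            union(int(a), int(b))
        pair_root.append(int(find(int(pos[0]))) if pos.size else None)
    # correct roots after all unions
    pair_root = [find(r) if r is not None else None for r in pair_root]

    components: dict[int, list[int]] = {}
    for pos in range(k):
        components.setdefault(find(pos), []).append(pos)

    total = 0.0
    # pairs untouched by any mutable bit contribute a fixed residual
    free_pairs = [p for p, r in enumerate(pair_root) if r is None]
    if free_pairs:
        taus = problem.taus_population(np.zeros((1, k), dtype=np.uint8), free_pairs)[0]
        for t, p in zip(taus, free_pairs):
            resid = problem.model.predict(float(t)) - problem.std_scores[p]
            total += float(resid) ** 2

    for root, members in sorted(components.items()):
        comp_pairs = [p for p, r in enumerate(pair_root) if r == root]
        if not comp_pairs:
            continue  # untouched positions stay 0
        members = sorted(members)
        c = len(members)
        if c > max_bits:
            raise EnumerationGuardError(
                f"component of {c} mutable bits exceeds the {max_bits}-bit "
                "enumeration budget"
            )
        n = 1 << c
        # row r encodes the chromosome whose members read as r's binary
        # digits, most-significant first: ascending r is lexicographic order
        shifts = np.arange(c - 1, -1, -1)
        combos = ((np.arange(n)[:, None] >> shifts) & 1).astype(np.uint8)
        pop = np.zeros((n, k), dtype=np.uint8)
        pop[:, members] = combos
        ssr_vals = np.zeros(n)
        taus = problem.taus_population(pop, comp_pairs).astype(float)
        for col, p in enumerate(comp_pairs):
            resid = problem.model.predict(taus[:, col]) - problem.std_scores[p]
            ssr_vals += resid**2
        idx = int(np.argmin(ssr_vals))  # first minimum = lexicographically smallest
        best[members] = combos[idx]
        total += float(ssr_vals[idx])

    return best, total
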