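"""Quadratic similarity model, Gaussian likelihood and the M-step fit.

The standardized similarity of an isoform pair is modelled as a quadratic
function of the number of GO terms the pair shares (tau):

    S ~ N(beta2*tau^2 + beta1*tau + beta0, 1)

with the noise standard deviation fixed at 1.  Maximizing the Gaussian
log-likelihood over the coefficients is ordinary least squares on the
design [1, tau, tau^2]; maximizing over the assignments (the E-step,
handled elsewhere) minimizes the same sum of squared residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .alignment import PairScoreTable
from .errors import DegenerateDataError, RankDeficiencyError

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class QuadraticModel:
    """Coefficients of the shared-term -> similarity regression."""

    beta0: float
    beta1: float
    beta2: float
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd != 1.0:
            raise ValueError("the noise standard deviation is fixed at 1")
        for b in (self.beta0, self.beta1, self.beta2):
            if not np.isfinite(b):
                raise ValueError("non-finite coefficient")

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.beta0, self.beta1, self.beta2)

    def predict(self, tau: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(tau, dtype=float)
        out = self.beta2 * t * t + self.beta1 * t + self.beta0
        return float(out) if np.isscalar(tau) or out.ndim == 0 else out

    def rel_change(self, other: "QuadraticModel") -> float:
        """max |delta beta| / (1 + |beta|), the outer-loop stopping metric."""
        return max(
            abs(a - b) / (1.0 + abs(b))
            for a, b in zip(self.coefficients, other.coefficients)
        )


def predict_similarity(tau: np.ndarray | float, model: QuadraticModel):
    """Model mean similarity for a shared-term count (Eq: beta2*t^2+beta1*t+beta0)."""
    return model.predict(tau)


def _scores_of(pairs: PairScoreTable | np.ndarray | Sequence[float]) -> np.ndarray:
    if isinstance(pairs, PairScoreTable):
        return pairs.std
    return np.asarray(pairs, dtype=float)


def ssr(
    pairs: PairScoreTable | Sequence[float],
    taus: Sequence[int] | np.ndarray,
    model: QuadraticModel,
) -> float:
    """Sum of squared residuals between observed and predicted similarity."""
    s = _scores_of(pairs)
    t = np.asarray(taus, dtype=float)
    if s.shape != t.shape:
        raise ValueError("taus must align one-to-one with pairs")
    resid = model.predict(t) - s
    return float(np.dot(resid, resid))


def log_likelihood(
    pairs: PairScoreTable | Sequence[float],
    taus: Sequence[int] | np.ndarray,
    model: QuadraticModel,
) -> tuple[float, int]:
    """Total Gaussian log-likelihood and the number of pair terms in it.

    total = -SSR/2 - n*log(2*pi)/2 under unit noise variance.  The pair
    count is the lambda* divisor of the mini-batch mean log-likelihood.
    """
    s = _scores_of(pairs)
    n = int(s.size)
    if n == 0:
        return 0.0, 0
    return -ssr(pairs, taus, model) / 2.0 - n * LOG_2PI / 2.0, n


def fit_quadratic(
    pairs: PairScoreTable | Sequence[float], taus: Sequence[int] | np.ndarray
) -> QuadraticModel:
    """Ordinary least squares of similarity on [1, tau, tau^2].

    Needs at least three distinct shared-term counts; otherwise raises
    :class:`RankDeficiencyError` and the caller should keep its previous
    coefficients (or resample, during initialization).
    """
    s = _scores_of(pairs)
    t = np.asarray(taus, dtype=float)
    if s.shape != t.shape:
        raise ValueError("taus must align one-to-one with pairs")
    if s.size < 3 or np.unique(t).size < 3:
        raise RankDeficiencyError(
            f"need >=3 pairs spanning >=3 distinct shared-term counts "
            f"(got {s.size} pairs, {np.unique(t).size} distinct); "
            "fall back to the previous coefficients"
        )
    design = np.column_stack([np.ones_like(t), t, t * t])
    coef, _, rank, _ = np.linalg.lstsq(design, s, rcond=None)
    if rank < 3:
        raise RankDeficiencyError(
            "rank-deficient design; fall back to the previous coefficients"
        )
    return QuadraticModel(beta0=float(coef[0]), beta1=float(coef[1]), beta2=float(coef[2]))


def initialize_beta(
    isoform_ids: Sequence[str],
    subset_size: int,
    pair_builder: Callable[[list[str]], list[tuple[str, str]]],
    scorer: Callable[[list[tuple[str, str]]], PairScoreTable],
    tau_of_pairs: Callable[[Sequence[tuple[str, str]]], np.ndarray],
    seed: int,
    max_attempts: int = 10,
) -> tuple[QuadraticModel, int]:
    """Initial coefficient guess from one random isoform subset.

    Samples ``subset_size`` isoforms, builds their eligible pairs, scores
    them and fits the quadratic against the seed assignment's shared-term
    counts.  A rank-deficient draw is resampled with the next seed (up to
    ``max_attempts``).  If the seed assignment never spans three distinct
    shared-term counts — common when domain seeding is sparse — the guess
    degrades gracefully to a linear or constant fit (higher coefficients
    zero); the first M-step replaces it anyway.  Returns the model and the
    seed that produced it.
    """
    ids = list(isoform_ids)
    size = min(max(subset_size, 1), len(ids))
    last_exc: Exception | None = None
    fallback: tuple[np.ndarray, np.ndarray, int] | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        subset = sorted(rng.choice(ids, size=size, replace=False).tolist())
        try:
            pairs = pair_builder(subset)
            if not pairs:
                raise DegenerateDataError("initialization subset has no pairs")
            table = scorer(pairs)
            taus = np.asarray(tau_of_pairs(table.pairs))
            try:
                return fit_quadratic(table, taus), seed + attempt
            except RankDeficiencyError:
                if fallback is None or np.unique(taus).size > np.unique(fallback[1]).size:
                    fallback = (_scores_of(table), taus, seed + attempt)
                raise
        except (RankDeficiencyError, DegenerateDataError) as exc:
            last_exc = exc
    if fallback is not None:
        s, t, used = fallback
        degree = min(2, int(np.unique(t).size) - 1)
        coef = np.zeros(3)
        coef[: degree + 1] = np.polyfit(t.astype(float), s, degree)[::-1]
        return QuadraticModel(beta0=float(coef[0]), beta1=float(coef[1]),
                              beta2=float(coef[2])), used
    raise DegenerateDataError(
        f"could not initialize coefficients after {max_attempts} subset draws"
    ) from last_exc


def normality_diagnostic(
    pairs: PairScoreTable | Sequence[float],
    taus: Sequence[int] | np.ndarray,
    model: QuadraticModel,
    alpha: float = 0.01,
):
    """One-sample Kolmogorov-Smirnov check of residuals against N(0, 1).

    Purely diagnostic: the unit-variance Gaussian noise assumption is never
    re-estimated and never gates a run.  Returns the scipy KS result.
    """
    s = _scores_of(pairs)
    resid = s - model.predict(np.asarray(taus, dtype=float))
    result = stats.kstest(resid, "norm")
    result.reject_at_alpha = bool(result.pvalue < alpha)  # type: ignore[attr-defined]
    return result
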