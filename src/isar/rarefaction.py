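"""Individual-based rarefaction, extrapolation, and Chao1 richness estimation.

Interpolated richness is the exact hypergeometric expectation

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)],

the mean number of species in a random subsample of ``n`` of the ``N``
individuals, computed with log-binomial arithmetic for stability.  Beyond
the observed sample size the curve is extended with the Chao1-conditional
extrapolator, which tends to the Chao1 asymptote

    S_chao1 = S_obs + F1^2 / (2 F2),

where F1 and F2 are the numbers of singleton and doubleton species.
"""
from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_model import AbundanceVector
from .errors import DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SADSummary:
    """Totals underlying Chao1 and extrapolation: N, S_obs, F1, F2."""

    n: int
    s_obs: int
    f1: int
    f2: int

    def __post_init__(self) -> None:
        if min(self.n, self.s_obs, self.f1, self.f2) < 0:
            raise DomainError("SADSummary fields must be non-negative")
        if self.f1 + 2 * self.f2 > self.n or self.f1 + self.f2 > self.s_obs:
            raise DomainError("inconsistent singleton/doubleton counts")


@dataclass(frozen=True)
class RarefactionBase:
    """The reference-n recipe: n_ref = max(n_max, 2 * n_min)."""

    n_max: int
    n_min: int
    n_b: int
    n_ref: int


@dataclass(frozen=True)
class RichnessEstimate:
    """Expected species count at a target sample size ``n``.

    ``mode`` records whether the value is interpolated (n < N), observed
    (n = N) or extrapolated (n > N); ``extrapolation_ratio`` is n / N.
    """

    value: float
    n: int
    mode: str
    extrapolation_ratio: float


def sad_summary(community: AbundanceVector) -> SADSummary:
    """Count N, S_obs, singletons, and doubletons for one community."""
    if not community:
        raise DomainError("sad_summary requires a non-empty community")
    counts = community.counts
    return SADSummary(
        n=int(counts.sum()),
        s_obs=int(counts.size),
        f1=int((counts == 1).sum()),
        f2=int((counts == 2).sum()),
    )


def chao1(summary: SADSummary) -> float:
    """Chao1 lower-bound estimate of total richness.

    Uses the classic S_obs + F1²/(2 F2) when doubletons are present, and the
    bias-corrected S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0, keeping
    the estimator finite on all samples.
    """
    if summary.s_obs < 1:
        raise DomainError("chao1 requires at least one observed species")
    if summary.f2 > 0:
        return summary.s_obs + summary.f1 ** 2 / (2.0 * summary.f2)
    return summary.s_obs + summary.f1 * (summary.f1 - 1) / 2.0


def reference_n(island_totals: list[int]) -> RarefactionBase:
    """Common reference sample size: max(largest total, 2 x smallest total)."""
    if not island_totals:
        raise DomainError("reference_n requires at least one sample total")
    if min(island_totals) < 1:
        raise DomainError("sample totals must be >= 1")
    n_max = int(max(island_totals))
    n_min = int(min(island_totals))
    n_b = 2 * n_min
    return RarefactionBase(n_max=n_max, n_min=n_min, n_b=n_b,
                           n_ref=max(n_max, n_b))


def _log_choose(a: np.ndarray | float, b: float) -> np.ndarray:
    return gammaln(np.asarray(a) + 1.0) - gammaln(b + 1.0) - gammaln(np.asarray(a) - b + 1.0)


def interpolated_richness(community: AbundanceVector, n: int) -> RichnessEstimate:
    """Exact expected richness of a random subsample of ``n`` individuals."""
    if not community:
        raise DomainError("interpolated_richness requires a non-empty community")
    counts = community.counts
    total = int(counts.sum())
    if not 1 <= n <= total:
        raise DomainError(f"n must be in [1, N={total}], got {n}")
    remaining = total - counts  # individuals not of species i
    feasible = remaining >= n
    terms = np.zeros(counts.size)
    if feasible.any():
        terms[feasible] = np.exp(
            _log_choose(remaining[feasible], n) - _log_choose(total, n)
        )
    value = float(counts.size - terms.sum())
    mode = "observed" if n == total else "interpolated"
    return RichnessEstimate(value=value, n=n, mode=mode,
                            extrapolation_ratio=n / total)


def extrapolated_richness(community: AbundanceVector, n: int) -> RichnessEstimate:
    """Chao1-conditional extrapolation of the rarefaction curve to ``n`` > N.

    S(N + m) = S_obs + f0 * [1 - (1 - F1 / (N f0 + F1))^m] with
    f0 = chao1 - S_obs; without singletons the curve is flat at S_obs.
    """
    summary = sad_summary(community)
    if n <= summary.n:
        raise DomainError(
            f"extrapolation requires n > N={summary.n}; use interpolated_richness"
        )
    m = n - summary.n
    f0 = chao1(summary) - summary.s_obs
    if summary.f1 == 0 or f0 <= 0:
        value = float(summary.s_obs)
    else:
        ratio = summary.f1 / (summary.n * f0 + summary.f1)
        value = summary.s_obs + f0 * (1.0 - (1.0 - ratio) ** m)
    return RichnessEstimate(value=value, n=n, mode="extrapolated",
                            extrapolation_ratio=n / summary.n)


def expected_richness(community: AbundanceVector, n: int) -> RichnessEstimate:
    """Expected richness at any n >= 1, interpolating or extrapolating as needed."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    total = community.n_individuals
    if total and n > 2 * total:
        logger.warning(
            "extrapolating to n=%d, %.1fx the observed N=%d; reliability "
            "degrades beyond 2N", n, n / total, total,
        )
    if n <= total:
        return interpolated_richness(community, n)
    return extrapolated_richness(community, n)


def rarefaction_curve(community: AbundanceVector, n_max: int | None = None) -> np.ndarray:
    """Expected richness at every n in [1, n_max] (defaults to the observed N)."""
    total = community.n_individuals
    n_max = total if n_max is None else n_max
    return np.array([expected_richness(community, n).value
                     for n in range(1, n_max + 1)])
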