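"""Probability of interspecific encounter (PIE) and its effective species number.

PIE (Hurlbert) is the probability that two individuals drawn without
replacement belong to different species:

    PIE = N / (N - 1) * (1 - sum_i p_i^2),    p_i = N_i / N.

S_PIE = 1 / (1 - PIE) converts PIE to an effective number of species; it is
dominated by the common species and insensitive to rare ones.  When every
individual is a distinct species PIE = 1 and S_PIE diverges; such samples
are flagged undefined rather than clamped.
"""
from __future__ import annotations

import logging

from dataclasses import dataclass

from .data_model import AbundanceVector
from .errors import DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvennessEstimate:
    pie: float
    s_pie: float | None  # None iff pie == 1 (all-singleton sample)

    @property
    def defined(self) -> bool:
        return self.s_pie is not None


def pie(community: AbundanceVector) -> float:
    """Hurlbert's PIE for one community; requires at least two individuals."""
    total = community.n_individuals
    if total < 2:
        raise DomainError(f"PIE requires N >= 2, got N={total}")
    counts = community.counts
    if counts.max() == 1:
        return 1.0  # all singletons: every pair is interspecific, exactly
    p = counts / total
    return total / (total - 1.0) * (1.0 - float(p @ p))


def s_pie(community: AbundanceVector) -> EvennessEstimate:
    """Effective number of species 1 / (1 - PIE); undefined when PIE = 1."""
    value = pie(community)
    if value >= 1.0:
        logger.warning(
            "all-singleton sample (N=%d): S_PIE undefined; sample excluded "
            "from S_PIE analyses", community.n_individuals,
        )
        return EvennessEstimate(pie=1.0, s_pie=None)
    return EvennessEstimate(pie=value, s_pie=1.0 / (1.0 - value))
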