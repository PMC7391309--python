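"""Within-island beta-diversity from plot-level data.

For taxa surveyed with bounded quadrats, island-scale (gamma) diversity can
be partitioned against the mean plot-scale (alpha) diversity.  Both scales
are standardized to a common number of individuals n_alpha, and

    beta = gamma / alpha

indexes how strongly species are clumped across an island's plots: beta = 1
when plots are random draws from the island community, beta > 1 when
composition varies among plots.  Regressing beta against island area asks
whether within-island compositional heterogeneity contributes to the ISAR.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import PlotSample, pool_plots
from .errors import DomainError
from .evenness import s_pie
from .inference import RegressionFit, fit_loglog
from .rarefaction import expected_richness, reference_n

logger = logging.getLogger(__name__)

#: plots with fewer individuals than this are excluded from beta computation
DEFAULT_MIN_PLOT_N = 2


@dataclass(frozen=True)
class BetaProfile:
    """Alpha/gamma/beta diversity components for one island."""

    island_id: str
    n_alpha: int
    alpha_sn: float
    gamma_sn: float
    beta_sn: float
    alpha_spie: float
    gamma_spie: float
    beta_spie: float
    plot_count: int


def _plots_by_island(plots: Sequence[PlotSample]) -> dict[str, list[PlotSample]]:
    grouped: dict[str, list[PlotSample]] = defaultdict(list)
    for p in plots:
        grouped[p.island_id].append(p)
    return grouped


def alpha_scale_n(
    plots: Sequence[PlotSample], min_plot_n: int = DEFAULT_MIN_PLOT_N
) -> int:
    """Plot-grain reference n: the reference-n recipe on per-plot totals.

    Totals are taken across every usable plot on islands with >= 2 usable
    plots, so alpha and gamma diversity are standardized to one common n
    for the whole taxon.
    """
    grouped = _plots_by_island(plots)
    totals: list[int] = []
    for island_plots in grouped.values():
        usable = [p.community.n_individuals for p in island_plots
                  if p.community.n_individuals >= min_plot_n]
        if len(usable) >= 2:
            totals.extend(usable)
    if not totals:
        raise DomainError("no island has >= 2 usable plots")
    return reference_n(totals).n_ref


def beta_profile(
    plots: Sequence[PlotSample],
    island_id: str,
    n_alpha: int,
    min_plot_n: int = DEFAULT_MIN_PLOT_N,
) -> BetaProfile:
    """Alpha, gamma and beta diversity for one island at sample size n_alpha.

    alpha_sn is the arithmetic mean over plots of the expected richness of
    n_alpha individuals; gamma_sn is the same expectation on the pooled
    island sample.  The identical ratio is formed for S_PIE.  Plots with
    fewer than ``min_plot_n`` individuals are dropped with a warning;
    all-singleton plots are additionally dropped from the S_PIE average.
    """
    mine = [p for p in plots if p.island_id == island_id]
    if not mine:
        raise KeyError(f"no plots for island {island_id!r}")
    usable = []
    for p in mine:
        if p.community.n_individuals < min_plot_n:
            logger.warning(
                "island %r plot %r has N=%d < %d; excluded from beta",
                island_id, p.plot_id, p.community.n_individuals, min_plot_n,
            )
        else:
            usable.append(p)
    if len(usable) < 2:
        raise DomainError(
            f"island {island_id!r} has {len(usable)} usable plot(s); need >= 2"
        )
    pooled = pool_plots(usable, island_id)

    alpha_sn = float(np.mean([expected_richness(p.community, n_alpha).value
                              for p in usable]))
    gamma_sn = expected_richness(pooled, n_alpha).value

    plot_spies = []
    for p in usable:
        est = s_pie(p.community)
        if est.defined:
            plot_spies.append(est.s_pie)
        else:
            logger.warning(
                "island %r plot %r is all singletons; excluded from S_PIE "
                "averaging", island_id, p.plot_id,
            )
    gamma_est = s_pie(pooled)
    alpha_spie = float(np.mean(plot_spies)) if plot_spies else np.nan
    gamma_spie = gamma_est.s_pie if gamma_est.defined else np.nan

    return BetaProfile(
        island_id=island_id,
        n_alpha=n_alpha,
        alpha_sn=alpha_sn,
        gamma_sn=gamma_sn,
        beta_sn=gamma_sn / alpha_sn,
        alpha_spie=alpha_spie,
        gamma_spie=gamma_spie,
        beta_spie=gamma_spie / alpha_spie,
        plot_count=len(usable),
    )


def beta_profiles(
    plots: Sequence[PlotSample],
    min_plot_n: int = DEFAULT_MIN_PLOT_N,
) -> list[BetaProfile]:
    """BetaProfile for every island with >= 2 usable plots."""
    n_alpha = alpha_scale_n(plots, min_plot_n=min_plot_n)
    profiles = []
    for island_id in sorted(_plots_by_island(plots)):
        try:
            profiles.append(
                beta_profile(plots, island_id, n_alpha, min_plot_n=min_plot_n)
            )
        except DomainError as exc:
            logger.warning("island %r excluded from beta analysis: %s",
                           island_id, exc)
    return profiles


def beta_area_regression(
    profiles: Sequence[BetaProfile], areas: Sequence[float]
) -> dict[str, RegressionFit]:
    """Log-log regressions of beta_sn and beta_spie against island area."""
    if len(profiles) != len(areas):
        raise DomainError("profiles and areas must have equal length")
    area_arr = np.asarray(areas, dtype=float)
    return {
        "beta_sn": fit_loglog(area_arr, [p.beta_sn for p in profiles]),
        "beta_spie": fit_loglog(area_arr, [p.beta_spie for p in profiles]),
    }
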