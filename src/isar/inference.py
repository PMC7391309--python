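"""Log-log diversity-area regressions and the ISAR mechanism decision logic.

Each diversity metric y is regressed as ln y = ln C + z ln A on island area
A (natural logs, unweighted OLS), the classic power-law species-area model
S = C A^z.  The slope tests then dissect the mechanism behind a positive
ISAR:

* rarefied richness S_n flat in area  -> passive sampling not rejected;
* S_n increasing but S_PIE flat       -> only the rarer species respond
  disproportionately to island area;
* S_n and S_PIE both increasing       -> common and rare species both
  respond (the whole abundance distribution shifts);
* a positive within-island beta-diversity slope additionally implicates
  within-island compositional heterogeneity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import ArchipelagoDataset
from .errors import InferenceError
from .evenness import s_pie
from .rarefaction import chao1, expected_richness, reference_n, sad_summary

logger = logging.getLogger(__name__)

MIN_ISLANDS = 3

VERDICTS = (
    "passive_sampling_not_rejected",
    "disproportionate_rare",
    "disproportionate_common_and_rare",
)


@dataclass(frozen=True)
class RegressionFit:
    """One row of the regression table: ln(metric) ~ ln(area)."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r2: float
    r2_adj: float
    p_slope: float
    n_points: int


@dataclass(frozen=True)
class MechanismVerdict:
    """Outcome of the decision logic at a given significance level."""

    verdict: str
    alpha_level: float
    heterogeneity_implicated: bool | None
    supporting_fits: dict = field(default_factory=dict)


def fit_loglog(areas: Sequence[float], metric: Sequence[float]) -> RegressionFit:
    """Unweighted OLS of ln(metric) on ln(area).

    Pairs with a missing or non-positive metric value (e.g. islands whose
    S_PIE is undefined) are dropped pairwise with a logged count.  The
    adjusted R² is reported as computed and may be negative.
    """
    x = np.asarray(areas, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape:
        raise InferenceError("areas and metric must have equal length")
    usable = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    dropped = int((~usable).sum())
    if dropped:
        logger.info("fit_loglog: dropped %d island(s) with undefined metric", dropped)
    x, y = x[usable], y[usable]
    if x.size < MIN_ISLANDS:
        raise InferenceError(
            f"need >= {MIN_ISLANDS} usable islands for a regression, have {x.size}"
        )
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise InferenceError("zero variance in ln(area); slope not identifiable")
    model = sm.OLS(np.log(y), sm.add_constant(lx)).fit()
    return RegressionFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        se_intercept=float(model.bse[0]),
        se_slope=float(model.bse[1]),
        r2=float(model.rsquared),
        r2_adj=float(model.rsquared_adj),
        p_slope=float(model.pvalues[1]),
        n_points=int(x.size),
    )


def island_diversity_table(dataset: ArchipelagoDataset) -> pd.DataFrame:
    """Per-island S_total (Chao1), S_n at the taxon's n_ref, and S_PIE.

    Empty islands are excluded (logged); islands whose S_PIE is undefined
    (all-singleton samples) get NaN in the s_pie column.  The extrapolation
    mode and ratio for S_n are recorded per island.
    """
    islands = dataset.nonempty_islands()
    if not islands:
        raise InferenceError("dataset has no non-empty islands")
    totals = [isl.community.n_individuals for isl in islands]
    base = reference_n(totals)
    rows = []
    for isl in islands:
        summary = sad_summary(isl.community)
        s_n = expected_richness(isl.community, base.n_ref)
        if summary.n >= 2:
            ev = s_pie(isl.community)
            pie_val, spie_val = ev.pie, ev.s_pie
        else:
            logger.warning("island %r has N=1; S_PIE undefined", isl.island_id)
            pie_val, spie_val = np.nan, None
        rows.append(
            {
                "island_id": isl.island_id,
                "area_km2": isl.area_km2,
                "n_individuals": summary.n,
                "s_obs": summary.s_obs,
                "s_total": chao1(summary),
                "n_ref": base.n_ref,
                "s_n": s_n.value,
                "s_n_mode": s_n.mode,
                "extrapolation_ratio": s_n.extrapolation_ratio,
                "pie": pie_val,
                "s_pie": np.nan if spie_val is None else spie_val,
            }
        )
    return pd.DataFrame(rows)


def isar_table(dataset: ArchipelagoDataset) -> dict[str, RegressionFit]:
    """Fit the three diversity-area regressions (S_total, S_n, S_PIE)."""
    table = island_diversity_table(dataset)
    if len(table) < MIN_ISLANDS:
        raise InferenceError(
            f"need >= {MIN_ISLANDS} non-empty islands, have {len(table)}"
        )
    areas = table["area_km2"].to_numpy()
    return {
        "s_total": fit_loglog(areas, table["s_total"].to_numpy()),
        "s_n": fit_loglog(areas, table["s_n"].to_numpy()),
        "s_pie": fit_loglog(areas, table["s_pie"].to_numpy()),
    }


def regression_table(
    fits: Mapping[str, RegressionFit], taxon: str = ""
) -> pd.DataFrame:
    """Regression summary table: one row per response metric."""
    rows = []
    for response, fit in fits.items():
        rows.append(
            {
                "taxon": taxon,
                "response": response,
                "intercept": fit.intercept,
                "se_intercept": fit.se_intercept,
                "slope": fit.slope,
                "se_slope": fit.se_slope,
                "r2_adj": fit.r2_adj,
                "p_slope": fit.p_slope,
                "n_islands": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def _significant_positive(fit: RegressionFit, alpha: float) -> bool:
    return fit.p_slope <= alpha and fit.slope > 0


def classify_mechanism(
    fits: Mapping[str, RegressionFit],
    beta_fits: Mapping[str, RegressionFit] | None = None,
    alpha_level: float = 0.05,
) -> MechanismVerdict:
    """Map regression outcomes to an ISAR mechanism verdict.

    ``fits`` must contain RegressionFits keyed ``s_total``, ``s_n`` and
    ``s_pie``; ``beta_fits`` optionally carries ``beta_sn`` and
    ``beta_spie``.  The verdict is a pure function of slope signs and
    p-values at ``alpha_level``.
    """
    if not 0 < alpha_level < 1:
        raise InferenceError(f"alpha_level must be in (0, 1), got {alpha_level}")
    for key in ("s_total", "s_n", "s_pie"):
        if key not in fits or fits[key] is None:
            raise InferenceError(f"missing regression fit for {key!r}")
    s_n_up = _significant_positive(fits["s_n"], alpha_level)
    s_pie_up = _significant_positive(fits["s_pie"], alpha_level)
    if not s_n_up:
        verdict = "passive_sampling_not_rejected"
    elif s_pie_up:
        verdict = "disproportionate_common_and_rare"
    else:
        verdict = "disproportionate_rare"
    heterogeneity: bool | None = None
    if beta_fits is not None:
        heterogeneity = any(
            _significant_positive(beta_fits[k], alpha_level)
            for k in ("beta_sn", "beta_spie")
            if beta_fits.get(k) is not None
        )
    supporting = dict(fits)
    if beta_fits:
        supporting.update(beta_fits)
    return MechanismVerdict(
        verdict=verdict,
        alpha_level=alpha_level,
        heterogeneity_implicated=heterogeneity,
        supporting_fits=supporting,
    )
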