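import itertools

import numpy as np
import pytest

from isar import (
    AbundanceVector,
    ArchipelagoDataset,
    IslandSample,
    classify_mechanism,
    extrapolated_richness,
    fit_loglog,
    island_diversity_table,
    isar_table,
    regression_table,
)
from isar.errors import InferenceError
from isar.inference import RegressionFit


def _island(iid, area, entries):
    return IslandSample(iid, area, AbundanceVector(entries))


def _fit(slope, p):
    return RegressionFit(
        intercept=0.0, slope=slope, se_intercept=0.1, se_slope=0.1,
        r2=0.5, r2_adj=0.4, p_slope=p, n_points=10,
    )


class TestFitLogLog:
    def test_exact_power_law_recovered(self):
        areas = np.array([1.0, 3.0, 10.0, 50.0, 400.0])
        fit = fit_loglog(areas, 2.0 * areas ** 0.25)
        assert fit.slope == pytest.approx(0.25, abs=1e-9)
        assert fit.intercept == pytest.approx(np.log(2.0), abs=1e-9)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert fit.p_slope < 1e-6

    def test_constant_metric_flat_and_unexplained(self):
        areas = np.logspace(-1, 3, 10)
        fit = fit_loglog(areas, np.full(10, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.r2_adj <= 0.0

    def test_matches_hand_ols_formulas(self):
        """Cross-check against closed-form OLS computed from scratch."""
        rng = np.random.default_rng(3)
        areas = np.exp(rng.uniform(0, 5, 12))
        y = np.exp(0.7 + 0.2 * np.log(areas) + rng.normal(0, 0.3, 12))
        fit = fit_loglog(areas, y)
        x, ly = np.log(areas), np.log(y)
        n = x.size
        b = np.sum((x - x.mean()) * (ly - ly.mean())) / np.sum((x - x.mean()) ** 2)
        a = ly.mean() - b * x.mean()
        resid = ly - (a + b * x)
        s2 = resid @ resid / (n - 2)
        se_b = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        ss_tot = np.sum((ly - ly.mean()) ** 2)
        r2 = 1 - resid @ resid / ss_tot
        r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        assert fit.slope == pytest.approx(b, rel=1e-10)
        assert fit.intercept == pytest.approx(a, rel=1e-10)
        assert fit.se_slope == pytest.approx(se_b, rel=1e-9)
        assert fit.r2_adj == pytest.approx(r2_adj, rel=1e-9)

    def test_negative_adjusted_r2_reported_unclamped(self):
        # a null predictor on noisy data: adjusted R2 must go negative
        rng = np.random.default_rng(0)
        areas = np.logspace(0, 2, 12)
        y = np.exp(rng.normal(1.0, 0.2, 12))
        fit = fit_loglog(areas, y)
        assert fit.r2_adj < 0

    def test_undefined_metrics_dropped_pairwise(self):
        areas = [1.0, 10.0, 100.0, 1000.0]
        fit = fit_loglog(areas, [2.0, np.nan, 2.0, 2.0])
        assert fit.n_points == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(InferenceError):
            fit_loglog([1.0, 10.0], [1.0, 2.0])

    def test_degenerate_areas_rejected(self):
        with pytest.raises(InferenceError):
            fit_loglog([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_slope_coverage_on_noisy_power_law(self):
        """Slope estimate falls within 2 SE of truth ~95% of the time."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 300
        for _ in range(reps):
            areas = np.exp(rng.uniform(-2, 7, 20))
            y = np.exp(1.0 + 0.25 * np.log(areas) + rng.normal(0, 0.2, 20))
            fit = fit_loglog(areas, y)
            hits += abs(fit.slope - 0.25) <= 2 * fit.se_slope
        assert hits / reps >= 0.90


class TestIslandDiversityTable:
    def test_single_island_chains_the_worked_examples(self, mixed_community):
        ds = ArchipelagoDataset(
            taxon="t",
            islands=[IslandSample("A", 3.0, mixed_community)],
        )
        table = island_diversity_table(ds)
        row = table.iloc[0]
        assert row["n_ref"] == 14  # sole island: max(7, 2*7)
        assert row["s_total"] == pytest.approx(6.0)
        assert row["s_n"] == pytest.approx(
            extrapolated_richness(mixed_community, 14).value
        )
        assert row["s_n_mode"] == "extrapolated"
        assert np.isfinite(row["s_pie"])

    def test_monoculture_island(self):
        ds = ArchipelagoDataset(
            taxon="t", islands=[_island("A", 1.0, {"x": 9})]
        )
        row = island_diversity_table(ds).iloc[0]
        assert row["s_total"] == 1.0
        assert row["s_pie"] == pytest.approx(1.0)

    def test_identical_islands_identical_rows(self):
        entries = {"x": 4, "y": 2, "z": 1}
        ds = ArchipelagoDataset(
            taxon="t",
            islands=[_island("A", 1.0, entries), _island("B", 50.0, entries)],
        )
        table = island_diversity_table(ds).drop(columns=["island_id", "area_km2"])
        assert table.iloc[0].equals(table.iloc[1])

    def test_all_singleton_island_gets_nan_spie(self):
        ds = ArchipelagoDataset(
            taxon="t",
            islands=[
                _island("A", 1.0, {"x": 1, "y": 1}),
                _island("B", 2.0, {"x": 3, "y": 2}),
            ],
        )
        table = island_diversity_table(ds)
        assert np.isnan(table.set_index("island_id").loc["A", "s_pie"])


class TestIsarTable:
    def test_identical_islands_give_flat_slopes(self):
        entries = {"x": 5, "y": 3, "z": 2}
        ds = ArchipelagoDataset(
            taxon="t",
            islands=[_island(f"i{k}", a, entries)
                     for k, a in enumerate([1.0, 10.0, 100.0])],
        )
        fits = isar_table(ds)
        for fit in fits.values():
            assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_regression_table_layout(self):
        entries = {"x": 5, "y": 3}
        ds = ArchipelagoDataset(
            taxon="frogs",
            islands=[_island(f"i{k}", a, entries)
                     for k, a in enumerate([1.0, 10.0, 100.0])],
        )
        table = regression_table(isar_table(ds), taxon="frogs")
        assert set(table["response"]) == {"s_total", "s_n", "s_pie"}
        assert (table["taxon"] == "frogs").all()
        assert (table["n_islands"] == 3).all()


class TestClassifyMechanism:
    def test_rare_only_pattern(self):
        # S_n rises clearly, S_PIE does not: the birds-like outcome
        fits = {"s_total": _fit(0.14, 1e-4), "s_n": _fit(0.08, 1e-4),
                "s_pie": _fit(0.05, 0.15)}
        assert classify_mechanism(fits).verdict == "disproportionate_rare"

    def test_common_and_rare_pattern(self):
        # S_PIE rises too: the butterflies-like outcome
        fits = {"s_total": _fit(0.14, 0.05), "s_n": _fit(0.11, 0.01),
                "s_pie": _fit(0.17, 0.02)}
        assert classify_mechanism(fits).verdict == "disproportionate_common_and_rare"

    def test_no_sn_signal_keeps_null(self):
        fits = {"s_total": _fit(0.2, 0.001), "s_n": _fit(0.01, 0.6),
                "s_pie": _fit(0.0, 0.9)}
        assert classify_mechanism(fits).verdict == "passive_sampling_not_rejected"

    def test_truth_table_is_total_and_deterministic(self):
        """Exhaustive sweep over slope signs and significance combinations."""
        levels = [(-0.1, 0.01), (-0.1, 0.5), (0.1, 0.01), (0.1, 0.5)]
        for (sn_s, sn_p), (sp_s, sp_p) in itertools.product(levels, levels):
            fits = {"s_total": _fit(0.1, 0.01), "s_n": _fit(sn_s, sn_p),
                    "s_pie": _fit(sp_s, sp_p)}
            verdict = classify_mechanism(fits).verdict
            sn_up = sn_p <= 0.05 and sn_s > 0
            sp_up = sp_p <= 0.05 and sp_s > 0
            if not sn_up:
                assert verdict == "passive_sampling_not_rejected"
            elif sp_up:
                assert verdict == "disproportionate_common_and_rare"
            else:
                assert verdict == "disproportionate_rare"

    @pytest.mark.parametrize(
        "beta_sn, beta_spie, expected",
        [
            ((0.2, 0.01), (0.0, 0.9), True),
            ((0.0, 0.9), (0.2, 0.01), True),
            ((0.2, 0.30), (-0.2, 0.01), False),
            ((0.0, 0.9), (0.0, 0.9), False),
        ],
    )
    def test_heterogeneity_flag(self, beta_sn, beta_spie, expected):
        fits = {"s_total": _fit(0.1, 0.01), "s_n": _fit(0.1, 0.01),
                "s_pie": _fit(0.0, 0.9)}
        beta = {"beta_sn": _fit(*beta_sn), "beta_spie": _fit(*beta_spie)}
        out = classify_mechanism(fits, beta)
        assert out.heterogeneity_implicated is expected
        assert out.verdict == "disproportionate_rare"

    def test_missing_fit_rejected(self):
        with pytest.raises(InferenceError):
            classify_mechanism({"s_total": _fit(0.1, 0.01), "s_n": _fit(0.1, 0.01)})

    def test_flag_absent_without_beta_fits(self):
        fits = {"s_total": _fit(0.1, 0.01), "s_n": _fit(0.1, 0.01),
                "s_pie": _fit(0.0, 0.9)}
        assert classify_mechanism(fits).heterogeneity_implicated is None
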