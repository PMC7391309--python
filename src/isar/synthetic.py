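"""Synthetic archipelagos with known ground-truth ISAR mechanisms.

The generator builds island (and plot) abundance data by sampling a shared
regional species pool, under one of four mechanisms:

``passive``
    The null: every island draws its J_i individuals multinomially from the
    unchanged regional relative abundances; larger islands hold more species
    only because they hold more individuals.
``disproportionate_rare``
    Species that are rare at the sampling scale (pool abundance below 1/J0)
    are progressively suppressed on smaller islands, leaving the common
    species' relative proportions untouched: rarefied richness responds to
    area while S_PIE barely moves.
``evenness_shift``
    The island abundance distribution is flattened on larger islands by a
    power transform of the pool (exponent decreasing in log-area), shifting
    common species too: S_PIE responds to area.
``heterogeneity``
    Island-scale composition follows the null, but individuals are clumped
    across plots (Dirichlet-multinomial), more strongly on larger islands:
    within-island beta-diversity responds to area.

Island community size follows J_i = round(J0 * area^d).  The default
exponent d is small: the generator emulates effort-standardized surveys
(quadrat or transect counts grow only weakly with island area), which keeps
every island's sample within the ~2x extrapolation range that the
reference-n recipe (n_ref = max(n_max, 2 n_min)) is built around.  The
default pool is large and strongly dominated (lognormal, heavy tail), so
observed richness keeps climbing with sample size while the evenness of the
common species stays put -- the regime in which total and rarefied richness
carry distinct information.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    AbundanceVector,
    ArchipelagoDataset,
    IslandSample,
    PlotSample,
    write_island_table,
    write_plot_table,
)
from .errors import DomainError

SCENARIOS = ("passive", "disproportionate_rare", "evenness_shift", "heterogeneity")

#: neutral value of each mechanism-strength parameter, and which scenario
#: is allowed to move it away from neutral.
_EFFECT_PARAMS = {
    "rare_boost": "disproportionate_rare",
    "evenness_gradient": "evenness_shift",
    "clumping": "heterogeneity",
}

DEFAULT_S_POOL = 2000
DEFAULT_SAD_SHAPE = 3.5
DEFAULT_J0 = 10_000.0
DEFAULT_DENSITY_EXPONENT = 0.09
DEFAULT_RARE_BOOST = 0.03
DEFAULT_EVENNESS_GRADIENT = 0.5
DEFAULT_CLUMPING = 0.8


@dataclass(frozen=True)
class RegionalPool:
    """Regional species pool: relative abundances summing to one."""

    relative_abundances: np.ndarray
    sad_shape: float

    def __post_init__(self) -> None:
        p = np.asarray(self.relative_abundances, dtype=float)
        if p.size < 2 or (p <= 0).any():
            raise DomainError("pool needs >= 2 species with positive abundance")
        if abs(p.sum() - 1.0) > 1e-12:
            raise DomainError("pool relative abundances must sum to 1")
        object.__setattr__(self, "relative_abundances", p)

    @property
    def s_pool(self) -> int:
        return int(self.relative_abundances.size)


def default_plots_per_island(areas: Sequence[float]) -> list[int]:
    """Plot counts increasing with area rank, from 2 to 10."""
    order = np.argsort(np.argsort(areas))  # rank of each island, 0-based
    n = len(areas)
    if n == 1:
        return [2]
    return [2 + int(round(8 * r / (n - 1))) for r in order]


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings for one synthetic archipelago under a named mechanism.

    Effect parameters not relevant to the named scenario are forced to
    their neutral value (0), so each scenario differs from the passive
    null through exactly one knob.
    """

    scenario: str
    island_areas: tuple[float, ...]
    s_pool: int = DEFAULT_S_POOL
    sad_shape: float = DEFAULT_SAD_SHAPE
    j0: float = DEFAULT_J0
    density_exponent: float = DEFAULT_DENSITY_EXPONENT
    rare_boost: float = DEFAULT_RARE_BOOST
    evenness_gradient: float = DEFAULT_EVENNESS_GRADIENT
    clumping: float = DEFAULT_CLUMPING
    plots_per_island: tuple[int, ...] | None = None
    generate_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise DomainError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        areas = tuple(float(a) for a in self.island_areas)
        if any(a <= 0 for a in areas):
            raise DomainError("island areas must be positive")
        object.__setattr__(self, "island_areas", areas)
        if not 0 <= self.clumping < 1:
            raise DomainError("clumping must be in [0, 1)")
        for param, owner in _EFFECT_PARAMS.items():
            if self.scenario != owner and getattr(self, param) != 0.0:
                object.__setattr__(self, param, 0.0)
        if self.plots_per_island is not None:
            counts = tuple(int(c) for c in self.plots_per_island)
            if len(counts) != len(areas):
                raise DomainError("plots_per_island must match island_areas")
            object.__setattr__(self, "plots_per_island", counts)

    @property
    def wants_plots(self) -> bool:
        return self.generate_plots or self.scenario == "heterogeneity"

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "island_areas": list(self.island_areas),
            "s_pool": self.s_pool,
            "sad_shape": self.sad_shape,
            "j0": self.j0,
            "density_exponent": self.density_exponent,
            "rare_boost": self.rare_boost,
            "evenness_gradient": self.evenness_gradient,
            "clumping": self.clumping,
            "plots_per_island": (
                None if self.plots_per_island is None else list(self.plots_per_island)
            ),
            "seed": self.seed,
        }


def log_uniform_areas(
    n_islands: int, area_min: float, area_max: float, seed: int
) -> tuple[float, ...]:
    """Island areas drawn log-uniformly on [area_min, area_max] km²."""
    rng = np.random.default_rng(seed)
    return tuple(
        np.exp(rng.uniform(np.log(area_min), np.log(area_max), n_islands))
    )


def sample_regional_pool(
    s_pool: int, sad_shape: float, seed: int | np.random.Generator
) -> RegionalPool:
    """Draw a lognormal regional species-abundance distribution."""
    if s_pool < 2:
        raise DomainError(f"s_pool must be >= 2, got {s_pool}")
    if sad_shape < 0:
        raise DomainError(f"sad_shape must be >= 0, got {sad_shape}")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sad_shape, size=s_pool) if sad_shape > 0 \
        else np.ones(s_pool)
    p = raw / raw.sum()
    # renormalize exactly so the invariant holds to 1e-12
    p = p / p.sum()
    return RegionalPool(relative_abundances=p, sad_shape=sad_shape)


def _island_relative_abundances(
    pool: RegionalPool, area: float, config: ScenarioConfig
) -> np.ndarray:
    p = pool.relative_abundances
    areas = np.asarray(config.island_areas)
    a_min, a_max = areas.min(), areas.max()

    if config.scenario == "disproportionate_rare" and config.rare_boost > 0:
        # suppress sample-rare species on smaller islands: "rare" means an
        # expected count of <= 1 individual in a unit-area survey (pool
        # abundance below 1/J0).  Species s gets the multiplier
        # (area / a_max)^(rare_boost * ln(p_ref / p_s)) with p_ref = 1/J0;
        # on the largest island every multiplier is 1 (pool recovered), and
        # species common in the samples keep their pool proportions
        # everywhere, so S_PIE is left essentially untouched.
        p_ref = 1.0 / config.j0
        rarity = np.maximum(0.0, np.log(p_ref / p))
        w = p * (area / a_max) ** (config.rare_boost * rarity)
        return w / w.sum()

    if config.scenario == "evenness_shift" and config.evenness_gradient > 0:
        # flatten the SAD on larger islands: exponent theta falls linearly
        # in log-area from 1 (smallest island) to 1 - gradient (largest).
        if a_max > a_min:
            frac = (np.log(area) - np.log(a_min)) / (np.log(a_max) - np.log(a_min))
        else:
            frac = 0.0
        theta = 1.0 - config.evenness_gradient * frac
        w = p ** theta
        return w / w.sum()

    # passive and heterogeneity leave the island-grain SAD untouched
    return p


def community_size(area: float, config: ScenarioConfig) -> int:
    """J_i = round(J0 * area^d)."""
    return int(round(config.j0 * area ** config.density_exponent))


def simulate_island(
    pool: RegionalPool,
    area: float,
    config: ScenarioConfig,
    island_seed: int | np.random.Generator,
) -> AbundanceVector:
    """Draw one island community multinomially from its scenario-adjusted SAD."""
    if area <= 0:
        raise DomainError("area must be positive")
    rng = np.random.default_rng(island_seed)
    pi = _island_relative_abundances(pool, area, config)
    j = community_size(area, config)
    counts = rng.multinomial(j, pi)
    width = len(str(pool.s_pool))
    return AbundanceVector(
        {f"sp{idx + 1:0{width}d}": int(c) for idx, c in enumerate(counts) if c > 0}
    )


def simulate_plots(
    island_community: AbundanceVector,
    plot_count: int,
    clumping: float,
    seed: int | np.random.Generator,
    island_id: str = "island",
) -> list[PlotSample]:
    """Allocate an island's individuals to plots, optionally clumped.

    Each species' count is split across plots by a Dirichlet-multinomial
    with per-plot concentration (1 - clumping)/clumping; at clumping = 0
    allocation is plain multinomial random placement.  Counts are conserved
    exactly: plot sums equal the island counts for every species.
    """
    if plot_count < 2:
        raise DomainError(f"plot_count must be >= 2, got {plot_count}")
    if not 0 <= clumping < 1:
        raise DomainError(f"clumping must be in [0, 1), got {clumping}")
    rng = np.random.default_rng(seed)
    width = len(str(plot_count))
    per_plot: list[dict[str, int]] = [dict() for _ in range(plot_count)]
    for sp in island_community.species:
        count = island_community.entries[sp]
        if clumping == 0:
            q = np.full(plot_count, 1.0 / plot_count)
        else:
            conc = (1.0 - clumping) / clumping
            q = rng.dirichlet(np.full(plot_count, conc))
        alloc = rng.multinomial(count, q)
        for j, c in enumerate(alloc):
            if c > 0:
                per_plot[j][sp] = int(c)
    return [
        PlotSample(island_id, f"p{j + 1:0{width}d}", AbundanceVector(entries))
        for j, entries in enumerate(per_plot)
    ]


def _island_clumping(area: float, config: ScenarioConfig) -> float:
    """Per-island clumping: rises linearly in log-area up to config.clumping."""
    if config.scenario != "heterogeneity" or config.clumping == 0:
        return 0.0
    areas = np.asarray(config.island_areas)
    a_min, a_max = areas.min(), areas.max()
    if a_max == a_min:
        return config.clumping
    frac = (np.log(area) - np.log(a_min)) / (np.log(a_max) - np.log(a_min))
    return float(config.clumping * frac)


def simulate_archipelago(config: ScenarioConfig) -> ArchipelagoDataset:
    """Assemble a full synthetic dataset under the configured scenario.

    Per-island seeds are spawned deterministically from the master seed, so
    identical configs give bit-identical datasets.
    """
    if len(config.island_areas) < 3:
        raise DomainError("need >= 3 island areas")
    root = np.random.SeedSequence(config.seed)
    pool_ss, *island_ss = root.spawn(1 + len(config.island_areas))
    pool = sample_regional_pool(config.s_pool, config.sad_shape,
                                np.random.default_rng(pool_ss))
    plot_counts = (
        list(config.plots_per_island)
        if config.plots_per_island is not None
        else default_plots_per_island(config.island_areas)
    )
    width = len(str(len(config.island_areas)))
    islands: list[IslandSample] = []
    plots: list[PlotSample] = []
    for idx, (area, ss) in enumerate(zip(config.island_areas, island_ss)):
        island_id = f"i{idx + 1:0{width}d}"
        com_ss, plot_ss = ss.spawn(2)
        community = simulate_island(pool, area, config,
                                    np.random.default_rng(com_ss))
        islands.append(
            IslandSample(island_id, float(area), community,
                         taxon=f"synthetic-{config.scenario}")
        )
        if config.wants_plots and community:
            plots.extend(
                simulate_plots(
                    community,
                    plot_counts[idx],
                    _island_clumping(area, config),
                    np.random.default_rng(plot_ss),
                    island_id=island_id,
                )
            )
    return ArchipelagoDataset(
        taxon=f"synthetic-{config.scenario}",
        islands=islands,
        plots=plots if config.wants_plots else None,
        provenance={"ground_truth": config.to_dict()},
    )


def write_archipelago(dataset: ArchipelagoDataset, out_dir: str | Path) -> None:
    """Write abundances/metadata (and plots) CSVs plus a ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_island_table(dataset, out / "abundances.csv", out / "metadata.csv")
    if dataset.plots:
        write_plot_table(dataset.plots, out / "plots.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(dataset.provenance, fh, indent=2)
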