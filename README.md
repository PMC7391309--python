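# isar — dissecting island species–area relationships with rarefaction

The island species–area relationship (ISAR) — more species on bigger
islands — is one of ecology's most robust patterns, and one of its least
diagnostic: it arises trivially if larger islands merely hold more
individuals sampled from a shared regional pool (*passive sampling*), but
also under genuinely ecological mechanisms such as disproportionate
effects of area on particular species or within-island habitat
heterogeneity. `isar` implements, as a tested reusable pipeline, the
individual-based rarefaction framework that separates these mechanisms
from abundance data alone.

For each island the package computes three diversity metrics from the
pooled abundance sample:

- **S_total** — estimated total richness, via the Chao1 lower bound
  `S_total = S_obs + F1²/(2·F2)` (F1, F2 = singleton and doubleton
  counts; bias-corrected form when F2 = 0);
- **S_n** — expected richness of `n_ref` individuals drawn at random,
  from the exact hypergeometric rarefaction curve
  `E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]`, extended beyond the observed N
  with the Chao1-conditional extrapolator; the common standardization
  size is `n_ref = max(n_max, 2·n_min)` over the taxon's island totals;
- **S_PIE** — the effective number of species `1/(1 − PIE)` of Hurlbert's
  probability of interspecific encounter
  `PIE = N/(N−1) · (1 − Σᵢ pᵢ²)`, sensitive to common species only.

Each metric is regressed on island area as the power law `S = C·A^z`
(OLS on natural-log axes), and the slope tests drive the decision logic:
an S_n slope indistinguishable from zero means passive sampling cannot be
rejected; S_n rising without S_PIE means area disproportionately favors
the rarer species; S_n and S_PIE both rising means the whole abundance
distribution shifts. Where plot-level (quadrat) data exist, within-island
β-diversity — pooled-island over mean per-plot diversity at a common
sample size — is regressed on area the same way; a positive slope
implicates within-island compositional heterogeneity.

A synthetic-archipelago generator (`isar.synthetic`) produces island and
plot abundance data under each of these mechanisms with known ground
truth, so the whole inference chain is testable without field data.

## Worked example

`examples/01_rarefaction_and_chao1.py` runs every estimator on a
hand-checkable sample {1, 1, 2, 3}:

```
N = 7, S_obs = 4, F1 = 2, F2 = 1
Chao1 total richness estimate: 6.0000
E[S_3]  (interpolated): 2.4571
E[S_15] (extrapolated): 5.3128
PIE = 0.8095, S_PIE = 5.2500
n_ref for totals [10, 12, 14]: 20
```

Chao1 adds F1²/(2F2) = 2 unseen species to the 4 observed; the
extrapolated curve climbs toward that asymptote of 6.

`examples/02_diversity_area_regression.py` simulates a 20-island passive
archipelago and prints the regression table:

```
            taxon response  intercept  se_intercept   slope  se_slope  r2_adj  p_slope  n_islands
synthetic-passive  s_total     6.4765        0.0172  0.0190    0.0047  0.4481   0.0007         20
synthetic-passive      s_n     6.2946        0.0093  0.0024    0.0025 -0.0038   0.3481         20
synthetic-passive    s_pie     3.4818        0.0032 -0.0009    0.0009  0.0086   0.2947         20

verdict: passive_sampling_not_rejected
```

S_total rises significantly with area (larger samples uncover more of the
pool) but rarefied richness at the common n_ref does not — exactly the
signature that withholds any claim beyond passive sampling. The other
examples recover the disproportionate-rare, evenness-shift, and
heterogeneity mechanisms from their respective generators.

## Command line

```bash
isar simulate --scenario heterogeneity --islands 20 --seed 3 --out sim/
isar analyze --abundances sim/abundances.csv --metadata sim/metadata.csv \
             --plots sim/plots.csv --out results/
isar calibrate --scenario passive --replicates 200 --out cal/
```

`analyze` accepts any long-format CSVs (`island_id, species_id,
abundance` plus `island_id, area_km2` metadata; optional
`island_id, plot_id, species_id, abundance` plots), with configurable
column names, and writes the diversity table, the regression table, the
β table, a JSON verdict, and an audit log.

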