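"""Core estimators on a tiny hand-checkable community.

A sample with two singletons, one doubleton and one tripleton (N = 7,
S_obs = 4) is small enough to verify every number by hand.
"""
from isar import (
    AbundanceVector,
    chao1,
    expected_richness,
    pie,
    reference_n,
    s_pie,
    sad_summary,
)

community = AbundanceVector({"a": 1, "b": 1, "c": 2, "d": 3})
summary = sad_summary(community)
print(f"N = {summary.n}, S_obs = {summary.s_obs}, "
      f"F1 = {summary.f1}, F2 = {summary.f2}")

# Chao1 adds F1^2 / (2 F2) unseen species: 4 + 4/2 = 6
print(f"Chao1 total richness estimate: {chao1(summary):.4f}")

# rarefy down to 3 individuals, extrapolate out to 15
print(f"E[S_3]  (interpolated): {expected_richness(community, 3).value:.4f}")
print(f"E[S_15] (extrapolated): {expected_richness(community, 15).value:.4f}")

# evenness: the chance two individuals are different species, and its
# effective species number (dominated by the common species)
print(f"PIE = {pie(community):.4f}, S_PIE = {s_pie(community).s_pie:.4f}")

# the common standardization size for islands with totals 10, 12, 14:
# max(largest sample, 2 x smallest) = max(14, 20) = 20
print(f"n_ref for totals [10, 12, 14]: {reference_n([10, 12, 14]).n_ref}")
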