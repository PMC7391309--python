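import numpy as np
import pytest

from isar import AbundanceVector


@pytest.fixture
def mixed_community() -> AbundanceVector:
    """The running worked example: two singletons, a doubleton, a tripleton."""
    return AbundanceVector({"a": 1, "b": 1, "c": 2, "d": 3})


def mc_rarefaction(counts, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo oracle: mean richness of random subsamples without
    replacement, at every n in [1, N], estimated from ``n_draws`` random
    permutations of the individuals (a prefix of length n is a uniform
    subsample of size n).  Independent of the analytic hypergeometric path.
    """
    counts = np.asarray(counts, dtype=np.int64)
    labels = np.repeat(np.arange(counts.size), counts)
    total = labels.size
    idx = np.argsort(rng.random((n_draws, total)), axis=1)
    perms = labels[idx]
    first = np.empty((counts.size, n_draws), dtype=np.int64)
    for s in range(counts.size):
        first[s] = np.argmax(perms == s, axis=1)
    out = np.empty(total)
    for n in range(1, total + 1):
        out[n - 1] = (first < n).mean(axis=1).sum()
    return out


def random_communities(n_communities: int, rng: np.random.Generator,
                       max_species: int = 10, max_n: int = 60):
    """Random small communities (S <= max_species, N <= max_n)."""
    coms = []
    while len(coms) < n_communities:
        s = rng.integers(2, max_species + 1)
        counts = rng.integers(1, 13, size=s)
        if counts.sum() <= max_n:
            coms.append(
                AbundanceVector({f"s{i}": int(c) for i, c in enumerate(counts)})
            )
    return coms
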