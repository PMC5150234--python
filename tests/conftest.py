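"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
naive furthest-neighbor agglomeration for OTU clustering, and random
additive trees built by explicit path-length bookkeeping for NJ.
"""

from __future__ import annotations

import numpy as np
import pytest

from aeronit import synthetic as syn


def naive_complete_linkage(d: np.ndarray, cutoff: float) -> list[frozenset[int]]:
    """Greedy furthest-neighbor agglomeration on a raw distance matrix."""
    clusters = [frozenset([i]) for i in range(d.shape[0])]

    def cdist(a, b):
        return max(d[i, j] for i in a for j in b)

    while True:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dd = cdist(clusters[x], clusters[y])
                if dd <= cutoff and (best is None or dd < best[0]):
                    best = (dd, x, y)
        if best is None:
            return clusters
        _, x, y = best
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)


def random_additive_matrix(
    n_leaves: int, rng: np.random.Generator
) -> np.ndarray:
    """Pairwise path distances of a random binary tree with branch
    lengths in [0.05, 1.0], built by explicit leaf-depth bookkeeping."""
    dists = np.zeros((n_leaves, n_leaves))
    depth = np.zeros(n_leaves)
    items: list[list[int]] = [[i] for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        li, lj = rng.uniform(0.05, 1.0, size=2)
        a_set, b_set = items[i], items[j]
        for a in a_set:
            depth[a] += li
        for b in b_set:
            depth[b] += lj
        for a in a_set:
            for b in b_set:
                dists[a, b] = dists[b, a] = depth[a] + depth[b]
        items = [c for k, c in enumerate(items) if k not in (i, j)]
        items.append(a_set + b_set)
    return dists


def exact_permutation_null_atoms(n: int) -> np.ndarray:
    """Null multiset of exact two-sided permutation p-values for
    distinct continuous data, built by direct enumeration.

    At small n the p-value is uniform on a discrete atom set, not on
    [0, 1]; empirical checks must compare against this multiset (e.g.
    via a two-sample KS test), not against a continuous uniform.
    """
    import itertools

    ranks = np.arange(1.0, n + 1)
    perms = np.array(list(itertools.permutations(range(n))))
    rc = ranks - ranks.mean()
    rho = (ranks[perms] - ranks.mean()) @ rc / (rc @ rc)
    a = np.abs(np.round(rho, 12))
    return np.sort(np.array([(a >= v - 1e-12).mean() for v in a]))


@pytest.fixture
def three_cluster_spec() -> syn.CommunitySpec:
    return syn.CommunitySpec(
        n_samples=2,
        clusters=(
            syn.ClusterSpec("A", 300, 0.005, (10, 10)),
            syn.ClusterSpec("B", 300, 0.005, (5, 5)),
            syn.ClusterSpec("C", 300, 0.005, (2, 1)),
        ),
        between_divergence=0.15,
        seed=42,
    )


@pytest.fixture
def clean_plate_spec() -> syn.QpcrPlateSpec:
    return syn.QpcrPlateSpec(
        true_slope=-3.3219,
        true_intercept=38.0,
        dilution_top=1e7,
        dilution_levels=5,
        unknown_true_copies={"u1": 1e5, "u2": 2.5e3},
        cq_noise_sd=0.0,
        replicates=3,
        seed=11,
    )


@pytest.fixture
def noiseless_incubation_spec() -> syn.IncubationSpec:
    return syn.IncubationSpec(
        guild_cells={"AOA": 1e5, "AOB": 5e3, "comammox": 1e3},
        guild_r_in={"AOA": 0.5, "AOB": 1.0, "comammox": 0.5},
        nh4_start=1.0,
        blank_level=0.35,
        noise_sd=0.0,
        seed=5,
    )
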