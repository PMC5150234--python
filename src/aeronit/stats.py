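"""Spearman rank correlations with permutation p-values.

With only a handful of samples per factor the asymptotic t
approximation for Spearman's rho is dubious, so the default p-value is
an exact enumeration over all n! orderings for n <= 8 (resolution 1/n!
— for n = 6, multiples of 1/720), falling back to seeded Monte Carlo or
the asymptotic approximation for larger n.  No multiple-testing
correction is applied by default; Benjamini-Hochberg is available.
"""

from __future__ import annotations

import itertools
import math
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_rho",
    "permutation_pvalue",
    "correlation_matrix",
]


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks.

    Ties get average ranks.  A constant vector makes the coefficient
    undefined and returns NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx, ry = _ranks(x), _ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


@lru_cache(maxsize=4)
def _all_perms(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _rho_against_perms(rx: np.ndarray, ry_perms: np.ndarray) -> np.ndarray:
    rxc = rx - rx.mean()
    ryc = ry_perms - ry_perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
    return (ryc @ rxc) / denom


def permutation_pvalue(x, y, n_perm="exact", seed: int | None = None) -> float:
    """Two-sided permutation p-value for Spearman's rho.

    ``n_perm="exact"`` enumerates all n! orderings of ``y`` (n <= 8);
    an integer runs that many seeded random permutations, with the
    identity permutation always counted.  p is the proportion of
    permutations whose |rho| is at least the observed |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = spearman_rho(x, y)
    if math.isnan(rho_obs):
        return float("nan")
    rx, ry = _ranks(x), _ranks(y)
    threshold = abs(rho_obs) - 1e-12
    if n_perm == "exact":
        n = x.size
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        perms = _all_perms(n)
        rhos = _rho_against_perms(rx, ry[perms])
        return float((np.abs(rhos) >= threshold).mean())
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 99:
        warnings.warn(
            f"n_perm={n_perm} gives a very coarse p-value", UserWarning, stacklevel=2
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x.size) for _ in range(n_perm)])
    rhos = _rho_against_perms(rx, ry[perms])
    hits = int((np.abs(rhos) >= threshold).sum())
    return float((hits + 1) / (n_perm + 1))  # identity permutation included


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


def correlation_matrix(
    factors: pd.DataFrame,
    variables: pd.DataFrame,
    method: str = "auto",
    n_perm: int = 999,
    seed: int | None = None,
    bh: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All variable x factor Spearman correlations, heatmap-ready.

    Both tables are indexed by sample; rows are restricted to shared
    samples (>= 4 required).  ``method``: "auto" (exact permutation for
    n <= 8, asymptotic otherwise), "exact", "montecarlo" or
    "asymptotic".  Returns a long table (variable, factor, rho, p_value,
    method, n, significant) with significance at ``p <= alpha`` and an
    optional BH-adjusted ``q_value`` column.
    """
    shared = factors.index.intersection(variables.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    f = factors.loc[shared]
    v = variables.loc[shared]
    n = len(shared)
    if method == "auto":
        method = "exact" if n <= 8 else "asymptotic"
    if method not in ("exact", "montecarlo", "asymptotic"):
        raise ValueError("unknown method")

    rows = []
    for var in v.columns:
        for fac in f.columns:
            x = f[fac].to_numpy(dtype=float)
            y = v[var].to_numpy(dtype=float)
            rho = spearman_rho(x, y)
            if math.isnan(rho):
                p = float("nan")
            elif method == "exact":
                p = permutation_pvalue(x, y, n_perm="exact")
            elif method == "montecarlo":
                p = permutation_pvalue(x, y, n_perm=n_perm, seed=seed)
            else:
                p = float(stats.spearmanr(x, y).pvalue)
            rows.append(
                {
                    "variable": var,
                    "factor": fac,
                    "rho": rho,
                    "p_value": p,
                    "method": method if method != "exact" else "exact-permutation",
                    "n": n,
                }
            )
    out = pd.DataFrame(rows)
    if bh:
        mask = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        q[mask.to_numpy()] = _bh_adjust(out.loc[mask, "p_value"].to_numpy())
        out["q_value"] = q
        out["significant"] = out["q_value"] <= alpha
    else:
        out["significant"] = out["p_value"] <= alpha
    return out
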