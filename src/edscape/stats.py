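"""Rank-based group comparison: Kruskal–Wallis with Dunn–Šidák post hoc.

The omnibus test is the tie-corrected Kruskal–Wallis H,

    H = [ 12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1) ] / [ 1 - sum(t^3-t)/(N^3-N) ]

with mid-ranks for ties and an asymptotic chi-square(k-1) p-value.  Pairwise
differences use Dunn's z on mean ranks,

    z_ij = (Rbar_i - Rbar_j) / sqrt( [N(N+1)/12 - sum(t^3-t)/(12(N-1))] *
                                     (1/n_i + 1/n_j) ),

two-sided normal p, with the Šidák family-wise adjustment
``p_adj = 1 - (1 - p)^m`` over the m = k(k-1)/2 comparisons (Bonferroni
available behind a flag).  For tiny designs an exact permutation p-value for
H is provided as an oracle.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def _ranks_and_ties(groups: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # mid-ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    out = []
    start = 0
    for g in groups:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    return out, tie_term


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("every group needs at least 1 observation")
    if sum(len(g) for g in gs) < 3:
        raise ValueError("need at least 3 observations in total")
    return gs


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p-value.

    All-identical observations give (H=0, p=1) rather than an error.
    """
    gs = _check_groups(groups)
    n = np.array([len(g) for g in gs])
    N = int(n.sum())
    granks, tie_term = _ranks_and_ties(gs)
    correction = 1.0 - tie_term / (N**3 - N)
    if correction <= 0:  # all observations identical
        return 0.0, 1.0
    rsum = np.array([r.sum() for r in granks])
    h = (12.0 / (N * (N + 1)) * np.sum(rsum**2 / n) - 3.0 * (N + 1)) / correction
    h = max(0.0, float(h))
    p = float(sps.chi2.sf(h, df=len(gs) - 1))
    return h, p


def kruskal_wallis_exact_p(groups: list, max_n: int = 10) -> float:
    """Exact permutation p-value for H (all relabelings of the pooled data).

    Enumerates every assignment of the pooled observations to groups of the
    given sizes; feasible for N <= ``max_n``.  P(H >= H_observed).
    """
    gs = _check_groups(groups)
    sizes = [len(g) for g in gs]
    N = sum(sizes)
    if N > max_n:
        raise ValueError(f"exact enumeration limited to N <= {max_n}")
    h_obs, _ = kruskal_wallis(gs)
    pooled = np.concatenate(gs)

    def assignments(indices: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield (indices,)
            return
        first = sizes_left[0]
        for chosen in combinations(indices, first):
            rest = tuple(i for i in indices if i not in chosen)
            for tail in assignments(rest, sizes_left[1:]):
                yield (chosen, *tail)

    count = 0
    total = 0
    for split in assignments(tuple(range(N)), sizes):
        perm_groups = [pooled[list(idx)] for idx in split]
        h, _ = kruskal_wallis(perm_groups)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def sidak_adjust(p_raw: float, m: int) -> float:
    """Šidák family-wise adjustment, clipped to [0, 1]."""
    if not (0.0 <= p_raw <= 1.0) or m < 1:
        raise ValueError("p_raw must be in [0,1] and m >= 1")
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def dunn_sidak(
    groups: list,
    labels: list[str] | None = None,
    adjust: str = "sidak",
) -> pd.DataFrame:
    """Dunn's pairwise rank test with Šidák (or Bonferroni) correction.

    Empty groups are dropped with a warning.  Returns one row per pair with
    z, p_raw and p_adjusted (two-sided).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    keep = [i for i, g in enumerate(gs) if len(g) > 0]
    if len(keep) < len(gs):
        dropped = [labels[i] for i in range(len(gs)) if i not in keep]
        warnings.warn(f"dropping empty groups: {dropped}")
    gs = [gs[i] for i in keep]
    labels = [labels[i] for i in keep]
    if len(gs) < 2:
        raise ValueError("need at least 2 non-empty groups")

    n = np.array([len(g) for g in gs])
    N = int(n.sum())
    granks, tie_term = _ranks_and_ties(gs)
    mean_ranks = np.array([r.mean() for r in granks])
    var_term = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    k = len(gs)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_term * (1.0 / n[i] + 1.0 / n[j]))
            if se == 0:
                z, p_raw = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_raw = float(2.0 * sps.norm.sf(abs(z)))
            if adjust == "sidak":
                p_adj = sidak_adjust(p_raw, m)
            elif adjust == "bonferroni":
                p_adj = float(min(1.0, p_raw * m))
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "z": float(z),
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                }
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])


def group_comparison(
    values: pd.DataFrame,
    group_col: str,
    value_col: str,
    adjust: str = "sidak",
) -> dict:
    """Omnibus + post hoc comparison of a tidy table of per-replicate values.

    NA values are dropped; groups left empty are excluded from the post
    hoc.  Returns {"H", "p_omnibus", "pairwise"} with the Dunn table.
    """
    df = values[[group_col, value_col]].dropna()
    labels = sorted(df[group_col].unique())
    groups = [df.loc[df[group_col] == lab, value_col].to_numpy() for lab in labels]
    if len(groups) < 2 or sum(len(g) for g in groups) < 3:
        return {"H": float("nan"), "p_omnibus": float("nan"),
                "pairwise": pd.DataFrame(
                    columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])}
    h, p = kruskal_wallis(groups)
    pairwise = dunn_sidak(groups, labels=labels, adjust=adjust)
    return {"H": h, "p_omnibus": p, "pairwise": pairwise}
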