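"""Single-cell mixed-cell analysis: observed vs expected editing heterogeneity.

Among cells with at least two reads of one site's transcript (edited and
unedited combined), a *mixed* cell carries at least one read of each
variant.  Under the null that every read is independently edited with the
pooled editing level p, a cell with n reads is mixed with probability
``1 - p^n - (1-p)^n``; the expected mixed proportion conditions on the
observed per-cell read-count histogram.  Sites where the observed mixed
proportion falls below the expectation indicate cell-to-cell editing
heterogeneity (bimodal per-cell editing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MixedCellStats:
    site_id: str
    n_cells_ge2: int
    read_count_histogram: dict[int, int] = field(default_factory=dict)
    observed_mixed: float = float("nan")
    expected_mixed: float = float("nan")
    editing_level: float = float("nan")

    @property
    def deviation(self) -> float:
        return self.observed_mixed - self.expected_mixed


def observed_mixed(cell_variant_counts: pd.DataFrame, site_id: str) -> MixedCellStats:
    """Observed mixed-cell proportion for one site.

    ``cell_variant_counts`` has one row per cell with columns n_edited and
    n_unedited for this site.  The denominator is the cells with >= 2 reads
    total; mixed cells have >= 1 of each variant.
    """
    tot = (
        cell_variant_counts["n_edited"] + cell_variant_counts["n_unedited"]
    ).to_numpy()
    ge2 = cell_variant_counts[tot >= 2]
    n = len(ge2)
    hist: dict[int, int] = {}
    for t in (ge2["n_edited"] + ge2["n_unedited"]).astype(int):
        hist[t] = hist.get(t, 0) + 1
    mixed = int(((ge2["n_edited"] >= 1) & (ge2["n_unedited"] >= 1)).sum())
    return MixedCellStats(
        site_id=site_id,
        n_cells_ge2=n,
        read_count_histogram=hist,
        observed_mixed=mixed / n if n else float("nan"),
    )


def expected_mixed(p: float, read_count_histogram: dict[int, int]) -> float:
    """Expected mixed proportion under independent per-read editing.

    ``sum_n f_n (1 - p^n - (1-p)^n) / sum_n f_n`` over the observed
    histogram of per-cell read counts (n >= 2).  NaN for an empty
    histogram; 0 at p in {0, 1}; symmetric in p <-> 1-p and maximal at
    p = 0.5.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("editing level must be in [0, 1]")
    total = sum(read_count_histogram.values())
    if total == 0:
        return float("nan")
    acc = 0.0
    for n, f in read_count_histogram.items():
        if n < 2 or f < 0:
            raise ValueError("histogram must cover counts n >= 2 with f >= 0")
        acc += f * (1.0 - p**n - (1.0 - p) ** n)
    return acc / total


def site_mixed_stats(
    cell_variant_counts: pd.DataFrame, site_id: str
) -> MixedCellStats:
    """Observed and expected mixed proportions for one site.

    The null editing level p is pooled over all reads of the site in the
    analyzed stratum (all cells, not only the >= 2-read ones), matching the
    convention of deriving the expectation from the observed editing level.
    """
    stats = observed_mixed(cell_variant_counts, site_id)
    n_ed = int(cell_variant_counts["n_edited"].sum())
    n_un = int(cell_variant_counts["n_unedited"].sum())
    if n_ed + n_un > 0:
        p = n_ed / (n_ed + n_un)
        stats.editing_level = p
        stats.expected_mixed = expected_mixed(p, stats.read_count_histogram)
    return stats


def compare_mixed(stats: list[MixedCellStats]) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of observed vs expected mixed proportions.

    Requires >= 3 sites with defined statistics.  Returns (r, table) where
    the table has one row per site with the deviation (observed - expected)
    and an ``under_represented`` flag for sites where mixed cells are rarer
    than the random-assignment expectation — the cell-to-cell heterogeneity
    signal.
    """
    rows = [
        {
            "site_id": s.site_id,
            "n_cells_ge2": s.n_cells_ge2,
            "observed": s.observed_mixed,
            "expected": s.expected_mixed,
            "deviation": s.deviation,
            "under_represented": s.observed_mixed < s.expected_mixed,
        }
        for s in stats
        if not (np.isnan(s.observed_mixed) or np.isnan(s.expected_mixed))
    ]
    if len(rows) < 3:
        raise ValueError("compare_mixed requires >= 3 sites with defined stats")
    df = pd.DataFrame(rows)
    if df["observed"].std() == 0 or df["expected"].std() == 0:
        r = 1.0 if np.allclose(df["observed"], df["expected"]) else float("nan")
    else:
        r = float(sps.pearsonr(df["observed"], df["expected"]).statistic)
    return r, df
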