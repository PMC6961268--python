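"""Marker-based cell classification and cell-type-resolved editing.

Classification is *non-strict*: a cell positive for markers of several
classes belongs to all of them (no mutual exclusion), since a single soma
can legitimately capture reads of more than one marker and misassignment is
mostly a segmentation effect.  Marker-stratified editing pools edited and
unedited reads over qualifying cells per replicate, applies the study's
cell-count filters (100-cell replicate mean for marker strata, 20 cells per
replicate for the three-class temporal analysis), and replicate-averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codebook import Codebook
from .quant import (
    CLASS_MIN_CELLS,
    MARKER_MIN_CELLS,
    QC_BELOW_20_CELLS,
    QC_BELOW_100_CELLS,
    editing_level,
    editing_ratio,
)
from .segment import UNASSIGNED

#: default classes of the temporal three-class comparison
TEMPORAL_CLASSES = {
    "interneuron": "Sst",
    "pyramidal": "Pcp4",
    "oligodendrocyte": "Plp1",
}


def build_cell_table(reads: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Long-format per-cell read counts from an assigned ReadTable.

    Counts pass-QC reads per (cell_id, target, *by*), dropping unassigned
    reads.  Columns: cell_id, *by*, target, count.
    """
    by = by or []
    sub = reads[reads["pass_qc"] & (reads["cell_id"] != UNASSIGNED)]
    counts = (
        sub.groupby(["cell_id", *by, "target"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def classify_cells(
    cell_counts: pd.DataFrame, cb: Codebook, min_marker_reads: int = 1
) -> pd.DataFrame:
    """Multi-label marker classification.

    Returns one row per cell with ``marker_classes`` (frozenset of class
    names) and ``markers`` (frozenset of marker targets with >=
    ``min_marker_reads`` reads).  Cells without marker reads get empty
    sets.  Raises if a marker-class lookup fails for a counted marker
    target present in the codebook as a marker.
    """
    marker_class = {e.target_name: e.cell_class for e in cb.markers()}
    known_targets = {e.target_name for e in cb.entries}
    unknown = set(cell_counts["target"].unique()) - known_targets
    if unknown:
        raise ValueError(f"targets absent from codebook: {sorted(unknown)}")
    sub = cell_counts[
        cell_counts["target"].isin(marker_class)
        & (cell_counts["count"] >= min_marker_reads)
    ]
    grouped = sub.groupby("cell_id", observed=True)["target"].agg(frozenset)
    all_cells = pd.Index(cell_counts["cell_id"].unique(), name="cell_id")
    markers = grouped.reindex(all_cells).apply(
        lambda v: v if isinstance(v, frozenset) else frozenset()
    )
    classes = markers.apply(
        lambda ms: frozenset(marker_class[m] for m in ms)
    )
    return pd.DataFrame(
        {"cell_id": all_cells, "markers": markers.to_numpy(),
         "marker_classes": classes.to_numpy()}
    ).reset_index(drop=True)


def _site_cell_counts(
    cell_counts: pd.DataFrame, cb: Codebook, site_id: str
) -> pd.DataFrame:
    """Per-cell (n_edited, n_unedited) for one site, cells with >= 1 site read."""
    ed, un = cb.variant_entries(site_id)
    sub = cell_counts[cell_counts["target"].isin([ed.target_name, un.target_name])]
    pivot = (
        sub.pivot_table(
            index="cell_id", columns="target", values="count",
            aggfunc="sum", fill_value=0,
        )
        .reindex(columns=[ed.target_name, un.target_name], fill_value=0)
    )
    pivot.columns = ["n_edited", "n_unedited"]
    return pivot.reset_index()


def marker_editing(
    cell_counts: pd.DataFrame,
    classification: pd.DataFrame,
    cb: Codebook,
    site_id: str,
    marker: str,
    replicates: pd.Series | None = None,
    min_cells: int = MARKER_MIN_CELLS,
) -> dict:
    """Editing level of one site among cells positive for one marker.

    A qualifying cell carries >= 1 read of the marker *and* >= 1 read of
    either variant of the site; counts are pooled over qualifying cells.
    When the replicate-mean number of qualifying cells is below
    ``min_cells`` the stratum is flagged ``below_100_cells``.

    ``replicates`` optionally maps cell_id -> replicate_id; without it the
    input is treated as a single replicate.

    Returns a dict with n_edited, n_unedited, level, n_cells,
    mean_cells_per_replicate and qc.
    """
    if marker not in {e.target_name for e in cb.markers()}:
        raise ValueError(f"unknown marker {marker!r}")
    positive = set(
        classification.loc[
            classification["markers"].apply(lambda ms: marker in ms), "cell_id"
        ]
    )
    site_counts = _site_cell_counts(cell_counts, cb, site_id)
    qual = site_counts[site_counts["cell_id"].isin(positive)]
    n_cells = len(qual)
    if replicates is not None:
        rep_of = replicates
        reps = qual["cell_id"].map(rep_of)
        n_reps = max(1, rep_of.nunique())
        mean_cells = n_cells / n_reps if n_reps else 0.0
        del reps
    else:
        mean_cells = float(n_cells)
    n_ed = int(qual["n_edited"].sum())
    n_un = int(qual["n_unedited"].sum())
    qc = "" if mean_cells >= min_cells else QC_BELOW_100_CELLS
    return {
        "site_id": site_id,
        "marker": marker,
        "n_edited": n_ed,
        "n_unedited": n_un,
        "level": editing_level(n_ed, n_un),
        "n_cells": n_cells,
        "mean_cells_per_replicate": mean_cells,
        "qc": qc,
    }


def marker_negative_editing(
    cell_counts: pd.DataFrame,
    classification: pd.DataFrame,
    cb: Codebook,
    site_id: str,
    marker: str,
) -> dict:
    """Editing level among cells where the marker was not detected."""
    negative = set(
        classification.loc[
            classification["markers"].apply(lambda ms: marker not in ms), "cell_id"
        ]
    )
    site_counts = _site_cell_counts(cell_counts, cb, site_id)
    qual = site_counts[site_counts["cell_id"].isin(negative)]
    n_ed = int(qual["n_edited"].sum())
    n_un = int(qual["n_unedited"].sum())
    return {
        "site_id": site_id,
        "marker": marker,
        "n_edited": n_ed,
        "n_unedited": n_un,
        "level": editing_level(n_ed, n_un),
        "n_cells": len(qual),
    }


def marker_editing_ratio(level_positive: float, level_negative: float) -> float:
    """Marker-positive over marker-negative editing level (NaN-propagating)."""
    return editing_ratio(level_positive, level_negative)


def class_temporal_editing(
    cell_counts: pd.DataFrame,
    classification: pd.DataFrame,
    cb: Codebook,
    site_id: str,
    cell_meta: pd.DataFrame,
    classes: dict[str, str] | None = None,
    min_cells_per_replicate: int = CLASS_MIN_CELLS,
) -> pd.DataFrame:
    """Per-(class, stage, replicate) editing levels with the 20-cell filter.

    ``classes`` maps class name -> defining marker target (default the
    Sst / Pcp4 / Plp1 trio); ``cell_meta`` needs cell_id, replicate and
    stage columns.  Replicates with fewer than ``min_cells_per_replicate``
    qualifying cells for a class are flagged ``below_20_cells``.
    """
    classes = classes or TEMPORAL_CLASSES
    site_counts = _site_cell_counts(cell_counts, cb, site_id)
    meta = cell_meta.set_index("cell_id")
    rows = []
    for cls, marker in classes.items():
        positive = set(
            classification.loc[
                classification["markers"].apply(lambda ms: marker in ms), "cell_id"
            ]
        )
        qual = site_counts[site_counts["cell_id"].isin(positive)].copy()
        qual["replicate"] = qual["cell_id"].map(meta["replicate"])
        qual["stage"] = qual["cell_id"].map(meta["stage"])
        for (stage, rep), grp in qual.groupby(["stage", "replicate"], observed=True):
            n_ed = int(grp["n_edited"].sum())
            n_un = int(grp["n_unedited"].sum())
            rows.append(
                {
                    "site_id": site_id,
                    "cell_class": cls,
                    "stage": stage,
                    "replicate": rep,
                    "n_cells": len(grp),
                    "n_edited": n_ed,
                    "n_unedited": n_un,
                    "level": editing_level(n_ed, n_un),
                    "qc": ""
                    if len(grp) >= min_cells_per_replicate
                    else QC_BELOW_20_CELLS,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "cell_class", "stage", "replicate", "n_cells",
            "n_edited", "n_unedited", "level", "qc",
        ],
    )
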