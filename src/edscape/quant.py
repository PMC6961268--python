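"""Editing levels, coverage filters, editing ratios, ADAR2 decomposition.

The editing level of a site in a stratum is ``n_edited / (n_edited +
n_unedited)`` over pass-QC reads, NA on a zero denominator.  Sites enter
the analysis only when, for at least one developmental stage, the
replicate-mean read count of the *least prevalent* variant at whole-tissue
level reaches 500.  Regional estimates require 100 combined reads per
replicate; strata failing a filter are flagged and excluded from replicate
aggregation rather than zero-imputed.  Editing ratios compare a stratum to
its complement (region vs whole-minus-region); ADAR2 reads are split into
active/inactive isoforms from the auto-editing level (editing at the
intronic -1 site creates the frameshifted, inactive splice isoform).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codebook import Codebook

WHOLE_MIN_VARIANT_READS = 500  # whole-tissue, replicate mean of the rarer variant
REGION_MIN_READS = 100  # combined reads per replicate within one region
MARKER_MIN_CELLS = 100  # replicate-mean qualifying cells for marker strata
CLASS_MIN_CELLS = 20  # qualifying cells per replicate in the temporal analysis

QC_BELOW_500_WHOLE = "below_500_whole"
QC_BELOW_100_REGION = "below_100_region"
QC_BELOW_100_CELLS = "below_100_cells"
QC_BELOW_20_CELLS = "below_20_cells"
QC_NA_DENOMINATOR = "NA_zero_denominator"

COMPLEMENT_SUFFIX = "whole_minus_"


def editing_level(n_edited: int, n_unedited: int) -> float:
    """Edited fraction, NaN when no reads at all."""
    if n_edited < 0 or n_unedited < 0:
        raise ValueError("read counts must be nonnegative")
    total = n_edited + n_unedited
    if total == 0:
        return float("nan")
    return n_edited / total


def editing_ratio(level_in: float, level_out: float) -> float:
    """Level in a stratum over the level in its complement; NaN-propagating."""
    if np.isnan(level_in) or np.isnan(level_out) or level_out == 0:
        return float("nan")
    return level_in / level_out


def adar2_decompose(
    auto_editing_level: float, total_adar2_reads: int
) -> tuple[float, float]:
    """Split ADAR2 reads into (active, inactive) isoform counts.

    Auto-editing at the -1 site produces the alternatively spliced,
    frameshifted *inactive* isoform, so inactive = round(level * total)
    (half rounds up) and active is the remainder.  NA level gives (NaN,
    NaN).
    """
    if total_adar2_reads < 0:
        raise ValueError("total_adar2_reads must be nonnegative")
    if np.isnan(auto_editing_level):
        return float("nan"), float("nan")
    if not (0.0 <= auto_editing_level <= 1.0):
        raise ValueError("auto-editing level must be in [0, 1]")
    inactive = int(np.floor(auto_editing_level * total_adar2_reads + 0.5))
    return float(total_adar2_reads - inactive), float(inactive)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def variant_counts(
    reads: pd.DataFrame, cb: Codebook, by: list[str] | None = None
) -> pd.DataFrame:
    """Edited/unedited read counts per site (pass-QC reads only).

    ``by`` lists extra grouping columns present on the ReadTable (e.g.
    ``["replicate", "stage"]`` or ``["region", "replicate"]``).  The result
    has one row per (site_id, *by*) with columns n_edited, n_unedited and
    level.
    """
    by = by or []
    site_of = {}
    class_of = {}
    for site, ed_bc, un_bc in cb.site_pairs():
        ed, un = cb.variant_entries(site)
        site_of[ed.target_name] = site
        site_of[un.target_name] = site
        class_of[ed.target_name] = "edited"
        class_of[un.target_name] = "unedited"
    sub = reads[reads["pass_qc"] & reads["target"].isin(site_of)].copy()
    if sub.empty:
        return pd.DataFrame(columns=["site_id", *by, "n_edited", "n_unedited", "level"])
    sub["site_id"] = sub["target"].map(site_of)
    sub["variant"] = sub["target"].map(class_of)
    counts = (
        sub.groupby(["site_id", *by, "variant"], observed=True)
        .size()
        .unstack("variant", fill_value=0)
        .reindex(columns=["edited", "unedited"], fill_value=0)
        .reset_index()
        .rename(columns={"edited": "n_edited", "unedited": "n_unedited"})
    )
    counts.columns.name = None
    counts["level"] = [
        editing_level(e, u) for e, u in zip(counts["n_edited"], counts["n_unedited"])
    ]
    return counts


def whole_brain_site_filter(
    whole_counts: pd.DataFrame, min_reads: int = WHOLE_MIN_VARIANT_READS
) -> tuple[list[str], pd.DataFrame]:
    """Retain sites with enough whole-tissue coverage of the rarer variant.

    ``whole_counts`` needs columns site_id, replicate, stage, n_edited,
    n_unedited.  A site is retained iff at some stage the mean over
    replicates of ``min(n_edited, n_unedited)`` is >= ``min_reads``;
    otherwise it is flagged ``below_500_whole``.
    Returns (retained site_ids, per-site qc table).
    """
    df = whole_counts.copy()
    df["min_variant"] = df[["n_edited", "n_unedited"]].min(axis=1)
    per_stage = (
        df.groupby(["site_id", "stage"], observed=True)["min_variant"]
        .mean()
        .reset_index()
    )
    best = per_stage.groupby("site_id", observed=True)["min_variant"].max()
    qc = pd.DataFrame(
        {
            "site_id": best.index,
            "best_stage_mean_min_variant": best.to_numpy(),
            "retained": (best >= min_reads).to_numpy(),
        }
    ).reset_index(drop=True)
    qc["qc"] = np.where(qc["retained"], "", QC_BELOW_500_WHOLE)
    retained = sorted(qc.loc[qc["retained"], "site_id"])
    return retained, qc


def regional_counts(
    reads: pd.DataFrame,
    cb: Codebook,
    region_names: list[str],
    min_reads: int = REGION_MIN_READS,
) -> pd.DataFrame:
    """Per-(site, region, replicate) estimates plus the complement stratum.

    For every named region the complement stratum ``whole_minus_<region>``
    pools all other pass-QC reads (including those outside every ROI), so
    in-region and complement counts add up to the whole-tissue counts.
    Replicates with fewer than ``min_reads`` combined reads in a stratum
    are flagged ``below_100_region`` (and should be excluded from
    aggregation).
    """
    known = set(region_names)
    seen = set(reads["region"].unique()) - {None}
    from .scene import NO_REGION

    unknown = seen - known - {NO_REGION}
    if unknown:
        raise ValueError(f"unknown region names in reads: {sorted(unknown)}")

    frames = []
    for region in region_names:
        for stratum, mask in (
            (f"region:{region}", reads["region"] == region),
            (f"{COMPLEMENT_SUFFIX}{region}", reads["region"] != region),
        ):
            counts = variant_counts(reads[mask], cb, by=["replicate"])
            counts["stratum"] = stratum
            if len(counts):
                frames.append(counts)
    if not frames:
        return pd.DataFrame(
            columns=["site_id", "replicate", "n_edited", "n_unedited",
                     "level", "stratum", "qc"]
        )
    out = pd.concat(frames, ignore_index=True)
    combined = out["n_edited"] + out["n_unedited"]
    out["qc"] = np.where(combined < min_reads, QC_BELOW_100_REGION, "")
    return out


def regional_editing_ratios(regional: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate region-vs-rest editing ratios from regional_counts output.

    Rows failing the regional coverage filter (on either side) propagate NA.
    """
    inr = regional[regional["stratum"].str.startswith("region:")].copy()
    inr["region"] = inr["stratum"].str.removeprefix("region:")
    outr = regional[regional["stratum"].str.startswith(COMPLEMENT_SUFFIX)].copy()
    outr["region"] = outr["stratum"].str.removeprefix(COMPLEMENT_SUFFIX)
    merged = inr.merge(
        outr,
        on=["site_id", "replicate", "region"],
        suffixes=("_in", "_out"),
        how="inner",
    )
    ratios = []
    for row in merged.itertuples(index=False):
        if row.qc_in or row.qc_out:
            ratios.append(float("nan"))
        else:
            ratios.append(editing_ratio(row.level_in, row.level_out))
    merged["ratio"] = ratios
    return merged[
        ["site_id", "region", "replicate", "level_in", "level_out", "ratio",
         "qc_in", "qc_out"]
    ]


def aggregate_replicates(
    estimates: pd.DataFrame,
    value: str = "level",
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Unweighted mean and sample SD of per-replicate values per stratum.

    Rows with a non-empty ``qc`` flag or NA value are excluded first; a
    stratum with zero contributing replicates is reported NA with qc
    reason.  SD is the ddof=1 sample SD, NA when only one replicate
    contributes.
    """
    by = by or ["site_id", "stratum"]
    df = estimates.copy()
    if "qc" in df.columns:
        contributing = df[(df["qc"] == "") & df[value].notna()]
    else:
        contributing = df[df[value].notna()]
    all_strata = df[by].drop_duplicates()
    agg = (
        contributing.groupby(by, observed=True)[value]
        .agg(mean="mean", sd="std", n_replicates="count")
        .reset_index()
    )
    out = all_strata.merge(agg, on=by, how="left")
    out["n_replicates"] = out["n_replicates"].fillna(0).astype(int)
    out["qc"] = np.where(out["n_replicates"] == 0, QC_NA_DENOMINATOR, "")
    return out
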