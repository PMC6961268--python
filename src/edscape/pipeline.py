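"""End-to-end pipeline orchestration: decode -> segment -> assign -> quantify.

A run is described by a YAML (or JSON) config naming the codebook, optional
region polygons, the per-replicate inputs (a pre-extracted spot-intensity
CSV or a directory of cycle/channel TIFFs, plus a DAPI TIFF) and the
analysis parameters, all defaulting to the assay's values (quality
threshold 0.40 in the reported 0.35-0.5 range, expected-read fraction 0.95,
20 px soma expansion, 500/100/100/20 coverage filters).  Every stage writes
its table to the run directory so any downstream figure table can be
rebuilt by selection only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .codebook import ALPHABET, Codebook, load_codebook
from .decode import DecodeParams, decode_images, decode_spot_table
from .scene import CycleImageSet, NO_REGION
from .segment import (
    DEFAULT_EXPANSION_PX,
    CellLabelMap,
    assign_reads,
    expand_cells,
    load_regions,
    segment_nuclei,
)
from . import celltype as ct
from . import mixed as mx
from . import quant
from . import stats as gstats


class PipelineError(RuntimeError):
    pass


@dataclass
class ReplicateInput:
    replicate: str
    stage: str
    spots: str | None = None  # pre-extracted spot-intensity CSV
    images: str | None = None  # directory with cycle{c}_{base}.tif
    dapi: str | None = None  # DAPI TIFF for segmentation


@dataclass
class RunConfig:
    codebook: str
    output_dir: str
    replicates: list[ReplicateInput]
    regions: str | None = None
    seed: int = 0
    threshold: float | str = 0.4  # "auto" = calibrate
    expected_fraction: float = 0.95
    expansion_distance: float = DEFAULT_EXPANSION_PX
    min_nucleus_area: float = 20.0
    max_nucleus_area: float = 10_000.0
    whole_min_variant_reads: int = quant.WHOLE_MIN_VARIANT_READS
    region_min_reads: int = quant.REGION_MIN_READS
    marker_min_cells: int = quant.MARKER_MIN_CELLS
    class_min_cells: int = quant.CLASS_MIN_CELLS
    decode_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        reps = [ReplicateInput(**r) for r in raw.pop("replicates")]
        cfg = cls(replicates=reps, **raw)
        cfg.validate(base=path.parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")

        def _resolve(p):
            q = Path(p)
            return q if q.is_absolute() else base / q

        if not _resolve(self.codebook).exists():
            raise PipelineError(f"codebook path does not exist: {self.codebook}")
        if self.regions and not _resolve(self.regions).exists():
            raise PipelineError(f"regions path does not exist: {self.regions}")
        for r in self.replicates:
            if not (r.spots or r.images):
                raise PipelineError(f"replicate {r.replicate}: no spots or images")
            for p in (r.spots, r.images, r.dapi):
                if p and not _resolve(p).exists():
                    raise PipelineError(f"replicate {r.replicate}: missing {p}")
        for name in ("whole_min_variant_reads", "region_min_reads",
                     "marker_min_cells", "class_min_cells"):
            if getattr(self, name) < 1:
                raise PipelineError(f"filter {name} must be a positive integer")
        # paths become absolute so the run directory can live anywhere
        self.codebook = str(_resolve(self.codebook))
        if self.regions:
            self.regions = str(_resolve(self.regions))
        for r in self.replicates:
            r.spots = str(_resolve(r.spots)) if r.spots else None
            r.images = str(_resolve(r.images)) if r.images else None
            r.dapi = str(_resolve(r.dapi)) if r.dapi else None


def load_cycle_images(directory, n_cycles: int, dapi_path=None) -> CycleImageSet:
    """Load ``cycle{c}_{base}.tif`` images (c 1-based) plus DAPI from a directory."""
    directory = Path(directory)
    channels = []
    for c in range(1, n_cycles + 1):
        cyc = []
        for base in ALPHABET:
            p = directory / f"cycle{c}_{base}.tif"
            if not p.exists():
                raise PipelineError(f"missing channel image {p}")
            cyc.append(tifffile.imread(p).astype(float))
        channels.append(cyc)
    dapi_path = dapi_path or (directory / "dapi.tif")
    dapi = tifffile.imread(dapi_path).astype(float) if Path(dapi_path).exists() else None
    return CycleImageSet(dapi=dapi, channels=channels)


def _decode_replicate(rep: ReplicateInput, cb: Codebook, cfg: RunConfig):
    threshold = None if cfg.threshold == "auto" else float(cfg.threshold)
    if rep.spots:
        spots = pd.read_csv(rep.spots)
        reads, info = decode_spot_table(
            spots, cb, threshold=threshold, expected_fraction=cfg.expected_fraction
        )
    else:
        images = load_cycle_images(rep.images, cb.n_cycles, dapi_path=rep.dapi)
        params = DecodeParams(
            threshold=threshold,
            expected_fraction=cfg.expected_fraction,
            **cfg.decode_params,
        )
        reads, info = decode_images(images, cb, params)
    return reads, info


def _segment_replicate(rep: ReplicateInput, cfg: RunConfig) -> CellLabelMap | None:
    if not rep.dapi:
        return None
    dapi = tifffile.imread(rep.dapi).astype(float)
    nuclei = segment_nuclei(
        dapi, min_area=cfg.min_nucleus_area, max_area=cfg.max_nucleus_area
    )
    return expand_cells(nuclei, distance=cfg.expansion_distance)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: decode each replicate, segment its DAPI and assign reads to
    cells and regions, pool replicates, apply the whole-tissue site filter,
    compute regional levels and ratios, marker- and class-stratified
    levels, the mixed-cell observed/expected analysis, and region-wise
    rank statistics for retained sites.  Any stage failure aborts with the
    stage name.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cb = load_codebook(cfg.codebook)
    regions = load_regions(cfg.regions) if cfg.regions else {}

    all_reads = []
    all_cells = []
    log: dict = {"version": __version__, "seed": cfg.seed, "replicates": {}}
    for rep in cfg.replicates:
        stage_name = f"decode[{rep.replicate}]"
        try:
            reads, info = _decode_replicate(rep, cb, cfg)
        except Exception as e:  # noqa: BLE001 - annotate failing stage
            raise PipelineError(f"stage {stage_name} failed: {e}") from e
        stage_name = f"segment[{rep.replicate}]"
        try:
            cells = _segment_replicate(rep, cfg)
            if cells is not None:
                reads = assign_reads(reads, cells, regions)
            else:
                from .segment import assign_regions

                reads = reads.copy()
                reads["cell_id"] = 0
                reads["region"] = assign_regions(
                    reads["x"].to_numpy(float), reads["y"].to_numpy(float), regions
                )
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage {stage_name} failed: {e}") from e
        reads["replicate"] = rep.replicate
        reads["stage"] = rep.stage
        # globally unique cell ids across replicates (0 stays unassigned)
        reads["cell_uid"] = np.where(
            reads["cell_id"] > 0,
            rep.replicate + ":" + reads["cell_id"].astype(str),
            "",
        )
        all_reads.append(reads)
        if cells is not None:
            cdf = cells.cells.copy()
            cdf["replicate"] = rep.replicate
            cdf["stage"] = rep.stage
            cdf["cell_uid"] = rep.replicate + ":" + cdf["cell_id"].astype(str)
            all_cells.append(cdf)
        log["replicates"][rep.replicate] = info

    reads = pd.concat(all_reads, ignore_index=True)
    reads.to_csv(outdir / "reads_assigned.csv", index=False)
    cells_df = (
        pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    )
    if len(cells_df):
        cells_df.to_csv(outdir / "cells.csv", index=False)

    # ---- whole-tissue editing and the 500-read site filter ----
    whole = quant.variant_counts(reads, cb, by=["replicate", "stage"])
    whole.to_csv(outdir / "whole_counts.csv", index=False)
    retained, site_qc = quant.whole_brain_site_filter(
        whole, min_reads=cfg.whole_min_variant_reads
    )
    site_qc.to_csv(outdir / "site_qc.csv", index=False)
    whole_kept = whole[whole["site_id"].isin(retained)].copy()
    whole_kept["stratum"] = "whole"
    whole_kept["qc"] = ""
    whole_agg = quant.aggregate_replicates(
        whole_kept, by=["site_id", "stage", "stratum"]
    )
    whole_agg.to_csv(outdir / "whole_editing.csv", index=False)

    # ---- regional levels and editing ratios ----
    if regions:
        regional = quant.regional_counts(
            reads, cb, list(regions), min_reads=cfg.region_min_reads
        )
        regional = regional[regional["site_id"].isin(retained)]
        regional.to_csv(outdir / "regional_counts.csv", index=False)
        ratios = quant.regional_editing_ratios(regional)
        ratios.to_csv(outdir / "regional_ratios.csv", index=False)
    else:
        regional = pd.DataFrame()
        ratios = pd.DataFrame()

    # ---- cell tables, marker classification, marker editing ----
    marker_rows = []
    class_rows = []
    mixed_rows = []
    if len(cells_df):
        reads_ct = reads.copy()
        reads_ct["cell_id"] = reads_ct["cell_uid"].where(reads_ct["cell_uid"] != "", 0)
        cell_counts = ct.build_cell_table(reads_ct)
        classification = ct.classify_cells(cell_counts, cb)
        cell_meta = cells_df.rename(columns={"cell_id": "nucleus_label"}).rename(
            columns={"cell_uid": "cell_id"}
        )[["cell_id", "replicate", "stage"]]
        rep_of = cell_meta.set_index("cell_id")["replicate"]
        markers = [e.target_name for e in cb.markers()]
        for site in retained:
            for marker in markers:
                pos = ct.marker_editing(
                    cell_counts, classification, cb, site, marker,
                    replicates=rep_of, min_cells=cfg.marker_min_cells,
                )
                neg = ct.marker_negative_editing(
                    cell_counts, classification, cb, site, marker
                )
                pos["level_negative"] = neg["level"]
                pos["ratio"] = ct.marker_editing_ratio(pos["level"], neg["level"])
                marker_rows.append(pos)
            class_rows.append(
                ct.class_temporal_editing(
                    cell_counts, classification, cb, site, cell_meta,
                    min_cells_per_replicate=cfg.class_min_cells,
                )
            )
            # mixed-cell analysis per stage
            for stage in sorted(set(cell_meta["stage"])):
                stage_cells = set(
                    cell_meta.loc[cell_meta["stage"] == stage, "cell_id"]
                )
                cc = cell_counts[cell_counts["cell_id"].isin(stage_cells)]
                site_cc = ct._site_cell_counts(cc, cb, site)
                s = mx.site_mixed_stats(site_cc, site)
                mixed_rows.append(
                    {
                        "site_id": site,
                        "stage": stage,
                        "n_cells_ge2": s.n_cells_ge2,
                        "observed": s.observed_mixed,
                        "expected": s.expected_mixed,
                        "deviation": s.deviation,
                        "under_represented": s.observed_mixed < s.expected_mixed
                        if not np.isnan(s.deviation)
                        else None,
                    }
                )
    marker_editing = pd.DataFrame(marker_rows)
    if len(marker_editing):
        marker_editing.to_csv(outdir / "marker_editing.csv", index=False)
    class_editing = (
        pd.concat(class_rows, ignore_index=True) if class_rows else pd.DataFrame()
    )
    if len(class_editing):
        class_editing.to_csv(outdir / "class_editing.csv", index=False)
    mixed_df = pd.DataFrame(mixed_rows)
    if len(mixed_df):
        mixed_df.to_csv(outdir / "mixed_cells.csv", index=False)

    # ---- region-wise rank statistics per retained site ----
    stat_rows = []
    if len(regional):
        per_rep = regional[
            regional["stratum"].str.startswith("region:") & (regional["qc"] == "")
        ].copy()
        per_rep["region"] = per_rep["stratum"].str.removeprefix("region:")
        for site, grp in per_rep.groupby("site_id", observed=True):
            res = gstats.group_comparison(grp, "region", "level")
            pw = res["pairwise"]
            pw = pw.assign(site_id=site, H=res["H"], p_omnibus=res["p_omnibus"])
            stat_rows.append(pw)
    stats_df = (
        pd.concat(stat_rows, ignore_index=True) if stat_rows else pd.DataFrame()
    )
    if len(stats_df):
        stats_df.to_csv(outdir / "regional_stats.csv", index=False)

    summary = {
        "n_sites_total": len(cb.site_ids),
        "n_sites_retained": len(retained),
        "retained_sites": retained,
        "n_reads": int(len(reads)),
        "n_reads_pass_qc": int(reads["pass_qc"].sum()),
        "n_cells": int(len(cells_df)),
        "regions": list(regions),
    }
    log["summary"] = summary
    log["config"] = {
        k: v for k, v in dataclasses.asdict(cfg).items() if k != "replicates"
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return outdir
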