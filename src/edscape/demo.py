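"""Shipped synthetic demo: a small multi-replicate run with known truth.

The demo emulates the study's structure at desk scale: a 22-site codebook
(15 sites with enough coverage to clear the 500-read whole-tissue filter,
7 deliberately scarce), ten cell-class markers, three ADAR probe groups,
four named regions with region-dependent editing probabilities, and three
replicates of one developmental stage.  Read depth per cell is set far
above the tissue's 1.9-6.2 reads/cell so that a few hundred simulated
cells carry enough reads for the coverage filters that real sections clear
with tens of thousands of cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml
from shapely.geometry import box

from .scene import (
    CellClassSpec,
    EditingProbTable,
    SceneConfig,
    make_codebook,
    render_dapi,
    simulate_scene,
)
from .segment import save_regions

DEMO_REGIONS = ("thalamus", "neocortex", "hippocampus", "hypothalamus")

DEMO_CLASSES = (
    CellClassSpec("interneuron", ("Sst", "Pvalb", "Vip", "Cck", "Nrn1"), 0.3),
    CellClassSpec("pyramidal", ("Pcp4", "Ndnf"), 0.3),
    CellClassSpec("oligodendrocyte", ("Plp1", "Enpp2"), 0.25),
    CellClassSpec("astrocyte", ("Gfap",), 0.15),
)

N_SITES = 22
N_COVERED_SITES = 15  # sites expected to clear the 500-read filter


def demo_regions(image_shape=(900, 900)) -> dict:
    """Four disjoint rectangular ROIs with an unannotated border strip."""
    h, w = image_shape
    m = 40  # outside-ROI margin
    cx, cy = w // 2, h // 2
    g = 6  # gap between ROIs so they are strictly disjoint
    return {
        "thalamus": box(m, m, cx - g, cy - g),
        "neocortex": box(cx + g, m, w - m, cy - g),
        "hippocampus": box(m, cy + g, cx - g, h - m),
        "hypothalamus": box(cx + g, cy + g, w - m, h - m),
    }


def demo_editing_probs(site_ids, covered) -> EditingProbTable:
    """Region-structured probabilities: thalamus runs ~0.1 above the rest."""
    table = {}
    for i, site in enumerate(site_ids):
        base = 0.40 + 0.02 * (i % 11)  # 0.40 .. 0.60
        if site in covered:
            table[(site, "*", "*")] = base
            table[(site, "thalamus", "*")] = min(0.95, base + 0.10)
        else:
            table[(site, "*", "*")] = base
    return EditingProbTable(table)


def demo_scene_config(seed: int = 0, n_cells: int = 300,
                      reads_per_cell_mean: float = 110.0) -> SceneConfig:
    cb = make_codebook(n_sites=N_SITES, seed=seed)
    sites = cb.site_ids
    covered = set(sites[:N_COVERED_SITES])
    weights = {s: (1.0 if s in covered else 0.02) for s in sites}
    shape = (900, 900)
    return SceneConfig(
        codebook=cb,
        image_shape=shape,
        n_cells=n_cells,
        nucleus_radius_px=6.0,
        cell_classes=DEMO_CLASSES,
        regions=demo_regions(shape),
        editing_probs=demo_editing_probs(sites, covered),
        site_weights=weights,
        marker_read_fraction=0.2,
        adar_read_fraction=0.1,
        reads_per_cell_mean=reads_per_cell_mean,
        noise_sd=5.0,
        unmatched_read_rate=0.02,
        seed=seed,
    )


def write_demo_run(outdir, seed: int = 0, n_replicates: int = 3,
                   render_images: bool = False) -> Path:
    """Write a complete demo run directory with a ready ``run.yaml``.

    Each replicate gets its own scene (seed offset per replicate), a
    spot-intensity CSV, a DAPI TIFF for segmentation and the ground-truth
    tables; the shared codebook and region polygons sit at the top level.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg0 = demo_scene_config(seed=seed)
    cfg0.codebook.save(outdir / "codebook.csv")
    save_regions(cfg0.regions, outdir / "regions.geojson")

    replicates = []
    for i in range(n_replicates):
        rep = f"rep{i + 1}"
        rdir = outdir / rep
        rdir.mkdir(exist_ok=True)
        cfg = demo_scene_config(seed=seed)
        cfg.seed = seed + 1 + i
        spots, truth = simulate_scene(cfg)
        spots.to_csv(rdir / "spots.csv", index=False)
        truth.cells.to_csv(rdir / "truth_cells.csv", index=False)
        truth.reads.to_csv(rdir / "truth_reads.csv", index=False)
        truth.editing_probs.to_csv(rdir / "truth_editing_probs.csv", index=False)
        dapi = render_dapi(truth, cfg)
        tifffile.imwrite(rdir / "dapi.tif", dapi.astype(np.uint16))
        if render_images:
            from .scene import render_scene, save_scene

            images = render_scene(spots, truth, cfg)
            save_scene(rdir, spots, truth, images)
        replicates.append(
            {
                "replicate": rep,
                "stage": "adult",
                "spots": f"{rep}/spots.csv",
                "dapi": f"{rep}/dapi.tif",
            }
        )

    run_cfg = {
        "codebook": "codebook.csv",
        "regions": "regions.geojson",
        "output_dir": str(outdir / "results"),
        "seed": seed,
        "threshold": 0.4,
        "replicates": replicates,
    }
    (outdir / "run.yaml").write_text(yaml.safe_dump(run_cfg, sort_keys=False))
    return outdir
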