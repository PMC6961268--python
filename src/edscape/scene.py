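"""Synthetic in situ sequencing scenes with known ground truth.

The generator emulates the statistical structure of a barcoded padlock-probe
ISS experiment on a tissue section: DAPI-stained nuclei scattered in 2D,
named anatomical regions given as polygons, cells belonging to classes with
class-specific marker expression, per-cell read counts that are Poisson, and
reads that are either markers, ADAR-family probes, or the edited/unedited
variant of an editing site drawn with a per-(site, region, class) editing
probability.  Each read produces one rolling-circle amplicon whose per-cycle
four-channel intensities follow a simple signal/background model with
optional channel crosstalk and additive Gaussian noise.

Everything is driven by one integer seed and is bit-reproducible; the
returned :class:`SceneTruth` carries every latent variable so that decoding,
segmentation, assignment and quantification can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon

from .codebook import ALPHABET, Codebook, CodebookEntry

#: soma expansion distance used throughout (pixels beyond the nucleus border)
SOMA_EXPANSION_PX = 20.0

NO_REGION = "NONE"


class SceneError(ValueError):
    pass


@dataclass(frozen=True)
class CellClassSpec:
    """One simulated cell class: its name, marker targets and abundance."""

    name: str
    marker_targets: tuple[str, ...]
    proportion: float


class EditingProbTable:
    """Editing probability lookup keyed by (site_id, region, cell_class).

    Keys may use ``"*"`` as a wildcard for region and/or class; resolution
    order is exact, (site, region, *), (site, *, class), (site, *, *).
    """

    def __init__(self, table: dict[tuple[str, str, str], float]):
        for key, p in table.items():
            if not (0.0 <= p <= 1.0):
                raise SceneError(f"editing probability {p} for {key} outside [0,1]")
        self.table = dict(table)

    def prob(self, site_id: str, region: str, cell_class: str) -> float:
        for key in (
            (site_id, region, cell_class),
            (site_id, region, "*"),
            (site_id, "*", cell_class),
            (site_id, "*", "*"),
        ):
            if key in self.table:
                return self.table[key]
        raise KeyError(f"no editing probability for site {site_id!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site_id": s, "region": r, "cell_class": c, "prob": p}
            for (s, r, c), p in sorted(self.table.items())
        ]
        return pd.DataFrame(rows, columns=["site_id", "region", "cell_class", "prob"])

    @classmethod
    def uniform(cls, site_ids, p: float) -> "EditingProbTable":
        return cls({(s, "*", "*"): p for s in site_ids})


@dataclass
class SceneConfig:
    """Full specification of a synthetic scene.

    Parameters mirror the study conditions: ~4-nt barcodes over 4 cycles,
    Poisson read counts per cell (the tissue averaged 1.9-6.2 reads/cell;
    simulations default higher so strata clear the coverage filters), a
    20 px soma expansion, and four named regions when regional analysis is
    exercised.
    """

    codebook: Codebook
    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 200
    nucleus_radius_px: float = 6.0
    cell_classes: tuple[CellClassSpec, ...] = ()
    regions: dict[str, Polygon] = field(default_factory=dict)
    editing_probs: EditingProbTable | None = None
    site_weights: dict[str, float] | None = None  # default: equal weight 1 per site
    marker_read_fraction: float = 0.2  # share of reads that are class markers
    adar_read_fraction: float = 0.0  # share of reads that are ADAR-family probes
    reads_per_cell_mean: float = 5.0
    signal_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    crosstalk: np.ndarray | None = None  # 4x4, identity = none
    unmatched_read_rate: float = 0.0
    min_spot_spacing: float = 0.0  # enforce a global minimum spot distance if > 0
    min_nucleus_spacing: float | None = None  # default 2*nucleus_radius_px
    soma_guard_px: float = 1.0  # reads stay this far inside the nominal soma rim
    dapi_intensity: float = 200.0
    spot_sigma_px: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if self.n_cells < 0 or self.nucleus_radius_px <= 0:
            raise SceneError("n_cells must be >= 0 and nucleus_radius_px > 0")
        if self.cell_classes:
            total = sum(c.proportion for c in self.cell_classes)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise SceneError(f"cell class proportions sum to {total}, not 1")
        for name, poly in self.regions.items():
            if not poly.is_simple or not poly.is_valid:
                raise SceneError(f"region {name!r} is not a simple polygon")
            minx, miny, maxx, maxy = poly.bounds
            if minx < 0 or miny < 0 or maxx > w or maxy > h:
                raise SceneError(f"region {name!r} extends outside image bounds")
        if not (0.0 <= self.unmatched_read_rate <= 1.0):
            raise SceneError("unmatched_read_rate must be in [0,1]")
        if self.marker_read_fraction + self.adar_read_fraction > 1.0:
            raise SceneError("marker + adar read fractions exceed 1")
        if self.reads_per_cell_mean <= 0 or self.signal_intensity <= 0:
            raise SceneError("reads_per_cell_mean and signal_intensity must be > 0")
        if self.background_intensity < 0 or self.noise_sd < 0:
            raise SceneError("background_intensity and noise_sd must be >= 0")
        if self.crosstalk is not None:
            ct = np.asarray(self.crosstalk, dtype=float)
            if ct.shape != (4, 4) or (ct < 0).any():
                raise SceneError("crosstalk must be a nonnegative 4x4 matrix")

    @property
    def soma_radius_px(self) -> float:
        return self.nucleus_radius_px + SOMA_EXPANSION_PX


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene.

    ``cells``: cell_id, x, y (nucleus center), cell_class, region.
    ``reads``: spot_id, cell_id, x, y, target, site_id, edited, barcode,
    unmatched.  ``editing_probs``: the configured probability table.
    """

    cells: pd.DataFrame
    reads: pd.DataFrame
    editing_probs: pd.DataFrame


@dataclass
class CycleImageSet:
    """Rendered images: a DAPI channel plus, per cycle, four base channels.

    ``channels[c][b]`` is the image of base ``ALPHABET[b]`` in cycle ``c``
    (0-based); :meth:`general_stain` is the per-cycle channel sum, standing
    in for the anchor/general stain used for spot detection and alignment.
    """

    dapi: np.ndarray
    channels: list[list[np.ndarray]]

    @property
    def n_cycles(self) -> int:
        return len(self.channels)

    def general_stain(self, cycle: int) -> np.ndarray:
        return sum(self.channels[cycle])


# ---------------------------------------------------------------------------
# fixture codebook generator
# ---------------------------------------------------------------------------

def make_codebook(
    n_sites: int = 22,
    marker_classes: dict[str, tuple[str, ...]] | None = None,
    adar_groups: tuple[str, ...] = ("Adar1", "Adar2", "Adar3"),
    barcode_length: int = 4,
    seed: int = 0,
) -> Codebook:
    """Generate a valid codebook with paired editing sites, markers and ADARs.

    Defaults mirror the study panel scale: 22 paired editing sites, ~10
    marker probes over four cell classes, and one probe group per ADAR
    enzyme.  Barcodes are drawn without replacement from the 4**L k-mers.
    """
    if marker_classes is None:
        marker_classes = {
            "interneuron": ("Sst", "Pvalb", "Vip", "Cck", "Nrn1"),
            "pyramidal": ("Pcp4", "Ndnf"),
            "oligodendrocyte": ("Plp1", "Enpp2"),
            "astrocyte": ("Gfap",),
        }
    rng = np.random.default_rng(seed)
    n_markers = sum(len(v) for v in marker_classes.values())
    n_needed = 2 * n_sites + n_markers + len(adar_groups)
    n_kmers = len(ALPHABET) ** barcode_length
    if n_needed > n_kmers:
        raise SceneError(f"need {n_needed} barcodes but only {n_kmers} exist")
    codes = rng.choice(n_kmers, size=n_needed, replace=False)
    barcodes = ["".join(ALPHABET[(c >> (2 * i)) & 3] for i in range(barcode_length))
                for c in codes]
    it = iter(barcodes)
    entries: list[CodebookEntry] = []
    for i in range(n_sites):
        site = f"site{i:02d}"
        entries.append(CodebookEntry(f"{site}_ed", next(it), "edited_variant", site_id=site))
        entries.append(CodebookEntry(f"{site}_un", next(it), "unedited_variant", site_id=site))
    for cls, targets in marker_classes.items():
        for t in targets:
            entries.append(CodebookEntry(t, next(it), "marker", cell_class=cls))
    for g in adar_groups:
        entries.append(CodebookEntry(g, next(it), "adar", transcript_group=g))
    return Codebook(entries)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centers at pairwise distance >= 2 r."""
    h, w = cfg.image_shape
    margin = cfg.soma_radius_px + 2.0
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise SceneError("cannot place nuclei: image too small for soma margin")
    spacing = max(2.0 * cfg.nucleus_radius_px, cfg.min_nucleus_spacing or 0.0)
    min_d2 = spacing**2
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(1000, cfg.n_cells * 2000)
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise SceneError("cannot place nuclei")
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_d2 for cx, cy in centers):
            centers.append((x, y))
    return np.asarray(centers, dtype=float).reshape(cfg.n_cells, 2)


def _region_of_point(x: float, y: float, regions: dict[str, Polygon]) -> str:
    pt = Point(x, y)
    for name, poly in regions.items():
        if poly.covers(pt):
            return name
    return NO_REGION


def _random_absent_barcode(rng, cb: Codebook, length: int) -> str:
    present = set(cb.barcodes)
    for _ in range(1000):
        bc = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if bc not in present:
            return bc
    raise SceneError("codebook saturates the barcode space; no absent barcode")


def simulate_scene(cfg: SceneConfig) -> tuple[pd.DataFrame, SceneTruth]:
    """Simulate one scene; returns (SpotTable, SceneTruth).

    The SpotTable is a DataFrame with spot_id, x, y and per-cycle,
    per-channel intensity columns ``cyc{c}_{base}`` (c 1-based).  Reads are
    placed uniformly in the soma disk (nucleus radius + 20 px), matching the
    downstream fixed-distance cell model so noiseless assignment is exact.
    """
    cfg.validate()
    cb = cfg.codebook
    L = cb.n_cycles
    rng = np.random.default_rng(cfg.seed)

    centers = _place_nuclei(cfg, rng)
    if cfg.cell_classes:
        names = [c.name for c in cfg.cell_classes]
        props = np.array([c.proportion for c in cfg.cell_classes], dtype=float)
        props = props / props.sum()
        classes = rng.choice(names, size=cfg.n_cells, p=props)
        markers_of = {c.name: c.marker_targets for c in cfg.cell_classes}
    else:
        classes = np.array(["*"] * cfg.n_cells)
        markers_of = {}
    regions = [
        _region_of_point(x, y, cfg.regions) for x, y in centers
    ]

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, cfg.n_cells + 1),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "cell_class": classes,
            "region": regions,
        }
    )

    site_ids = cb.site_ids
    weights = np.array(
        [(cfg.site_weights or {}).get(s, 1.0) for s in site_ids], dtype=float
    )
    if site_ids and weights.sum() <= 0:
        raise SceneError("site weights must have positive sum")
    site_p = weights / weights.sum() if site_ids else weights
    adar_targets = [e.target_name for e in cb.adar_entries()]
    probs = cfg.editing_probs or EditingProbTable.uniform(site_ids, 0.5)

    ct = (
        np.asarray(cfg.crosstalk, dtype=float)
        if cfg.crosstalk is not None
        else np.eye(4)
    )
    base_index = {b: i for i, b in enumerate(ALPHABET)}

    read_rows = []
    spot_id = 0
    placed_xy: list[tuple[float, float]] = []
    # guard band keeps rim reads inside the pixel-discretized expanded cell
    soma_r = max(cfg.nucleus_radius_px, cfg.soma_radius_px - cfg.soma_guard_px)
    for cell in cells.itertuples(index=False):
        n_reads = rng.poisson(cfg.reads_per_cell_mean)
        class_markers = markers_of.get(cell.cell_class, ())
        for _ in range(n_reads):
            u = rng.uniform()
            if class_markers and u < cfg.marker_read_fraction:
                target = class_markers[rng.integers(len(class_markers))]
                site, edited = None, None
            elif adar_targets and u < cfg.marker_read_fraction + cfg.adar_read_fraction:
                target = adar_targets[rng.integers(len(adar_targets))]
                site, edited = None, None
            elif site_ids:
                site = site_ids[rng.choice(len(site_ids), p=site_p)]
                p = probs.prob(site, cell.region, cell.cell_class)
                edited = bool(rng.uniform() < p)
                ed, un = cb.variant_entries(site)
                target = ed.target_name if edited else un.target_name
            else:
                continue
            barcode = cb.entry_for_target(target).barcode
            unmatched = bool(rng.uniform() < cfg.unmatched_read_rate)
            if unmatched:
                barcode = _random_absent_barcode(rng, cb, L)
                target, site, edited = None, None, None
            # uniform position in the soma disk; optional global min spacing
            for _attempt in range(200):
                r = soma_r * math.sqrt(rng.uniform())
                theta = rng.uniform(0.0, 2.0 * math.pi)
                x = cell.x + r * math.cos(theta)
                y = cell.y + r * math.sin(theta)
                if cfg.min_spot_spacing <= 0:
                    break
                d2min = cfg.min_spot_spacing**2
                if all(
                    (x - px) ** 2 + (y - py) ** 2 >= d2min for px, py in placed_xy
                ):
                    break
            else:
                continue  # crowded neighbourhood: drop the read
            if cfg.min_spot_spacing > 0:
                placed_xy.append((x, y))
            spot_id += 1
            read_rows.append(
                {
                    "spot_id": spot_id,
                    "cell_id": cell.cell_id,
                    "x": x,
                    "y": y,
                    "target": target,
                    "site_id": site,
                    "edited": edited,
                    "barcode": barcode,
                    "unmatched": unmatched,
                }
            )

    reads = pd.DataFrame(
        read_rows,
        columns=[
            "spot_id", "cell_id", "x", "y", "target", "site_id",
            "edited", "barcode", "unmatched",
        ],
    )

    # per-cycle intensities: one-hot signal + background, crosstalk, noise
    n = len(reads)
    intensities = np.zeros((n, L, 4))
    if n:
        codes = np.array(
            [[base_index[b] for b in bc] for bc in reads["barcode"]], dtype=int
        )
        base_vecs = np.full((n, L, 4), cfg.background_intensity, dtype=float)
        rows = np.arange(n)[:, None]
        cyc = np.arange(L)[None, :]
        base_vecs[rows, cyc, codes] = cfg.signal_intensity
        intensities = np.einsum("ij,nlj->nli", ct, base_vecs)
        if cfg.noise_sd > 0:
            intensities = intensities + rng.normal(
                0.0, cfg.noise_sd, size=intensities.shape
            )
        intensities = np.clip(intensities, 0.0, None)

    spot_cols = {"spot_id": reads["spot_id"], "x": reads["x"], "y": reads["y"]}
    for c in range(L):
        for b, base in enumerate(ALPHABET):
            spot_cols[f"cyc{c + 1}_{base}"] = intensities[:, c, b] if n else []
    spots = pd.DataFrame(spot_cols)

    truth = SceneTruth(cells=cells, reads=reads, editing_probs=probs.to_frame())
    return spots, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _stamp_gaussian(img: np.ndarray, x: float, y: float, amp: float, sigma: float):
    """Add a 2D Gaussian of peak ``amp`` at (x, y) into ``img`` (in place)."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    xi, yi = int(round(x)), int(round(y))
    x0, x1 = max(0, xi - half), min(w, xi + half + 1)
    y0, y1 = max(0, yi - half), min(h, yi + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2))
    img[y0:y1, x0:x1] += amp * g


def _stamp_disk(img: np.ndarray, x: float, y: float, radius: float, amp: float):
    """Set pixels within ``radius`` of (x, y) to ``amp`` (in place)."""
    h, w = img.shape
    half = int(math.ceil(radius)) + 1
    xi, yi = int(round(x)), int(round(y))
    x0, x1 = max(0, xi - half), min(w, xi + half + 1)
    y0, y1 = max(0, yi - half), min(h, yi + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    mask = ys[:, None] ** 2 + xs[None, :] ** 2 <= radius**2
    view = img[y0:y1, x0:x1]
    view[mask] = amp


def render_dapi(truth: SceneTruth, cfg: SceneConfig) -> np.ndarray:
    """DAPI image: Gaussian-blurred nucleus disks at the true centers."""
    h, w = cfg.image_shape
    dapi = np.zeros((h, w), dtype=float)
    for cell in truth.cells.itertuples(index=False):
        _stamp_disk(dapi, cell.x, cell.y, cfg.nucleus_radius_px, cfg.dapi_intensity)
    return np.clip(ndi.gaussian_filter(dapi, sigma=1.5), 0, 65535)


def render_scene(
    spots: pd.DataFrame, truth: SceneTruth, cfg: SceneConfig
) -> CycleImageSet:
    """Render a scene into a DAPI image and per-cycle channel images.

    Each spot contributes an isotropic Gaussian (sd ``cfg.spot_sigma_px``)
    whose peak equals the spot's channel intensity; DAPI is the union of
    blurred nucleus disks.  Values stay within a 16-bit range.
    """
    h, w = cfg.image_shape
    L = cfg.codebook.n_cycles
    xs = spots["x"].to_numpy(dtype=float) if len(spots) else np.empty(0)
    ys = spots["y"].to_numpy(dtype=float) if len(spots) else np.empty(0)
    if len(spots) and (
        (xs < 0).any() or (ys < 0).any() or (xs > w - 1).any() or (ys > h - 1).any()
    ):
        raise SceneError("spot outside image bounds")

    dapi = render_dapi(truth, cfg)

    channels: list[list[np.ndarray]] = []
    for c in range(L):
        cyc_imgs = []
        for base in ALPHABET:
            img = np.zeros((h, w), dtype=float)
            vals = spots[f"cyc{c + 1}_{base}"].to_numpy(dtype=float) if len(spots) else []
            for x, y, v in zip(xs, ys, vals):
                if v > 0:
                    _stamp_gaussian(img, x, y, v, cfg.spot_sigma_px)
            cyc_imgs.append(np.clip(img, 0, 65535))
        channels.append(cyc_imgs)
    return CycleImageSet(dapi=dapi, channels=channels)


# ---------------------------------------------------------------------------
# scene IO
# ---------------------------------------------------------------------------

def save_scene(
    outdir,
    spots: pd.DataFrame,
    truth: SceneTruth,
    images: CycleImageSet | None = None,
) -> None:
    """Write spot table and truth tables (CSV) and optionally TIFF images."""
    from pathlib import Path

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spots.to_csv(outdir / "spots.csv", index=False)
    truth.cells.to_csv(outdir / "truth_cells.csv", index=False)
    truth.reads.to_csv(outdir / "truth_reads.csv", index=False)
    truth.editing_probs.to_csv(outdir / "truth_editing_probs.csv", index=False)
    if images is not None:
        tifffile.imwrite(outdir / "dapi.tif", images.dapi.astype(np.uint16))
        for c, cyc in enumerate(images.channels, start=1):
            for base, img in zip(ALPHABET, cyc):
                tifffile.imwrite(
                    outdir / f"cycle{c}_{base}.tif", img.astype(np.uint16)
                )
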