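"""Barcode decoding from multi-cycle fluorescence: detection, base calling, QC.

The decoding chain mirrors the standard ISS image analysis: the general
stain is background-suppressed with a white top-hat and amplicons (RCPs)
are split by watershed; each cycle's merged signal image is aligned to the
reference by integer translation at the cross-correlation peak; per-spot,
per-cycle channel intensities are extracted with a small window maximum;
the base with the highest intensity is called each cycle, with per-base
quality ``max / sum`` over the four channels — bounded in [0.25, 1], 0.25
when all four channels are equal (pure ambiguity) and 1 when a single
channel carries all signal.  The read quality is the minimum base quality
over cycles, and reads are kept when the quality clears a threshold and the
barcode matches the codebook exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .codebook import ALPHABET, UNMATCHED, Codebook
from .scene import CycleImageSet

QUALITY_MIN = 0.25
QUALITY_MAX = 1.0

#: grid on which the expected-read-fraction threshold is calibrated
THRESHOLD_GRID = np.round(np.arange(0.25, 1.0 + 1e-9, 0.01), 2)


class DecodeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_translation(moving: np.ndarray, reference: np.ndarray) -> tuple[int, int]:
    """Integer translation (dx, dy) aligning ``moving`` onto ``reference``.

    The shift is the cross-correlation peak (FFT-based, no phase
    normalization), i.e. the integer translation maximizing correlation.
    Shifting ``moving`` by (dx, dy) (x = column, y = row) superimposes it on
    the reference.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2:
        raise DecodeError("registration requires two same-shape 2D images")
    if moving.std() == 0 or reference.std() == 0:
        raise DecodeError("registration undefined for a flat image")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=1, normalization=None
    )
    dy, dx = (int(round(s)) for s in shift)
    return dx, dy


def apply_translation(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Shift an image by integer (dx, dy), zero-filling exposed borders."""
    dx, dy = shift
    return ndi.shift(np.asarray(img, dtype=float), (dy, dx), order=0, cval=0.0)


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

def enhance_and_detect(
    general_stain: np.ndarray,
    tophat_radius: float = 3.0,
    min_intensity: float = 10.0,
    smooth_sigma: float = 1.0,
    min_distance: int = 2,
) -> pd.DataFrame:
    """Detect amplicon candidates on the general stain.

    White top-hat (disk structuring element) removes slowly varying
    background; a light Gaussian smooth stabilizes peak finding against
    pixel noise; local maxima above ``min_intensity`` seed a watershed on
    the inverted enhanced image so that merged spots are split, one spot
    per basin at the basin's intensity maximum.

    Returns a SpotTable skeleton with columns spot_id, x, y.
    """
    if tophat_radius <= 0:
        raise DecodeError("tophat_radius must be positive")
    img = np.asarray(general_stain, dtype=float)
    enhanced = white_tophat(img, footprint=disk(int(round(tophat_radius))))
    if smooth_sigma > 0:
        enhanced = ndi.gaussian_filter(enhanced, sigma=smooth_sigma)
    peaks = peak_local_max(
        enhanced,
        min_distance=min_distance,
        threshold_abs=min_intensity,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return pd.DataFrame(columns=["spot_id", "x", "y"])
    markers = np.zeros(img.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    mask = enhanced > min_intensity
    mask |= markers > 0
    basins = watershed(-enhanced, markers=markers, mask=mask)
    rows = []
    # one spot per basin; coordinate = basin intensity maximum (= its seed peak)
    maxima = ndi.maximum_position(
        enhanced, labels=basins, index=np.arange(1, len(peaks) + 1)
    )
    for i, (py, px) in enumerate(maxima, start=1):
        rows.append({"spot_id": i, "x": int(px), "y": int(py)})
    return pd.DataFrame(rows, columns=["spot_id", "x", "y"])


def extract_intensities(
    spots: pd.DataFrame,
    cycles: CycleImageSet,
    window_radius: int = 1,
) -> pd.DataFrame:
    """Fill per-cycle per-channel intensities into a coordinates-only SpotTable.

    The intensity is the channel maximum in a (2r+1)^2 window centred on the
    spot, robust to 1 px residual registration error.  Spots whose window is
    clipped at the image border are flagged ``clipped_window`` but still
    extracted.
    """
    out = spots.copy().reset_index(drop=True)
    n = len(out)
    L = cycles.n_cycles
    if n == 0:
        for c in range(L):
            for base in ALPHABET:
                out[f"cyc{c + 1}_{base}"] = pd.Series(dtype=float)
        out["clipped_window"] = pd.Series(dtype=bool)
        return out
    xi = np.rint(out["x"].to_numpy(dtype=float)).astype(int)
    yi = np.rint(out["y"].to_numpy(dtype=float)).astype(int)
    h, w = cycles.channels[0][0].shape
    if (xi < 0).any() or (yi < 0).any() or (xi >= w).any() or (yi >= h).any():
        raise DecodeError("spot coordinates outside image bounds")
    r = int(window_radius)
    out["clipped_window"] = (xi < r) | (yi < r) | (xi >= w - r) | (yi >= h - r)
    size = 2 * r + 1
    for c in range(L):
        for b, base in enumerate(ALPHABET):
            filt = ndi.maximum_filter(
                np.asarray(cycles.channels[c][b], dtype=float),
                size=size,
                mode="nearest",
            )
            out[f"cyc{c + 1}_{base}"] = filt[yi, xi]
    return out


# ---------------------------------------------------------------------------
# base calling
# ---------------------------------------------------------------------------

def call_bases(
    intensities: np.ndarray,
) -> tuple[str, np.ndarray, float]:
    """Call one spot's barcode from an (L, 4) intensity array.

    Per cycle the called base is the argmax channel (ties broken by the
    fixed channel order A<C<G<T); base quality is ``max / sum`` of the four
    channel intensities, and the read quality is the minimum base quality.
    Raises if any cycle has zero total intensity (uncallable spot).
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise DecodeError("intensities must be an (L, 4) array")
    if (arr < 0).any():
        raise DecodeError("negative intensity")
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        raise DecodeError("uncallable spot: cycle with zero total intensity")
    idx = arr.argmax(axis=1)  # first max wins: the A<C<G<T tie rule
    barcode = "".join(ALPHABET[i] for i in idx)
    base_q = arr.max(axis=1) / sums
    return barcode, base_q, float(base_q.min())


def call_reads(spots: pd.DataFrame, n_cycles: int) -> pd.DataFrame:
    """Vectorized base calling over a filled SpotTable.

    Adds ``barcode``, ``quality`` (read quality = min base quality over
    cycles) and ``callable`` (False for spots with an all-zero cycle, which
    are excluded from matching with that reason recorded).
    """
    out = spots.copy().reset_index(drop=True)
    n = len(out)
    if n == 0:
        out["barcode"] = pd.Series(dtype=str)
        out["quality"] = pd.Series(dtype=float)
        out["callable"] = pd.Series(dtype=bool)
        return out
    arr = np.stack(
        [
            np.stack(
                [out[f"cyc{c + 1}_{base}"].to_numpy(dtype=float) for base in ALPHABET],
                axis=1,
            )
            for c in range(n_cycles)
        ],
        axis=1,
    )  # (n, L, 4)
    if (arr < 0).any():
        raise DecodeError("negative intensity in spot table")
    sums = arr.sum(axis=2)
    ok = (sums > 0).all(axis=1)
    idx = arr.argmax(axis=2)
    letters = np.array(list(ALPHABET))
    barcodes = ["".join(row) for row in letters[idx]]
    base_q = np.where(sums > 0, arr.max(axis=2) / np.where(sums > 0, sums, 1), np.nan)
    quality = np.full(n, np.nan)
    if ok.any():
        quality[ok] = base_q[ok].min(axis=1)
    out["barcode"] = barcodes
    out["quality"] = quality
    out["callable"] = ok
    out.loc[~ok, "barcode"] = ""
    out.loc[~ok, "quality"] = np.nan
    return out


# ---------------------------------------------------------------------------
# matching and thresholding
# ---------------------------------------------------------------------------

def match_and_filter(
    reads: pd.DataFrame,
    cb: Codebook,
    threshold: float,
    require_match: bool = True,
) -> pd.DataFrame:
    """Match barcodes to the codebook and apply the quality threshold.

    ``pass_qc`` is True iff the read is callable, its quality >= threshold
    and (when ``require_match``) its barcode is in the codebook.  The filter
    conserves counts: n_total = n_pass + n_fail.
    """
    if not (QUALITY_MIN <= threshold <= QUALITY_MAX):
        raise DecodeError(f"threshold {threshold} outside [0.25, 1]")
    out = reads.copy()
    out["target"] = [
        cb.lookup(bc) if ok else UNMATCHED
        for bc, ok in zip(out["barcode"], out["callable"])
    ]
    matched = out["target"] != UNMATCHED
    good_q = out["callable"] & (out["quality"] >= threshold)
    out["pass_qc"] = good_q & (matched if require_match else True)
    return out


def filter_counts(reads: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping for a matched/filtered ReadTable (count conservation)."""
    n_total = len(reads)
    n_pass = int(reads["pass_qc"].sum())
    matched = reads["target"] != UNMATCHED
    return {
        "n_total": n_total,
        "n_pass": n_pass,
        "n_fail": n_total - n_pass,
        "n_unmatched": int((~matched).sum()),
    }


def calibrate_threshold(
    reads: pd.DataFrame,
    cb: Codebook,
    target_fraction: float = 0.95,
) -> tuple[float, bool]:
    """Smallest grid threshold achieving the expected-read fraction.

    The expected-read fraction at threshold t is (matched reads passing t)
    / (all reads passing t); the calibration returns the smallest t on the
    0.01 grid in [0.25, 1] reaching ``target_fraction`` (the assay used 95
    or 96%).  Returns ``(threshold, attained)``; when unattainable, (1.0,
    False).
    """
    if len(reads) == 0:
        raise DecodeError("cannot calibrate threshold with no reads")
    matched = np.array([cb.lookup(bc) != UNMATCHED for bc in reads["barcode"]])
    quality = reads["quality"].to_numpy(dtype=float)
    ok = reads["callable"].to_numpy(dtype=bool)
    for t in THRESHOLD_GRID:
        passing = ok & (quality >= t)
        n_pass = passing.sum()
        if n_pass == 0:
            continue
        frac = matched[passing].sum() / n_pass
        if frac >= target_fraction:
            return float(t), True
    return 1.0, False


# ---------------------------------------------------------------------------
# end-to-end image decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodeParams:
    tophat_radius: float = 3.0
    min_intensity: float = 10.0
    smooth_sigma: float = 1.0
    window_radius: int = 1
    threshold: float | None = 0.4  # None = calibrate from expected fraction
    expected_fraction: float = 0.95
    require_match: bool = True


def decode_images(
    images: CycleImageSet, cb: Codebook, params: DecodeParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full decode from rendered/acquired cycle images.

    Registers each cycle's merged signal to the first cycle's general
    stain, detects spots on the reference stain, extracts window-max
    intensities from the registered channels, calls bases, matches the
    codebook and applies the (fixed or calibrated) quality threshold.
    Returns the ReadTable and a small info dict (shifts, threshold, counts).
    """
    params = params or DecodeParams()
    reference = images.general_stain(0)
    registered: list[list[np.ndarray]] = []
    shifts = []
    for c in range(images.n_cycles):
        merged = images.general_stain(c)
        dx, dy = register_translation(merged, reference)
        shifts.append((dx, dy))
        registered.append(
            [apply_translation(ch, (dx, dy)) for ch in images.channels[c]]
        )
    reg_set = CycleImageSet(dapi=images.dapi, channels=registered)
    spots = enhance_and_detect(
        reference,
        tophat_radius=params.tophat_radius,
        min_intensity=params.min_intensity,
        smooth_sigma=params.smooth_sigma,
    )
    spots = extract_intensities(spots, reg_set, window_radius=params.window_radius)
    reads = call_reads(spots, cb.n_cycles)
    if params.threshold is None:
        threshold, attained = calibrate_threshold(reads, cb, params.expected_fraction)
    else:
        threshold, attained = float(params.threshold), True
    reads = match_and_filter(reads, cb, threshold, require_match=params.require_match)
    info = {
        "shifts": shifts,
        "threshold": threshold,
        "threshold_attained": attained,
        **filter_counts(reads),
    }
    return reads, info


def decode_spot_table(
    spots: pd.DataFrame,
    cb: Codebook,
    threshold: float | None = 0.4,
    expected_fraction: float = 0.95,
    require_match: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Decode a pre-extracted spot-intensity table (no image stage)."""
    reads = call_reads(spots, cb.n_cycles)
    if threshold is None:
        thr, attained = calibrate_threshold(reads, cb, expected_fraction)
    else:
        thr, attained = float(threshold), True
    reads = match_and_filter(reads, cb, thr, require_match=require_match)
    info = {"threshold": thr, "threshold_attained": attained, **filter_counts(reads)}
    return reads, info
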