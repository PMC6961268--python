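import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from edscape.codebook import ALPHABET, UNMATCHED
from edscape.decode import (
    DecodeError,
    calibrate_threshold,
    call_bases,
    call_reads,
    enhance_and_detect,
    extract_intensities,
    match_and_filter,
    register_translation,
)
from edscape.scene import (
    CycleImageSet,
    EditingProbTable,
    SceneConfig,
    _stamp_gaussian,
    render_scene,
    simulate_scene,
)


def _spot_image(rng, shape=(200, 200), n=40, amp=100.0):
    img = np.zeros(shape)
    for x, y in rng.uniform(30, shape[0] - 30, size=(n, 2)):
        _stamp_gaussian(img, x, y, amp, 1.5)
    return img


class TestRegistration:
    def test_identical_images_give_zero_shift(self, rng):
        img = _spot_image(rng)
        assert register_translation(img, img) == (0, 0)

    def test_known_shift_recovered(self, rng):
        img = _spot_image(rng)
        moving = ndi.shift(img, (-2, 3), order=0, cval=0.0)  # (dy, dx) = (-2, 3)
        assert register_translation(moving, img) == (-3, 2)

    def test_flat_image_rejected(self):
        with pytest.raises(DecodeError, match="registration undefined"):
            register_translation(np.zeros((10, 10)), np.ones((10, 10)))


class TestDetection:
    def test_uniform_image_yields_no_spots(self):
        spots = enhance_and_detect(np.full((64, 64), 7.0), min_intensity=1.0)
        assert len(spots) == 0

    def test_single_spot_found_at_peak(self):
        img = np.zeros((64, 64))
        _stamp_gaussian(img, 30, 22, 100.0, 1.5)
        spots = enhance_and_detect(img, min_intensity=10.0)
        assert len(spots) == 1
        assert (spots.loc[0, "x"], spots.loc[0, "y"]) == (30, 22)

    def test_two_close_spots_split(self):
        img = np.zeros((64, 64))
        _stamp_gaussian(img, 20, 32, 100.0, 1.5)
        _stamp_gaussian(img, 30, 32, 100.0, 1.5)
        spots = enhance_and_detect(img, min_intensity=10.0)
        assert len(spots) == 2
        found = sorted(zip(spots["x"], spots["y"]))
        for (fx, fy), (tx, ty) in zip(found, [(20, 32), (30, 32)]):
            assert abs(fx - tx) <= 1 and abs(fy - ty) <= 1

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DecodeError):
            enhance_and_detect(np.zeros((8, 8)), tophat_radius=0)


class TestExtraction:
    def _render_single(self, intensities):
        channels = []
        for c in range(1):
            cyc = []
            for v in intensities:
                img = np.zeros((64, 64))
                if v > 0:
                    _stamp_gaussian(img, 30, 22, v, 1.5)
                cyc.append(img)
            channels.append(cyc)
        return CycleImageSet(dapi=np.zeros((64, 64)), channels=channels)

    def test_render_extract_round_trip(self):
        images = self._render_single((100.0, 10.0, 10.0, 10.0))
        spots = pd.DataFrame({"spot_id": [1], "x": [30], "y": [22]})
        filled = extract_intensities(spots, images)
        got = [filled.loc[0, f"cyc1_{b}"] for b in ALPHABET]
        assert np.allclose(got, (100, 10, 10, 10), rtol=0.01)
        assert not filled.loc[0, "clipped_window"]

    def test_border_spot_flagged_but_extracted(self):
        images = self._render_single((50.0, 0.0, 0.0, 0.0))
        spots = pd.DataFrame({"spot_id": [1], "x": [0], "y": [0]})
        filled = extract_intensities(spots, images)
        assert bool(filled.loc[0, "clipped_window"])
        assert filled.loc[0, "cyc1_A"] >= 0

    def test_empty_table_passes_through(self, minimal_codebook):
        images = self._render_single((0.0, 0.0, 0.0, 0.0))
        spots = pd.DataFrame(columns=["spot_id", "x", "y"])
        filled = extract_intensities(spots, images)
        assert len(filled) == 0
        assert "cyc1_A" in filled.columns


class TestBaseCalling:
    def test_all_equal_cycle_has_quality_quarter(self):
        barcode, base_q, read_q = call_bases(np.array([[1.0, 1.0, 1.0, 1.0]]))
        assert read_q == pytest.approx(0.25)
        assert barcode == "A"  # tie broken by fixed channel order

    def test_single_channel_cycle_has_quality_one(self):
        barcode, base_q, read_q = call_bases(np.array([[10.0, 0.0, 0.0, 0.0]]))
        assert barcode == "A"
        assert read_q == pytest.approx(1.0)

    def test_read_quality_is_minimum_base_quality(self):
        # maxima land on channels A, C, G, T; worst cycle 4/10 = 0.4
        arr = np.array(
            [
                [4.0, 2.0, 2.0, 2.0],
                [1.0, 9.0, 0.0, 0.0],
                [0.0, 1.0, 9.0, 0.0],
                [0.0, 0.0, 1.0, 9.0],
            ]
        )
        barcode, base_q, read_q = call_bases(arr)
        assert barcode == "ACGT"
        assert read_q == pytest.approx(0.4)
        assert base_q[0] == pytest.approx(0.4)

    def test_zero_cycle_uncallable(self):
        with pytest.raises(DecodeError, match="uncallable"):
            call_bases(np.array([[0.0, 0.0, 0.0, 0.0]]))

    def test_vectorized_calling_flags_uncallable_rows(self):
        spots = pd.DataFrame(
            {
                "spot_id": [1, 2],
                "x": [0, 0],
                "y": [0, 0],
                "cyc1_A": [5.0, 0.0],
                "cyc1_C": [1.0, 0.0],
                "cyc1_G": [0.0, 0.0],
                "cyc1_T": [0.0, 0.0],
            }
        )
        reads = call_reads(spots, n_cycles=1)
        assert reads.loc[0, "callable"] and reads.loc[0, "barcode"] == "A"
        assert not reads.loc[1, "callable"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=4,
        ).filter(lambda v: sum(v) > 0)
    )
    def test_quality_bounds_property(self, vec):
        """Base quality lies in [0.25, 1] for any nonnegative 4-vector."""
        _, base_q, read_q = call_bases(np.array([vec]))
        assert 0.25 - 1e-12 <= read_q <= 1.0 + 1e-12
        if len(set(vec)) == 1:
            assert read_q == pytest.approx(0.25)
        if sum(v > 0 for v in vec) == 1:
            assert read_q == pytest.approx(1.0)


class TestMatchFilter:
    def _reads(self, qualities, barcodes):
        return pd.DataFrame(
            {
                "spot_id": range(1, len(qualities) + 1),
                "barcode": barcodes,
                "quality": qualities,
                "callable": [True] * len(qualities),
            }
        )

    def test_threshold_boundary_is_inclusive(self, minimal_codebook):
        reads = self._reads([0.34, 0.35], ["AAGC", "AAGC"])
        out = match_and_filter(reads, minimal_codebook, 0.35)
        assert list(out["pass_qc"]) == [False, True]

    def test_unmatched_read_never_passes(self, minimal_codebook):
        reads = self._reads([1.0], ["TTTT"])
        out = match_and_filter(reads, minimal_codebook, 0.25)
        assert out.loc[0, "target"] == UNMATCHED
        assert not out.loc[0, "pass_qc"]

    def test_threshold_out_of_range_rejected(self, minimal_codebook):
        with pytest.raises(DecodeError):
            match_and_filter(self._reads([0.5], ["AAGC"]), minimal_codebook, 0.1)

    def test_count_conservation_and_monotonicity(self, minimal_codebook, rng):
        n = 500
        barcodes = rng.choice(["AAGC", "AAGT", "GGGG"], size=n)
        qualities = rng.uniform(0.25, 1.0, size=n)
        reads = self._reads(qualities, barcodes)
        last = None
        for thr in (0.3, 0.4, 0.5, 0.8):
            out = match_and_filter(reads, minimal_codebook, thr)
            n_pass = out["pass_qc"].sum()
            assert n_pass + (~out["pass_qc"]).sum() == n
            if last is not None:
                assert n_pass <= last  # raising threshold never adds reads
            last = n_pass


class TestCalibration:
    def test_all_matched_calibrates_to_grid_minimum(self, minimal_codebook):
        reads = pd.DataFrame(
            {"barcode": ["AAGC"] * 10, "quality": [0.9] * 10, "callable": True}
        )
        thr, attained = calibrate_threshold(reads, minimal_codebook, 0.95)
        assert thr == 0.25 and attained

    def test_unattainable_target_returns_one_with_warning(self, minimal_codebook):
        reads = pd.DataFrame(
            {"barcode": ["AAGC", "TTTT"], "quality": [1.0, 1.0], "callable": True}
        )
        thr, attained = calibrate_threshold(reads, minimal_codebook, 1.0)
        assert thr == 1.0 and not attained

    def test_no_reads_rejected(self, minimal_codebook):
        with pytest.raises(DecodeError):
            calibrate_threshold(
                pd.DataFrame(columns=["barcode", "quality", "callable"]),
                minimal_codebook,
            )

    def test_calibrated_threshold_achieves_target_on_noisy_scene(self, small_codebook):
        """Self-consistency: re-filtering at the returned threshold reaches 95%."""
        cfg = SceneConfig(
            codebook=small_codebook,
            image_shape=(800, 800),
            n_cells=150,
            reads_per_cell_mean=10.0,
            editing_probs=EditingProbTable.uniform(small_codebook.site_ids, 0.5),
            noise_sd=25.0,
            unmatched_read_rate=0.3,
            seed=4,
        )
        spots, _ = simulate_scene(cfg)
        # degrade unmatched reads: pure noise intensities, like spurious spots
        rng = np.random.default_rng(9)
        reads = call_reads(spots, small_codebook.n_cycles)
        thr, attained = calibrate_threshold(reads, small_codebook, 0.95)
        assert attained
        out = match_and_filter(reads, small_codebook, thr, require_match=False)
        passing = out[out["pass_qc"]]
        frac = (passing["target"] != UNMATCHED).mean()
        assert frac >= 0.95


def test_end_to_end_noiseless_decode_recall(small_codebook):
    """Rendered noiseless scene decodes with full recall and accuracy."""
    from scipy.spatial import cKDTree

    from edscape.decode import DecodeParams, decode_images

    cfg = SceneConfig(
        codebook=small_codebook,
        image_shape=(600, 600),
        n_cells=50,
        reads_per_cell_mean=6.0,
        editing_probs=EditingProbTable.uniform(small_codebook.site_ids, 0.5),
        min_spot_spacing=6.0,
        seed=3,
    )
    spots, truth = simulate_scene(cfg)
    images = render_scene(spots, truth, cfg)
    reads, info = decode_images(
        images, small_codebook, DecodeParams(min_intensity=20.0, threshold=0.4)
    )
    tree = cKDTree(truth.reads[["x", "y"]].to_numpy())
    d, idx = tree.query(reads[["x", "y"]].to_numpy())
    assert (d <= 2).all()
    matched = truth.reads.iloc[idx]
    assert (matched["target"].to_numpy() == reads["target"].to_numpy()).all()
    # and every true read was found
    back = cKDTree(reads[["x", "y"]].to_numpy())
    d2, _ = back.query(truth.reads[["x", "y"]].to_numpy())
    assert (d2 <= 2).all()
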