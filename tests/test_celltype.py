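import numpy as np
import pandas as pd
import pytest

from edscape.celltype import (
    build_cell_table,
    class_temporal_editing,
    classify_cells,
    marker_editing,
    marker_editing_ratio,
    marker_negative_editing,
)
from edscape.quant import QC_BELOW_20_CELLS, QC_BELOW_100_CELLS
from edscape.scene import (
    CellClassSpec,
    EditingProbTable,
    SceneConfig,
    simulate_scene,
)
from edscape.stats import kruskal_wallis


def _counts(rows):
    return pd.DataFrame(rows, columns=["cell_id", "target", "count"])


class TestClassify:
    def test_multiple_markers_give_multiple_classes(self, panel_codebook):
        counts = _counts([(1, "Sst", 1), (1, "Pcp4", 1)])
        out = classify_cells(counts, panel_codebook)
        assert out.loc[0, "marker_classes"] == frozenset(
            {"interneuron", "pyramidal"}
        )

    def test_no_marker_reads_give_empty_class_set(self, panel_codebook):
        counts = _counts([(1, "site00_ed", 3)])
        out = classify_cells(counts, panel_codebook)
        assert out.loc[0, "marker_classes"] == frozenset()

    def test_unknown_target_rejected(self, panel_codebook):
        with pytest.raises(ValueError, match="absent from codebook"):
            classify_cells(_counts([(1, "Mystery", 1)]), panel_codebook)

    def test_exclusive_markers_recover_true_classes(self, small_codebook):
        """Noise-free class-exclusive markers classify every cell correctly."""
        cfg = SceneConfig(
            codebook=small_codebook,
            image_shape=(900, 900),
            n_cells=120,
            reads_per_cell_mean=15.0,
            cell_classes=(
                CellClassSpec("neuron", ("Sst",), 0.5),
                CellClassSpec("glia", ("Gfap",), 0.5),
            ),
            editing_probs=EditingProbTable.uniform(small_codebook.site_ids, 0.5),
            marker_read_fraction=0.4,
            seed=21,
        )
        _, truth = simulate_scene(cfg)
        reads = truth.reads.assign(pass_qc=True)
        counts = build_cell_table(reads)
        out = classify_cells(counts, small_codebook)
        true_class = truth.cells.set_index("cell_id")["cell_class"]
        checked = 0
        for row in out.itertuples(index=False):
            if row.marker_classes:  # cells w/o marker reads are unclassifiable
                assert row.marker_classes == frozenset({true_class[row.cell_id]})
                checked += 1
        assert checked > 60

    def test_multilabel_class_counts_bound(self, panel_codebook):
        counts = _counts([(1, "Sst", 1), (1, "Pcp4", 1), (2, "Sst", 2)])
        out = classify_cells(counts, panel_codebook)
        n_classified = (out["marker_classes"].apply(len) > 0).sum()
        total_memberships = out["marker_classes"].apply(len).sum()
        assert total_memberships >= n_classified


class TestMarkerEditing:
    def _fixture(self, panel_codebook, n_cells_per_rep, n_reps=2):
        rows = []
        cid = 0
        reps = {}
        for r in range(n_reps):
            for _ in range(n_cells_per_rep):
                cid += 1
                rows += [(cid, "Sst", 1), (cid, "site00_ed", 1),
                         (cid, "site00_un", 1)]
                reps[cid] = f"r{r}"
        return _counts(rows), pd.Series(reps)

    def test_cell_count_filter_boundary(self, panel_codebook):
        counts, reps = self._fixture(panel_codebook, n_cells_per_rep=99)
        cls = classify_cells(counts, panel_codebook)
        res = marker_editing(counts, cls, panel_codebook, "site00", "Sst",
                             replicates=reps)
        assert res["qc"] == QC_BELOW_100_CELLS
        counts, reps = self._fixture(panel_codebook, n_cells_per_rep=100)
        cls = classify_cells(counts, panel_codebook)
        res = marker_editing(counts, cls, panel_codebook, "site00", "Sst",
                             replicates=reps)
        assert res["qc"] == ""
        assert res["level"] == pytest.approx(0.5)

    def test_marker_never_seen_gives_na(self, panel_codebook):
        counts = _counts([(1, "site00_ed", 2)])
        cls = classify_cells(counts, panel_codebook)
        res = marker_editing(counts, cls, panel_codebook, "site00", "Gfap")
        assert np.isnan(res["level"]) and res["qc"] == QC_BELOW_100_CELLS

    def test_unknown_marker_rejected(self, panel_codebook):
        counts = _counts([(1, "Sst", 1)])
        cls = classify_cells(counts, panel_codebook)
        with pytest.raises(ValueError, match="unknown marker"):
            marker_editing(counts, cls, panel_codebook, "site00", "NotAMarker")

    def test_positive_negative_partition_conserves_reads(self, panel_codebook):
        rows = [(1, "Sst", 1), (1, "site00_ed", 2), (2, "site00_un", 3),
                (3, "Gfap", 1), (3, "site00_ed", 1), (3, "site00_un", 1)]
        counts = _counts(rows)
        cls = classify_cells(counts, panel_codebook)
        pos = marker_editing(counts, cls, panel_codebook, "site00", "Sst")
        neg = marker_negative_editing(counts, cls, panel_codebook, "site00", "Sst")
        assert pos["n_edited"] + neg["n_edited"] == 3
        assert pos["n_unedited"] + neg["n_unedited"] == 4

    def test_class_contrast_recovered_from_simulation(self, small_codebook):
        """Editing 0.8 in marker-positive class vs 0.2 in the other recovers."""
        probs = EditingProbTable(
            {(s, "*", cls): p
             for s in small_codebook.site_ids
             for cls, p in (("neuron", 0.8), ("glia", 0.2))}
        )
        cfg = SceneConfig(
            codebook=small_codebook,
            image_shape=(1100, 1100),
            n_cells=300,
            reads_per_cell_mean=25.0,
            cell_classes=(
                CellClassSpec("neuron", ("Sst",), 0.5),
                CellClassSpec("glia", ("Gfap",), 0.5),
            ),
            editing_probs=probs,
            marker_read_fraction=0.3,
            seed=31,
        )
        _, truth = simulate_scene(cfg)
        reads = truth.reads.assign(pass_qc=True)
        counts = build_cell_table(reads)
        cls = classify_cells(counts, small_codebook)
        site = small_codebook.site_ids[0]
        for marker, p in (("Sst", 0.8), ("Gfap", 0.2)):
            res = marker_editing(counts, cls, small_codebook, site, marker)
            n = res["n_edited"] + res["n_unedited"]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(res["level"] - p) <= 3 * se


@pytest.mark.parametrize(
    "pos,neg,expected", [(0.6, 0.6, 1.0), (0.9, 0.45, 2.0)]
)
def test_marker_ratio_arithmetic(pos, neg, expected):
    assert marker_editing_ratio(pos, neg) == pytest.approx(expected)


def test_marker_ratio_zero_negative_is_na():
    assert np.isnan(marker_editing_ratio(0.5, 0.0))


class TestClassTemporal:
    def _fixture(self, panel_codebook, n_cells, level=0.5):
        rows = []
        meta = []
        rng = np.random.default_rng(2)
        cid = 0
        for marker in ("Sst", "Pcp4", "Plp1"):
            for _ in range(n_cells):
                cid += 1
                n_ed = int(rng.random() < level)
                rows += [(cid, marker, 1),
                         (cid, "site00_ed" if n_ed else "site00_un", 1)]
                meta.append({"cell_id": cid, "replicate": "r1", "stage": "P7"})
        return _counts(rows), pd.DataFrame(meta)

    def test_replicate_cell_filter_boundary(self, panel_codebook):
        for n, flagged in ((19, True), (20, False)):
            counts, meta = self._fixture(panel_codebook, n)
            cls = classify_cells(counts, panel_codebook)
            out = class_temporal_editing(counts, cls, panel_codebook, "site00", meta)
            plp = out[out["cell_class"] == "oligodendrocyte"].iloc[0]
            assert (plp["qc"] == QC_BELOW_20_CELLS) == flagged

    def test_class_difference_detected_by_rank_test(self, panel_codebook):
        """Neuronal editing 0.8 vs oligodendrocyte 0.4 is flagged by KW."""
        rng = np.random.default_rng(77)
        detections = 0
        n_sims = 10
        for _ in range(n_sims):
            groups = []
            for p in (0.8, 0.8, 0.4):  # Sst, Pcp4 at 0.8; Plp1 at 0.4
                reads_per_rep = 500
                groups.append(
                    rng.binomial(reads_per_rep, p, size=5) / reads_per_rep
                )
            _, pval = kruskal_wallis(groups)
            detections += pval < 0.05
        assert detections == n_sims
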