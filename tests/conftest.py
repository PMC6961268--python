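import numpy as np
import pytest

from edscape.codebook import Codebook, CodebookEntry
from edscape.scene import (
    CellClassSpec,
    EditingProbTable,
    SceneConfig,
    make_codebook,
)


@pytest.fixture
def minimal_codebook() -> Codebook:
    """One paired editing site, mirroring a Cyfip2 K/E probe pair."""
    return Codebook(
        [
            CodebookEntry("Cyfip2_ed", "AAGC", "edited_variant", site_id="Cyfip2_KE"),
            CodebookEntry("Cyfip2_un", "AAGT", "unedited_variant", site_id="Cyfip2_KE"),
        ]
    )


@pytest.fixture
def panel_codebook() -> Codebook:
    """Study-scale panel: 22 paired sites, 10 markers, 3 ADAR groups."""
    return make_codebook(n_sites=22, seed=11)


@pytest.fixture
def small_codebook() -> Codebook:
    return make_codebook(
        n_sites=4,
        marker_classes={"neuron": ("Sst",), "glia": ("Gfap",)},
        adar_groups=(),
        seed=5,
    )


@pytest.fixture
def small_scene_cfg(small_codebook) -> SceneConfig:
    """Small noiseless scene: two classes, no regions, uniform editing 0.5."""
    return SceneConfig(
        codebook=small_codebook,
        image_shape=(512, 512),
        n_cells=40,
        reads_per_cell_mean=8.0,
        cell_classes=(
            CellClassSpec("neuron", ("Sst",), 0.5),
            CellClassSpec("glia", ("Gfap",), 0.5),
        ),
        editing_probs=EditingProbTable.uniform(small_codebook.site_ids, 0.5),
        marker_read_fraction=0.25,
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
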