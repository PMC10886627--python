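"""Shared fixtures: small deterministic cohorts and their tile datasets.

Everything is generated in-process; no fixture files are stored.
"""

import numpy as np
import pytest
from hypothesis import settings

from srshisto.image import build_three_channel, normalize_for_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from srshisto.synthetic import CohortSpec, generate_cohort
from srshisto.tiling import build_dataset, extract_tile_pixels

#: Desk-scale study-condition cohort: same image count as the study,
#: reduced resolution (320 px, 64 px tiles) for CPU work.
DESK_SPEC = CohortSpec(n_images=80, image_size=(320, 320), regions_range=(1, 3), seed=7)
DESK_TILE = 64


@pytest.fixture(scope="session")
def desk_cohort():
    specimens, manifest = generate_cohort(DESK_SPEC)
    return specimens


@pytest.fixture(scope="session")
def desk_dataset(desk_cohort):
    images = [img for img, _ in desk_cohort]
    asets = [aset for _, aset in desk_cohort]
    return build_dataset(images, asets, tile_size=DESK_TILE)


@pytest.fixture(scope="session")
def desk_tensors(desk_cohort):
    """Normalized three-channel model inputs, one per specimen."""
    return {
        img.image_id: normalize_for_model(
            build_three_channel(img), "global_fixed_range", fixed_range=(-1.5, 1.5)
        ).planes
        for img, _ in desk_cohort
    }


def subset_tiles(dataset, tensors, image_ids):
    """Stack tile tensors and integer labels for a list of image ids."""
    xs, ys = [], []
    for iid in image_ids:
        for rec in dataset.tiles_for_images([iid]):
            xs.append(extract_tile_pixels(tensors[iid], rec))
            ys.append(rec.label.index)
    return np.stack(xs), np.array(ys, dtype=np.int64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
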