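import numpy as np
import pytest

from uroscreen.slide_io import SlidePyramid
from uroscreen.synthetic_slides import SyntheticSlideConfig, generate_slide
from uroscreen.training import prepare_slides


@pytest.fixture(scope="session")
def toy_config():
    """Desk-scale config: 1024px canvas, tile-128-friendly morphometry."""
    return SyntheticSlideConfig(
        width=1024,
        height=1024,
        n_normal_cells=40,
        n_neoplastic_clusters=0,
        cells_per_cluster=(3, 6),
        normal_nucleus_radius=(5.0, 8.0),
        neoplastic_nucleus_radius=(12.0, 18.0),
        neoplastic_chromatin_darkening=60,
        n_debris=8,
        n_crystals=4,
        seed=0,
    )


@pytest.fixture(scope="session")
def neoplastic_bundle(toy_config):
    from dataclasses import replace

    return generate_slide(replace(toy_config, n_neoplastic_clusters=2, seed=11))


@pytest.fixture(scope="session")
def negative_bundle(toy_config):
    from dataclasses import replace

    return generate_slide(replace(toy_config, seed=12))


def build_contexts(bundles, config):
    """In-memory SlideContexts for a list of synthetic bundles."""
    by_id = {b.record.slide_id: b for b in bundles}
    records = [b.record for b in bundles]
    annotations = {b.record.slide_id: b.annotations for b in bundles}
    return prepare_slides(
        records,
        annotations,
        config,
        open_slide=lambda rec: SlidePyramid.from_array(
            by_id[rec.slide_id].image, rec.slide_id, rec.scan_magnification
        ),
    )


def pyramid_of(bundle):
    return SlidePyramid.from_array(
        bundle.image, bundle.record.slide_id, bundle.record.scan_magnification
    )
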