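"""Shared fixtures: small synthetic photos and a reusable feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import striaekit as sk


@pytest.fixture(scope="session")
def striped_photo() -> sk.SyntheticPhoto:
    """A moderate synthetic photo with stripes in all four quadrants."""
    spec = sk.StriaeSpec(
        image_size=192,
        n_stripes=10,
        stripe_width_px=7.0,
        stripe_contrast=45.0,
        skin_noise_sd=2.0,
        seed=7,
    )
    return sk.generate_photo(spec)


@pytest.fixture(scope="session")
def small_cohort_features() -> pd.DataFrame:
    """Feature table of a small labeled cohort, via the full image pipeline."""
    items = sk.generate_cohort(12, seed=5, image_size=192)
    rows = []
    for item in items:
        fv = sk.extract_features(
            item.photo.image,
            item.photo.spec.navel,
            elasticity=item.elasticity_record[2],
        )
        rows.append({"photo_id": item.photo_id, "label": item.label, **fv.as_row()})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
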