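"""Shared fixtures: small phantoms and scans, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from interpmotion import (
    PhantomSpec,
    Scan,
    make_phantom,
)


@pytest.fixture(scope="session")
def phantom_and_labels():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom(phantom_and_labels):
    return phantom_and_labels[0]


@pytest.fixture(scope="session")
def labels(phantom_and_labels):
    return phantom_and_labels[1]


@pytest.fixture()
def static_scan(phantom):
    """12 identical volumes of the default phantom."""
    data = np.repeat(phantom[..., None], 12, axis=3).astype(np.float32)
    return Scan(data, tr_s=2.5, slice_order="alt+z2", voxel_mm=(3, 3, 3), n_ignore=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
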