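"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from clearvasc import extravasation as ex
from clearvasc import phantoms
from clearvasc.imstore import LabelMask

SPACING = (3.0, 0.69, 0.69)


@pytest.fixture(scope="session")
def straight_tube_mask():
    """Flat-ended axial cylinder, L = 100 µm, r = 5 µm, anisotropic lattice."""
    z, y, x = np.indices((44, 44, 44)).astype(float)
    rad = np.hypot(y * 0.69 - 15.0, x * 0.69 - 15.0)
    data = ((z * 3 >= 14) & (z * 3 <= 114) & (rad <= 5.0)).astype(np.uint8)
    return LabelMask(data, SPACING)


def cylinder_mask(radius_um: float, z_lo: float = 4.0, z_hi: float = 144.0) -> LabelMask:
    """Flat-ended axial cylinder of given radius spanning [z_lo, z_hi] µm."""
    ny = int((2 * radius_um + 30) / 0.69)
    z, y, x = np.indices((50, ny, ny)).astype(float)
    c = radius_um + 15.0
    rad = np.hypot(y * 0.69 - c, x * 0.69 - c)
    data = ((z * 3 >= z_lo) & (z * 3 <= z_hi) & (rad <= radius_um)).astype(np.uint8)
    return LabelMask(data, SPACING)


@pytest.fixture(scope="session")
def y_junction_phantom():
    """Rendered Y-shaped tube tree: one junction, three ~60 µm branches."""
    j = np.array([75.0, 60.0, 60.0])
    cl = [
        (np.vstack([j + np.array([-60.0, 0.0, 0.0]), j]), 4.0),
        (np.vstack([j, j + np.array([55.0, 35.0, 0.0])]), 4.0),
        (np.vstack([j, j + np.array([55.0, -30.0, 25.0])]), 4.0),
    ]
    spec = phantoms.PhantomSpec(
        shape=(50, 176, 176), spacing=SPACING, centerlines=cl, noise_sd=0.0, seed=0
    )
    _, truth = phantoms.make_vessel_phantom(spec)
    return truth


@pytest.fixture(scope="session")
def spot_phantom_bundle():
    """Seeded spot phantom plus the full default spot-pipeline output.

    Returns (spec, truth, dextran_grid, kept_table, full_table).
    Seed chosen so the requested 10 spots and several artifacts all fit.
    """
    spec = phantoms.PhantomSpec(
        shape=(96, 224, 224),
        spacing=SPACING,
        n_vessels=8,
        radius_range=(3.0, 5.0),
        n_spots=10,
        spot_radius_range=(17.0, 21.0),
        n_artifacts=5,
        artifact_z_extent=30.0,
        noise_sd=4.0,
        seed=58,
    )
    _, truth = phantoms.make_vessel_phantom(spec)
    dex, truth2 = phantoms.make_spot_phantom(spec, truth)
    seg = LabelMask((dex.data >= 150).astype(np.uint8), spec.spacing)
    kept, full, _ = ex.run_spot_pipeline(seg, dex)
    return spec, truth2, dex, kept, full


@pytest.fixture(scope="session")
def perfusion_slide_bundle():
    """2D 4-class slide phantom with a classifier trained on sparse scribbles.

    Returns (spec, truth, dextran, lectin, predicted_class_mask).
    """
    from clearvasc import pixelclass as pc

    spec = phantoms.PhantomSpec(
        shape=(256, 256),
        spacing=(0.69, 0.69),
        n_vessels=60,
        radius_range=(2.5, 3.5),
        noise_sd=4.0,
        seed=5,
        class_proportions=(0.25, 0.25, 0.5),
    )
    dex, lec, truth = phantoms.make_perfusion_slide(spec)
    cm = truth.class_map.data
    rng = np.random.default_rng(0)
    labels = np.zeros_like(cm, dtype=np.int32)
    for c in (0, 1, 2, 3):
        idx = np.argwhere(cm == c)
        pick = idx[rng.choice(len(idx), size=min(2000, len(idx)), replace=False)]
        labels[tuple(pick.T)] = c + 1  # model classes 1..4, 1 = background
    model = pc.train(
        [[dex, lec]], [labels], pc.FeatureBankConfig(scales=(1.0, 2.0, 4.0)), seed=0
    )
    _, mask = pc.predict(model, [dex, lec])
    predicted = LabelMask((mask.data - 1).astype(np.int32), spec.spacing)
    return spec, truth, dex, lec, predicted
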