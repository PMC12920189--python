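import numpy as np
import pytest

from perivox import BinaryMask, PhantomParams, ThresholdPolicy, generate_patient


def cube_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    """Axis-aligned cube occupying [lo, hi) on every axis."""
    values = np.zeros(shape, dtype=bool)
    values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return BinaryMask(values, spacing)


def random_blob_mask(rng, shape=(14, 14, 14), n_seeds=3, growth=40, spacing=(1.0, 1.0, 1.0)):
    """Small random mask grown from a few seed voxels (possibly empty)."""
    values = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = rng.integers(1, np.array(shape) - 1)
        values[tuple(c)] = True
    for _ in range(growth):
        c = rng.integers(0, np.array(shape))
        if values.any():
            # grow next to existing foreground half of the time
            idx = np.argwhere(values)
            base = idx[rng.integers(len(idx))]
            step = rng.integers(-1, 2, size=3)
            c = np.clip(base + step, 0, np.array(shape) - 1)
        values[tuple(c)] = True
    return BinaryMask(values, spacing)


@pytest.fixture
def policy():
    return ThresholdPolicy()


@pytest.fixture(scope="session")
def small_params():
    """Phantom conditions scaled for fast tests (64^3 grid, smaller tumor)."""
    return PhantomParams(
        shape=(64, 64, 64),
        brain_semi_axes_mm=(28.0, 26.0, 24.0),
        tc_volume_ml=(6.0, 12.0),
        snfh_margin_mm=5.0,
        center_jitter_mm=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    return generate_patient(small_params, "pt", seed=11)
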