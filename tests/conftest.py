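"""Shared phantom fixtures.

Phantoms are generated once per session where possible; unit tests use
small 64^3 grids, acceptance tests build their own spec-mandated sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from calvaria import PhantomSpec, generate_phantom


def small_closed_spec(**overrides) -> PhantomSpec:
    """64^3 closed-shell phantom that comfortably fits its layers."""
    params = dict(
        shape=(64, 64, 64),
        brain_radii=(16.0, 15.0, 14.0),
        csf_gap_mm=2.0,
        inner_table_mm=1.5,
        diploe_mm=2.5,
        outer_table_mm=1.5,
        scalp_mm=5.0,
        noise_sd=0.0,
        seed=0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free closed phantom (label segmentation)."""
    return generate_phantom(small_closed_spec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """Closed phantom with moderate noise."""
    return generate_phantom(small_closed_spec(noise_sd=10.0, seed=11))


@pytest.fixture(scope="session")
def open_phantom():
    """Open-inferior phantom with noise, 96^3 (exercises exclusion logic)."""
    spec = PhantomSpec(noise_sd=15.0, seed=1, open_inferior=True)
    return generate_phantom(spec)


def make_slab_labels(n_slab: int, axis: int = 0, size: int = 24,
                     inner_class: int = 2, slab_class: int = 3, outer_class: int = 4):
    """Axis-aligned slab: inner class below, ``n_slab`` slab voxels, outer above.

    Defaults build CSF | skull | head along ``axis``; remaining voxels are
    the outer class.  Returns (labels, slab_slice_range).
    """
    labels = np.full((size, size, size), outer_class, dtype=np.uint8)
    start = size // 2 - n_slab // 2
    sl = [slice(None)] * 3
    sl[axis] = slice(0, start)
    labels[tuple(sl)] = inner_class
    sl[axis] = slice(start, start + n_slab)
    labels[tuple(sl)] = slab_class
    return labels, (start, start + n_slab)
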