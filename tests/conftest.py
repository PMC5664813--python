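"""Shared fixtures: small phantoms reused across test modules.

Phantom volumes are generated at 137.6 µm voxel pitch on (448, 96, 96)
grids — half the linear sampling of a routine scan, same millimetre
grain geometry — so the whole suite runs quickly while every grain is
still tens of voxels across.
"""

import numpy as np
import pytest

from spikect import segment_spike, separate_grains
from spikect.phantom import PhantomSpec, generate_phantom

TEST_PITCH_UM = 137.6
TEST_SHAPE = (448, 96, 96)


def small_spec(**kwargs) -> PhantomSpec:
    defaults = dict(
        n_spikelet_pairs=10,
        voxel_pitch_um=TEST_PITCH_UM,
        volume_shape=TEST_SHAPE,
        seed=1,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def phantom_small():
    """One 20-grain tube-enclosed phantom with rachis and specks."""
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def segmented_small(phantom_small):
    """The standard segmentation products of ``phantom_small``."""
    vol, truth = phantom_small
    masked, mask, thr = segment_spike(vol)
    return vol, truth, masked, mask, thr


@pytest.fixture(scope="session")
def labelled_small(segmented_small):
    """Separated grain labels of ``phantom_small``."""
    vol, truth, masked, mask, thr = segmented_small
    labels = separate_grains(mask)
    return vol, truth, masked, mask, thr, labels


def digitize_ellipsoid(semi_axes, axes=None, pad=4):
    """Binary image of one ellipsoid centred in a tight volume."""
    from spikect.phantom import _ellipsoid_voxels

    semi_axes = np.asarray(semi_axes, dtype=float)
    if axes is None:
        axes = np.eye(3)
    half = np.sqrt(((np.asarray(axes) * semi_axes[:, None]) ** 2).sum(0))
    shape = tuple(int(np.ceil(2 * h)) + 2 * pad + 1 for h in half)
    center = tuple((s - 1) / 2.0 for s in shape)
    vox = _ellipsoid_voxels(center, semi_axes, axes, shape)
    img = np.zeros(shape, dtype=bool)
    img[vox] = True
    return img
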