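"""Shared fixtures: small deterministic phantoms and helpers.

Phantoms are generated programmatically (no binary fixtures on disk) and
cached per session because rasterization + rendering is the slow part.
"""

from __future__ import annotations

import numpy as np
import pytest

from rootvox import phantom as ph
from rootvox.segmentation import TrackerConfig
from rootvox.volume_io import ImageStack


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (int(np.count_nonzero(a)) + int(np.count_nonzero(b)))


@pytest.fixture
def cfg() -> TrackerConfig:
    return TrackerConfig()


def make_tube_phantom(
    n_slices: int = 40, side: int = 48, radius: float = 5.0, rng_seed: int = 0,
    **overrides,
) -> ph.PhantomSpec:
    """Single vertical tube, the simplest trackable phantom."""
    c = side / 2.0
    return ph.PhantomSpec(
        shape=(n_slices, side, side),
        branches=[
            ph.BranchSpec(
                [(0.0, c, c), (float(n_slices - 1), c, c)], radius, radius
            )
        ],
        rng_seed=rng_seed,
        **overrides,
    )


def make_upward_phantom(
    n_slices: int = 80, side: int = 64, rng_seed: int = 0, **overrides
) -> ph.PhantomSpec:
    """Vertical taproot with one upward lateral joining at 60% depth.

    Radii are kept >= 4 so the junction contact is wider than one diagonal
    pixel (at very small scales the contact degenerates and a contour
    cannot cross it).
    """
    c = side / 2.0
    zjoin = 0.6 * (n_slices - 1)
    return ph.PhantomSpec(
        shape=(n_slices, side, side),
        branches=[
            ph.BranchSpec([(0.0, c, c), (float(n_slices - 1), c, c)], 5.5, 4.5),
            ph.BranchSpec(
                [(zjoin, c, c), (0.25 * (n_slices - 1), 0.76 * side, 0.72 * side)],
                4.0, 3.5, parent=0,
            ),
        ],
        rng_seed=rng_seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def tube_data() -> tuple[np.ndarray, np.ndarray, ph.PhantomSpec, ImageStack]:
    spec = make_tube_phantom()
    mask, labels = ph.rasterize_branches(spec)
    stack = ph.render_greyscale(mask, spec)
    return mask, labels, spec, stack


@pytest.fixture(scope="session")
def upward_data() -> tuple[np.ndarray, np.ndarray, ph.PhantomSpec, ImageStack]:
    spec = make_upward_phantom()
    mask, labels = ph.rasterize_branches(spec)
    stack = ph.render_greyscale(mask, spec)
    return mask, labels, spec, stack


def seed_point(spec: ph.PhantomSpec) -> tuple[int, int]:
    z0, r0, c0 = spec.branches[0].control_points[0]
    return (round(r0), round(c0))
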