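"""Shared fixtures: small phantoms and their precomputed pipeline stages.

Everything is generated programmatically at test time; session scope keeps
the expensive stages (distance map, watershed hierarchy) computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tesseg import (
    DiffusionParams,
    PhantomSpec,
    ThresholdParams,
    build_hierarchy,
    distance_map_2d,
    generate_phantom,
    segment_foreground,
    smooth_anisotropic,
)

SMALL_SPEC = PhantomSpec(shape=(24, 64, 64), n_tiles=12, thickness=5, seed=1)
SMALL_DIFFUSION = DiffusionParams(stop_threshold=100.0, steps=25)
SMALL_THRESHOLD = ThresholdParams(
    box_length=15, strip_threshold=100.0, strip_grow_radius=7.0
)


@pytest.fixture(scope="session")
def small_phantom():
    """Flat 12-tile phantom at unit-test scale."""
    vol, truth = generate_phantom(SMALL_SPEC)
    return vol, truth, SMALL_SPEC


@pytest.fixture(scope="session")
def small_pipeline(small_phantom):
    """Smoothed volume, mask, 2D distance map and hierarchy for the phantom."""
    vol, truth, spec = small_phantom
    smoothed = smooth_anisotropic(vol.data, SMALL_DIFFUSION)
    mask = segment_foreground(smoothed, SMALL_THRESHOLD)
    dist = distance_map_2d(mask, n_rays=400, m_rays=180)
    hierarchy = build_hierarchy(dist, mask)
    return {
        "smoothed": smoothed,
        "mask": mask,
        "dist": dist,
        "hierarchy": hierarchy,
        "truth": truth,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def cap_phantom():
    """Spherical-cap phantom for curvature / plane-normal checks."""
    spec = PhantomSpec(
        shape=(40, 72, 72), mode="cap", n_tiles=15, thickness=5,
        noise_sigma=4.0, seed=4,
    )
    vol, truth = generate_phantom(spec)
    return vol, truth, spec


def slab_mask(shape=(16, 40, 40), z0=6, thickness=5):
    """Axis-aligned foreground slab (helper, not a fixture)."""
    m = np.zeros(shape, dtype=bool)
    m[z0 : z0 + thickness] = True
    return m


def enumerate_min_plateaus(values, mask):
    """Independent watershed oracle: 26-connected local-minimum plateaus.

    Pure BFS enumeration, no shared code with the flooding implementation.
    """
    shape = mask.shape
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    seen = np.zeros(shape, dtype=bool)
    plateaus = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        v = values[start]
        comp, stack, is_min = [], [start], True
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if not all(0 <= c < s for c, s in zip(q, shape)):
                    continue
                if not mask[q]:
                    continue
                if values[q] == v and not seen[q]:
                    seen[q] = True
                    stack.append(q)
                elif values[q] < v:
                    is_min = False
        if is_min:
            plateaus.append(comp)
    return plateaus


def three_tile_row(missing_pore=True):
    """Three tiles in a row; the pore between tiles 2 and 3 is missing.

    The classic bad-boundary defect a merge-then-split edit has to fix.
    Returns (label field, one landmark per true tile)."""
    lab = np.zeros((10, 20, 60), dtype=np.int32)
    lab[3:7, :, :] = 1
    lab[3:7, :, 20:40] = 2
    lab[3:7, :, 40:] = 3
    pore = np.zeros((20, 60), dtype=bool)
    yy = np.arange(20)
    pore[(yy < 6) | (yy > 13), 19:21] = True
    if not missing_pore:
        pore[(yy < 6) | (yy > 13), 39:41] = True
    lab[3:7, pore] = 0
    landmarks = np.array([[4.5, 10, 10], [4.5, 10, 30], [4.5, 10, 50]])
    return lab, landmarks
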