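"""Shared fixtures: phantoms are expensive, so build each once per session."""

from __future__ import annotations

import numpy as np
import pytest

from rtcurate.nomenclature import LabelRegistry
from rtcurate.phantom import PhantomConfig, generate
from rtcurate.rtdata_model import ImageGrid, VolumeMask


@pytest.fixture(scope="session")
def registry() -> LabelRegistry:
    return LabelRegistry.default()


@pytest.fixture(scope="session")
def default_phantom():
    """Full 42-organ head-and-neck phantom on the planning-CT grid."""
    return generate(PhantomConfig.default(seed=0))


@pytest.fixture(scope="session")
def fine_phantom():
    """Small phantom on a 0.59 x 0.59 x 1.0 mm grid for threshold probing."""
    return generate(PhantomConfig.fine(seed=0))


@pytest.fixture()
def unit_grid() -> ImageGrid:
    """1 mm isotropic single-frame-of-reference grid for geometry tests."""
    return ImageGrid(
        origin=(0.0, 0.0, 0.0),
        spacing=(1.0, 1.0, 1.0),
        dims=(32, 32, 8),
        frame_of_reference="1.2.3.4",
    )


def make_mask(grid: ImageGrid, coords: np.ndarray | None = None) -> VolumeMask:
    m = VolumeMask(grid, np.zeros(grid.dims, dtype=bool))
    if coords is not None:
        m.voxels[tuple(np.asarray(coords).T)] = True
    return m


# ---------------------------------------------------------------------------
# Independent oracles (used by several test modules)
# ---------------------------------------------------------------------------

def point_in_polygon(px: float, py: float, vertices: np.ndarray) -> bool:
    """Even-odd ray casting, written independently of the rasterizer."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_force_slice_mask(
    polygons: list[np.ndarray], xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Even-odd union over polygons by per-point parity counting."""
    out = np.zeros((len(ys), len(xs)), dtype=bool)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            parity = sum(point_in_polygon(x, y, poly) for poly in polygons)
            out[i, j] = parity % 2 == 1
    return out


def flood_fill_components(voxels: np.ndarray) -> list[int]:
    """3-D 26-connected component sizes by explicit BFS (oracle)."""
    seen = np.zeros_like(voxels, dtype=bool)
    sizes = []
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    shape = voxels.shape
    for start in zip(*np.nonzero(voxels & ~seen)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            i, j, k = queue.pop()
            size += 1
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if (
                    0 <= ni < shape[0]
                    and 0 <= nj < shape[1]
                    and 0 <= nk < shape[2]
                    and voxels[ni, nj, nk]
                    and not seen[ni, nj, nk]
                ):
                    seen[ni, nj, nk] = True
                    queue.append((ni, nj, nk))
        sizes.append(size)
    return sorted(sizes, reverse=True)
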