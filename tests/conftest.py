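"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's own code paths: the surface
oracle is a plain triple loop over sites, the sector oracle a recursive
(stack-based) flood fill over explicit coordinate sets.
"""

from __future__ import annotations

import numpy as np
import pytest

FACE = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
FULL = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def brute_force_surface(labels: np.ndarray) -> set[tuple[int, int, int]]:
    """Occupied sites with >= 1 empty face neighbour, by exhaustive scan."""
    d0, d1, d2 = labels.shape
    out = set()
    for x in range(d0):
        for y in range(d1):
            for z in range(d2):
                if labels[x, y, z] == 0:
                    continue
                for dx, dy, dz in FACE:
                    qx, qy, qz = x + dx, y + dy, z + dz
                    if (
                        0 <= qx < d0
                        and 0 <= qy < d1
                        and 0 <= qz < d2
                        and labels[qx, qy, qz] == 0
                    ):
                        out.add((x, y, z))
                        break
    return out


def flood_fill_sectors(volume: np.ndarray, connectivity: int = 26,
                       min_area: int = 1) -> list[tuple[int, int]]:
    """Same-color connected components by flood fill: [(color, size), ...]."""
    offs = FACE if connectivity == 6 else FULL
    d0, d1, d2 = volume.shape
    seen = np.zeros(volume.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(volume != 0)):
        if seen[start]:
            continue
        color = int(volume[start])
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in offs:
                q = (x + dx, y + dy, z + dz)
                if (
                    0 <= q[0] < d0
                    and 0 <= q[1] < d1
                    and 0 <= q[2] < d2
                    and not seen[q]
                    and volume[q] == color
                ):
                    seen[q] = True
                    stack.append(q)
        comps.append((color, size))
    return [c for c in comps if c[1] >= min_area]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
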