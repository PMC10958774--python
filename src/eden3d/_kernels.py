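"""Numba kernels for the lattice growth engine and surface-sector labeling.

These are internal hot loops; the public semantics live in
:mod:`eden3d.eden_sim` and :mod:`eden3d.morphometrics`.  Pure-Python
reference implementations of the same rules exist in ``eden_sim.growth_step``
and in the test-suite oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by grow_until
STATUS_OK = 0            # reached t_stop
STATUS_EVENTS_DONE = 1   # exhausted the event budget before t_stop
STATUS_BOUNDARY = 2      # a division targeted the outermost lattice shell
STATUS_NO_SURFACE = 3    # surface list empty


@njit(cache=True, inline="always")
def _has_empty_face_neighbor(labels, x, y, z, L):
    if x > 0 and labels[((x - 1) * L + y) * L + z] == 0:
        return True
    if x < L - 1 and labels[((x + 1) * L + y) * L + z] == 0:
        return True
    if y > 0 and labels[(x * L + (y - 1)) * L + z] == 0:
        return True
    if y < L - 1 and labels[(x * L + (y + 1)) * L + z] == 0:
        return True
    if z > 0 and labels[(x * L + y) * L + z - 1] == 0:
        return True
    if z < L - 1 and labels[(x * L + y) * L + z + 1] == 0:
        return True
    return False


@njit(cache=True)
def grow_until(labels, surf, pos, n_surf, t, L, t_stop, max_events, rng):
    """Run division events until the clock reaches ``t_stop``.

    labels : flat (L**3,) integer lattice, 0 = empty.
    surf   : surface-site flat indices in surf[:n_surf] (order arbitrary).
    pos    : inverse map, pos[flat] = position in surf or -1.
    t      : current time in generations; advances by 1/|S| per division,
             with |S| taken before the division's surface update.

    Returns (n_surf, t, events_done, status).  On STATUS_BOUNDARY the
    offending division is *not* performed.
    """
    events = 0
    cand = np.empty(6, np.int64)
    while t < t_stop:
        if events >= max_events:
            return n_surf, t, events, STATUS_EVENTS_DONE
        if n_surf == 0:
            return n_surf, t, events, STATUS_NO_SURFACE
        # (i) uniform parent choice among surface sites
        i = rng.integers(0, n_surf)
        idx = surf[i]
        z = idx % L
        y = (idx // L) % L
        x = idx // (L * L)
        # (ii) uniform choice among the parent's empty face neighbours
        nn = 0
        if x > 0 and labels[idx - L * L] == 0:
            cand[nn] = idx - L * L
            nn += 1
        if x < L - 1 and labels[idx + L * L] == 0:
            cand[nn] = idx + L * L
            nn += 1
        if y > 0 and labels[idx - L] == 0:
            cand[nn] = idx - L
            nn += 1
        if y < L - 1 and labels[idx + L] == 0:
            cand[nn] = idx + L
            nn += 1
        if z > 0 and labels[idx - 1] == 0:
            cand[nn] = idx - 1
            nn += 1
        if z < L - 1 and labels[idx + 1] == 0:
            cand[nn] = idx + 1
            nn += 1
        new = cand[rng.integers(0, nn)]
        nz = new % L
        ny = (new // L) % L
        nx = new // (L * L)
        if nx == 0 or nx == L - 1 or ny == 0 or ny == L - 1 or nz == 0 or nz == L - 1:
            return n_surf, t, events, STATUS_BOUNDARY
        ns_before = n_surf
        # (iii) fill with the parent's colour
        labels[new] = labels[idx]
        # (iv)(a) the new site joins S if it has an empty face neighbour
        if _has_empty_face_neighbor(labels, nx, ny, nz, L):
            surf[n_surf] = new
            pos[new] = n_surf
            n_surf += 1
        # (iv)(b) occupied face neighbours of the new site (the parent among
        # them) leave S if they no longer have an empty face neighbour
        for k in range(6):
            if k == 0:
                if nx == 0:
                    continue
                q = new - L * L
                qx, qy, qz = nx - 1, ny, nz
            elif k == 1:
                if nx == L - 1:
                    continue
                q = new + L * L
                qx, qy, qz = nx + 1, ny, nz
            elif k == 2:
                if ny == 0:
                    continue
                q = new - L
                qx, qy, qz = nx, ny - 1, nz
            elif k == 3:
                if ny == L - 1:
                    continue
                q = new + L
                qx, qy, qz = nx, ny + 1, nz
            elif k == 4:
                if nz == 0:
                    continue
                q = new - 1
                qx, qy, qz = nx, ny, nz - 1
            else:
                if nz == L - 1:
                    continue
                q = new + 1
                qx, qy, qz = nx, ny, nz + 1
            p = pos[q]
            if p >= 0 and not _has_empty_face_neighbor(labels, qx, qy, qz, L):
                last = n_surf - 1
                moved = surf[last]
                surf[p] = moved
                pos[moved] = p
                pos[q] = -1
                n_surf = last
        t += 1.0 / ns_before
        events += 1
    return n_surf, t, events, STATUS_OK


@njit(cache=True, inline="always")
def _find(parent, a):
    while parent[a] != a:
        parent[a] = parent[parent[a]]
        a = parent[a]
    return a


@njit(cache=True)
def label_same_color_components(members, n, pos, labels, d0, d1, d2, offsets):
    """Union-find labeling of same-colored voxel components.

    members : flat voxel indices of the mask in members[:n]
    pos     : inverse map over the full (d0*d1*d2,) grid, -1 outside the mask
    labels  : flat color grid (nonzero on mask voxels)
    offsets : (k, 3) integer neighbour offsets defining connectivity

    Returns (component_id_per_voxel, sizes, colors) where component ids are
    root positions remapped to 0..n_components-1.
    """
    parent = np.arange(n)
    nk = offsets.shape[0]
    for a in range(n):
        idx = members[a]
        z = idx % d2
        y = (idx // d2) % d1
        x = idx // (d2 * d1)
        col = labels[idx]
        for k in range(nk):
            qx = x + offsets[k, 0]
            qy = y + offsets[k, 1]
            qz = z + offsets[k, 2]
            if qx < 0 or qx >= d0 or qy < 0 or qy >= d1 or qz < 0 or qz >= d2:
                continue
            q = (qx * d1 + qy) * d2 + qz
            b = pos[q]
            if b > a and labels[q] == col:
                ra = _find(parent, a)
                rb = _find(parent, b)
                if ra != rb:
                    parent[rb] = ra
    comp = np.full(n, -1, np.int64)
    n_comp = 0
    for a in range(n):
        r = _find(parent, a)
        if comp[r] < 0:
            comp[r] = n_comp
            n_comp += 1
    sizes = np.zeros(n_comp, np.int64)
    colors = np.zeros(n_comp, labels.dtype)
    out = np.empty(n, np.int64)
    for a in range(n):
        c = comp[_find(parent, a)]
        out[a] = c
        sizes[c] += 1
        colors[c] = labels[members[a]]
    return out, sizes, colors
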