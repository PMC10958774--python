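"""Stochastic 3D Eden growth of spherical bacterial colonies.

The model coarse-grains a colony growing from an inoculation bead into a
cubic lattice: each site is empty (0) or carries a genotype label.  A
*surface site* is an occupied site with at least one of its six face
neighbours empty.  Growth proceeds by division events: a surface site is
drawn uniformly, one of its empty face neighbours is drawn uniformly and
filled with the parent's label, and the surface list is updated
incrementally.  Each division advances the clock by ``1/|S|`` with ``|S|``
the surface size just before the division, so one unit of time is a
generation: every surface site divides on average once per unit time.

Two seeding variants are provided.  In ``two_species`` mode founders carry
one of two neutral colors with equal probability (a 1:1 co-culture); in
``multi_species`` mode every founder is a distinct lineage.

The hot loop is compiled (``eden3d._kernels``); :func:`growth_step` is a
pure-Python reference implementation of the same update rule used by the
tests as an executable statement of the semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import (
    STATUS_BOUNDARY,
    STATUS_EVENTS_DONE,
    STATUS_NO_SURFACE,
    STATUS_OK,
)

__all__ = [
    "SimParams",
    "ColonyLattice",
    "SurfaceSet",
    "SimClock",
    "Snapshot",
    "ColonyRun",
    "EnsembleRun",
    "BoundaryError",
    "DegenerateRunError",
    "seed_lattice",
    "compute_surface_set",
    "growth_step",
    "run_colony",
    "run_ensemble",
    "replicate_seeds",
]

#: paper-scale seeding concentrations m/10, m, m x 10 as mean founder counts
CONCENTRATION_SEEDS = {"m/10": 16, "m": 144, "mx10": 1150}

FACE_OFFSETS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
    dtype=np.int64,
)


class BoundaryError(RuntimeError):
    """Growth reached the outermost lattice shell."""


class DegenerateRunError(RuntimeError):
    """Seeding repeatedly produced zero founders."""


@dataclass
class SimParams:
    """Parameters of one colony simulation.

    Defaults are the study conditions: a 200^3 lattice, founders placed in a
    central sphere of radius 19 sites, 5e5 division events, snapshots at
    every integer generation.
    """

    lattice_size: int = 200
    seed_sphere_radius: float = 19.0
    mean_seed_count: float = 144.0
    species_mode: Literal["two_species", "multi_species"] = "two_species"
    n_steps: int = 500_000
    record_interval: float = 1.0
    rng_seed: int | None = None
    boundary_policy: Literal["error", "stop"] = "error"
    seed_retries: int = 10

    @property
    def sphere_volume(self) -> float:
        """Nominal seeding volume V = (4/3) pi R_s^3 in sites."""
        return 4.0 / 3.0 * np.pi * self.seed_sphere_radius**3

    @property
    def fill_probability(self) -> float:
        """Per-site founder probability N/V inside the seeding sphere."""
        return self.mean_seed_count / self.sphere_volume

    def validate(self) -> None:
        if self.lattice_size <= 2 * self.seed_sphere_radius:
            raise ValueError(
                f"lattice_size must exceed 2*seed_sphere_radius "
                f"({self.lattice_size} <= {2 * self.seed_sphere_radius})"
            )
        if self.mean_seed_count < 0:
            raise ValueError("mean_seed_count must be nonnegative")
        if self.fill_probability > 1.0:
            raise ValueError(
                f"mean_seed_count {self.mean_seed_count} exceeds the seeding "
                f"sphere volume {self.sphere_volume:.1f} (fill probability > 1)"
            )
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.record_interval <= 0:
            raise ValueError("record_interval must be positive")
        if self.species_mode not in ("two_species", "multi_species"):
            raise ValueError(f"unknown species_mode {self.species_mode!r}")
        if self.boundary_policy not in ("error", "stop"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")


@dataclass
class ColonyLattice:
    """3D integer label grid; 0 = empty, k >= 1 = species/lineage."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")

    @property
    def occupied_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class SurfaceSet:
    """Occupied sites with >= 1 empty face neighbour (the list S)."""

    members: set[tuple[int, int, int]]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SimClock:
    """Generation-time clock; advances by 1/|S| per division."""

    t: float = 0.0
    events: int = 0


@dataclass
class Snapshot:
    """State summary at one recording time of one replicate."""

    t: float
    replicate: int
    metrics: dict
    grid: np.ndarray | None = None


@dataclass
class ColonyRun:
    """Result of one colony simulation: snapshot series plus final state."""

    params: SimParams
    snapshots: list[Snapshot]
    final_lattice: ColonyLattice
    n_seeds: int
    status: int
    sector_tables: pd.DataFrame | None = None
    #: flat indices of the incrementally maintained surface list at the end
    final_surface: np.ndarray | None = None

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-snapshot metric rows as a tidy DataFrame."""
        return pd.DataFrame([s.metrics for s in self.snapshots])


@dataclass
class EnsembleRun:
    """Independent replicates sharing SimParams, on a common time grid."""

    params: SimParams
    runs: list[ColonyRun]
    base_seed: int | None = None
    seeds: list[int] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.runs)

    @property
    def metrics(self) -> pd.DataFrame:
        frames = []
        for i, run in enumerate(self.runs):
            df = run.metrics.copy()
            df.insert(0, "replicate", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def aligned(self, column: str) -> pd.DataFrame:
        """Replicate-by-generation table of one metric on the common grid.

        Snapshot times differ slightly across replicates (each snapshot is
        the first state past a multiple of ``record_interval``), so series
        are aligned on the recording index ``gen`` and truncated to indices
        present in every replicate.
        """
        df = self.metrics.dropna(subset=["gen"]).pivot_table(
            index="gen", columns="replicate", values=column
        )
        return df.dropna(axis=0)


def _sphere_site_mask(L: int, radius: float) -> np.ndarray:
    """Boolean mask of sites whose center lies within ``radius`` of the lattice center."""
    c = (L - 1) / 2.0
    ax = np.arange(L, dtype=np.float64) - c
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return d2 <= radius**2


def seed_lattice(params: SimParams, rng: np.random.Generator) -> ColonyLattice:
    """Place founder cells in the central seeding sphere.

    Every site whose center lies inside the sphere of radius ``R_s`` about
    the lattice center is occupied independently with probability ``N/V``,
    ``V = (4/3) pi R_s^3`` — the founder count is binomial with mean ~N, not
    fixed.  ``two_species``: each founder is color 1 or 2 with probability
    1/2.  ``multi_species``: founders get consecutive unique lineage labels
    1, 2, ... in site-scan order.
    """
    params.validate()
    L = params.lattice_size
    inside = _sphere_site_mask(L, params.seed_sphere_radius)
    n_inside = int(inside.sum())
    draws = rng.random(n_inside) < params.fill_probability
    labels = np.zeros((L, L, L), dtype=np.int32)
    n_seeds = int(draws.sum())
    if params.species_mode == "two_species":
        colors = rng.integers(1, 3, size=n_seeds).astype(np.int32)
    else:
        colors = np.arange(1, n_seeds + 1, dtype=np.int32)
    vals = np.zeros(n_inside, dtype=np.int32)
    vals[draws] = colors
    labels[inside] = vals
    return ColonyLattice(labels)


def compute_surface_set(lattice: ColonyLattice) -> SurfaceSet:
    """Definitional surface set: occupied sites with >= 1 empty face neighbour.

    Pure function; sites outside the lattice do not count as empty.
    """
    occ = lattice.labels != 0
    empty = ~occ
    has_empty = np.zeros_like(occ)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.zeros_like(empty)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            rolled[tuple(dst)] = empty[tuple(src)]
            has_empty |= rolled
    surf = occ & has_empty
    coords = np.argwhere(surf)
    return SurfaceSet({tuple(int(v) for v in c) for c in coords})


def growth_step(
    lattice: ColonyLattice,
    surface: SurfaceSet,
    clock: SimClock,
    rng: np.random.Generator,
    boundary_policy: str = "error",
) -> dict:
    """One division event; reference (pure-Python) implementation.

    Mutates the lattice, the surface set and the clock in place and returns
    an event record ``{"parent", "child", "dt"}``.  The clock advances by
    ``1/|S|`` with ``|S|`` measured before the surface update.
    """
    if surface.size == 0:
        raise RuntimeError("no surface sites: nothing can divide")
    L = lattice.labels.shape[0]
    members = sorted(surface.members)
    parent = members[rng.integers(0, len(members))]

    def face_neighbors(site):
        x, y, z = site
        for dx, dy, dz in FACE_OFFSETS:
            q = (x + dx, y + dy, z + dz)
            if 0 <= q[0] < L and 0 <= q[1] < L and 0 <= q[2] < L:
                yield q

    empties = [q for q in face_neighbors(parent) if lattice.labels[q] == 0]
    child = empties[rng.integers(0, len(empties))]
    if any(c in (0, L - 1) for c in child):
        if boundary_policy == "error":
            raise BoundaryError(f"division into boundary shell site {child}")
        return {"parent": parent, "child": None, "dt": 0.0}
    ns_before = surface.size
    lattice.labels[child] = lattice.labels[parent]
    if any(lattice.labels[q] == 0 for q in face_neighbors(child)):
        surface.members.add(child)
    for q in face_neighbors(child):
        if q in surface.members and not any(
            lattice.labels[r] == 0 for r in face_neighbors(q)
        ):
            surface.members.discard(q)
    dt = 1.0 / ns_before
    clock.t += dt
    clock.events += 1
    return {"parent": parent, "child": child, "dt": dt}


class _EngineState:
    """Array-backed surface-list state driving the compiled kernel."""

    def __init__(self, lattice: ColonyLattice, capacity: int):
        L = lattice.labels.shape[0]
        self.L = L
        self.labels = lattice.labels.reshape(-1)
        surface = compute_surface_set(lattice)
        self.surf = np.empty(capacity, dtype=np.int64)
        self.pos = np.full(L**3, -1, dtype=np.int64)
        for i, (x, y, z) in enumerate(sorted(surface.members)):
            flat = (x * L + y) * L + z
            self.surf[i] = flat
            self.pos[flat] = i
        self.n_surf = surface.size
        self.t = 0.0
        self.events = 0

    def grow_until(self, t_stop: float, max_events: int, rng) -> int:
        self.n_surf, self.t, done, status = _kernels.grow_until(
            self.labels, self.surf, self.pos, self.n_surf, self.t,
            self.L, t_stop, max_events, rng,
        )
        self.events += done
        return status

    def surface_indices(self) -> np.ndarray:
        return self.surf[: self.n_surf]


def _snapshot_metrics(
    state: _EngineState,
    params: SimParams,
    sector_connectivity_offsets: np.ndarray,
    min_sector_area: int,
    collect_sectors: bool,
):
    """Morphometric row computed from the live engine state."""
    L = state.L
    labels3 = state.labels.reshape(L, L, L)
    occupied = int(np.count_nonzero(state.labels))
    a_prj = int((labels3 != 0).any(axis=2).sum())
    radius = float(np.sqrt(a_prj / np.pi))
    proj = (labels3 != 0).any(axis=2)
    perimeter = _projection_perimeter(proj)
    surf_idx = state.surface_indices()
    surf_colors = state.labels[surf_idx]
    counts = np.bincount(surf_colors)
    total_surface = int(surf_idx.size)
    comp, sizes, colors = _kernels.label_same_color_components(
        surf_idx, state.n_surf, state.pos, state.labels,
        L, L, L, sector_connectivity_offsets,
    )
    keep = sizes >= min_sector_area
    row = {
        "t": state.t,
        "events": state.events,
        "occupied": occupied,
        "surface_area": total_surface,
        "a_prj": a_prj,
        "perimeter": perimeter,
        "radius": radius,
        "n_sectors": int(keep.sum()),
        "area_color1": int(counts[1]) if counts.size > 1 else 0,
        "area_color2": int(counts[2]) if counts.size > 2 else 0,
    }
    if params.species_mode == "two_species" and total_surface > 0:
        row["occupancy"] = row["area_color1"] / total_surface
    sectors = None
    if collect_sectors:
        sectors = pd.DataFrame(
            {
                "t": state.t,
                "sector_id": np.arange(sizes.size)[keep],
                "color": colors[keep],
                "area": sizes[keep],
            }
        )
    return row, sectors


def _projection_perimeter(proj: np.ndarray) -> int:
    """Exposed pixel-edge count of a binary image (edges in lattice units)."""
    padded = np.pad(proj, 1)
    p = 0
    p += int((padded[1:, :] != padded[:-1, :]).sum())
    p += int((padded[:, 1:] != padded[:, :-1]).sum())
    return p


def run_colony(
    params: SimParams,
    rng_seed: int | None = None,
    *,
    store_grids: bool = False,
    sector_times: Sequence[float] | Literal["all"] | None = None,
    min_sector_area: int = 1,
    sector_connectivity: int = 26,
    replicate: int = 0,
) -> ColonyRun:
    """Seed and grow one colony, recording per-generation snapshots.

    Snapshots are taken at t=0 and the first state at or past every multiple
    of ``record_interval``.  Deterministic given ``rng_seed`` (which
    overrides ``params.rng_seed``).  Seedings that produce zero founders are
    redrawn up to ``params.seed_retries`` times, then raise
    :class:`DegenerateRunError`.
    """
    params.validate()
    seed = params.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    lattice = None
    n_seeds = 0
    for _ in range(max(1, params.seed_retries)):
        lattice = seed_lattice(params, rng)
        n_seeds = lattice.occupied_count
        if n_seeds > 0:
            break
    if n_seeds == 0:
        raise DegenerateRunError(
            f"seeding produced zero founders after {params.seed_retries} attempts"
        )
    offsets = _connectivity_offsets(sector_connectivity)
    state = _EngineState(lattice, capacity=n_seeds + params.n_steps + 8)
    collect_all = sector_times == "all"
    # a requested sector time is served by the first snapshot at or past it
    pending_times = (
        [] if (sector_times is None or collect_all)
        else sorted(float(t) for t in sector_times)
    )

    snapshots: list[Snapshot] = []
    sector_frames: list[pd.DataFrame] = []

    def record(gen: float | None):
        want_sectors = collect_all or (
            pending_times and state.t >= pending_times[0] - 1e-9
        )
        while pending_times and state.t >= pending_times[0] - 1e-9:
            pending_times.pop(0)
        row, sectors = _snapshot_metrics(
            state, params, offsets, min_sector_area, bool(want_sectors)
        )
        row["gen"] = gen
        grid = state.labels.reshape(state.L, state.L, state.L).copy() if store_grids else None
        snapshots.append(Snapshot(t=state.t, replicate=replicate, metrics=row, grid=grid))
        if sectors is not None:
            sectors.insert(0, "replicate", replicate)
            sector_frames.append(sectors)

    record(0)
    remaining = params.n_steps
    status = STATUS_OK
    k = 1
    while remaining > 0:
        t_stop = k * params.record_interval
        status = state.grow_until(t_stop, remaining, rng)
        remaining = params.n_steps - state.events
        if status == STATUS_BOUNDARY:
            if params.boundary_policy == "error":
                raise BoundaryError(
                    f"growth reached the lattice boundary shell at t={state.t:.2f}; "
                    f"increase lattice_size or reduce n_steps"
                )
            break
        if status == STATUS_NO_SURFACE:
            break
        if status == STATUS_OK:
            gen = int(np.floor(state.t / params.record_interval))
            record(gen)
            k = gen + 1
        else:  # events exhausted mid-interval: final partial state below
            break
    if status == STATUS_EVENTS_DONE or (status != STATUS_OK and snapshots[-1].t < state.t):
        record(None)

    final = ColonyLattice(state.labels.reshape(state.L, state.L, state.L))
    tables = pd.concat(sector_frames, ignore_index=True) if sector_frames else None
    return ColonyRun(
        params=params,
        snapshots=snapshots,
        final_lattice=final,
        n_seeds=n_seeds,
        status=status,
        sector_tables=tables,
        final_surface=state.surface_indices().copy(),
    )


def replicate_seeds(base_seed: int, n_replicates: int) -> list[int]:
    """Distinct per-replicate seeds from a base seed via SeedSequence spawning."""
    out = []
    for i in range(n_replicates):
        ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(i,))
        out.append(int(ss.generate_state(1, np.uint32)[0] % 2**31))
    return out


def run_ensemble(
    params: SimParams,
    n_replicates: int = 15,
    base_seed: int = 0,
    **run_kwargs,
) -> EnsembleRun:
    """Independent colony replicates with derived distinct seeds."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = replicate_seeds(base_seed, n_replicates)
    runs = [
        run_colony(params, rng_seed=s, replicate=i, **run_kwargs)
        for i, s in enumerate(seeds)
    ]
    return EnsembleRun(params=params, runs=runs, base_seed=base_seed, seeds=seeds)


def _connectivity_offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return FACE_OFFSETS
    if connectivity == 26:
        offs = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
        return np.array(offs, dtype=np.int64)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
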