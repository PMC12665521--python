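"""Desk-scale reentry scenarios: seeded spiral-pair and anatomical-reentry
fixtures on 2D sheets.

These stand in for full-scale atrial simulations: a 50 x 50 mm
monodomain sheet of AF-remodeled Courtemanche tissue with coupling reduced
so that one reentry wavelength fits the domain, seeded by phase
distribution.  A short pre-roll lets the analytic initial condition
organize into true rotors before recording starts (the full-scale protocol
applies pre-pacing beats before its recordings).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .mesh import SampledGraph, sheet_mesh_from_geometry, subsample_mesh
from .sim.courtemanche import RemodelingParams, VARIANTS
from .sim.tissue import (SheetGeometry, TissueSim, detect_termination,
                         limit_cycle)


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


@lru_cache(maxsize=4)
def cached_limit_cycle(variant: str, bcl: float) -> np.ndarray:
    return limit_cycle(VARIANTS[variant], bcl=bcl)


def spiral_pair_phases(geo: SheetGeometry, seed: int) -> np.ndarray:
    """Seeded +-2 pi phase winding around two cores: a counter-rotating
    spiral pair.  The seed randomizes core separation, axis orientation,
    chirality and a global phase offset."""
    rng = np.random.default_rng(seed)
    x, y = geo.positions[:, 0], geo.positions[:, 1]
    cx, cy = geo.width / 2.0, geo.height / 2.0
    sep = rng.uniform(0.4 * geo.width, 0.56 * geo.width)
    ang = rng.uniform(0.0, np.pi)
    chir = rng.choice([-1, 1])
    off = rng.uniform(-np.pi, np.pi)
    dx, dy = sep / 2.0 * np.cos(ang), sep / 2.0 * np.sin(ang)
    theta = chir * (np.arctan2(y - (cy - dy), x - (cx - dx))
                    - np.arctan2(y - (cy + dy), x - (cx + dx))) + off
    return wrap_angle(theta)


def single_winding_phases(geo: SheetGeometry, center=None,
                          chirality: int = 1, offset: float = 0.0):
    """Single 2 pi winding about ``center`` (default domain center): one
    rotor, paired with the outer boundary; around a hole this seeds an
    anatomical reentry."""
    x, y = geo.positions[:, 0], geo.positions[:, 1]
    cx, cy = center if center is not None else (geo.width / 2.0,
                                                geo.height / 2.0)
    return wrap_angle(chirality * np.arctan2(y - cy, x - cx) + offset)


@dataclass
class FixtureRun:
    """A recorded fixture simulation plus its termination bookkeeping."""

    geo: SheetGeometry
    graph: SampledGraph
    times: np.ndarray              # recording grid (absolute ms)
    vm: np.ndarray                 # (nt, n_samples) at graph.sample_ids
    vmax: np.ndarray               # global max Vm per output step
    snapshots: dict                # t -> full state
    t_sp: float | None             # spontaneous termination time
    sim: TissueSim = None


DEFAULT_SHEET = dict(width=50.0, height=50.0, dx=0.5)
DEFAULT_DIFFUSION = 0.06     # mm^2/ms -> CV ~0.23 m/s on the fixture lattice
DEFAULT_DT = 0.1             # ms
DEFAULT_SPACING = 1.5        # mm analysis subsampling on desk-scale sheets
DEFAULT_PRE_ROLL = 400.0     # ms of unrecorded organization


def build_sheet_graph(geo: SheetGeometry,
                      spacing: float = DEFAULT_SPACING) -> SampledGraph:
    return subsample_mesh(sheet_mesh_from_geometry(geo), spacing)


def run_spiral_fixture(seed: int, geo: SheetGeometry | None = None,
                       graph: SampledGraph | None = None,
                       params: RemodelingParams | None = None,
                       diffusion: float = DEFAULT_DIFFUSION,
                       dt: float = DEFAULT_DT,
                       pre_roll: float = DEFAULT_PRE_ROLL,
                       duration: float = 1050.0,
                       checkpoints: tuple = (),
                       theta: np.ndarray | None = None,
                       variant: str = "af") -> FixtureRun:
    """Simulate one seeded spiral-pair fixture and record Vm on the analysis
    samples (5 ms steps), the global max-Vm trace and any requested full
    state snapshots (absolute times, after the pre-roll)."""
    geo = geo or SheetGeometry(**DEFAULT_SHEET)
    if graph is None:
        graph = build_sheet_graph(geo)
    params = params or VARIANTS[variant]
    lc = cached_limit_cycle(variant, 300.0)
    sim = TissueSim(geo, params, diffusion=diffusion, dt=dt)
    if theta is None:
        theta = spiral_pair_phases(geo, seed)
    sim.induce_phases(theta, lc)
    if pre_roll > 0:
        sim.run(pre_roll, out_step=5.0, record_ids=np.array([0]))
    times, vm, vmax, snaps = sim.run(duration, out_step=5.0,
                                     record_ids=graph.sample_ids,
                                     checkpoints=tuple(checkpoints))
    t_sp = detect_termination(times, vmax)
    return FixtureRun(geo, graph, times, vm, vmax, snaps, t_sp, sim)


def lattice_connect(geo: SheetGeometry, vertex_path: np.ndarray) -> np.ndarray:
    """Make a lattice vertex polyline 4-connected by inserting a node at
    each diagonal hop (the 5-point monodomain stencil does not couple
    diagonals, so a diagonal chain would not block conduction)."""
    iy, ix = np.nonzero(geo.active)
    yy = np.full(geo.n_nodes, -1, np.int64)
    xx = np.full(geo.n_nodes, -1, np.int64)
    yy[geo.node_of[iy, ix]] = iy
    xx[geo.node_of[iy, ix]] = ix
    out = []
    path = np.asarray(vertex_path, np.int64)
    for k, v in enumerate(path):
        if k > 0:
            u = path[k - 1]
            if yy[u] != yy[v] and xx[u] != xx[v]:
                cand = geo.node_of[yy[u], xx[v]]
                if cand < 0:
                    cand = geo.node_of[yy[v], xx[u]]
                if cand >= 0:
                    out.append(int(cand))
        out.append(int(v))
    return np.array(out, np.int64)
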