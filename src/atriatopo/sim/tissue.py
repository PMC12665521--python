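"""Monodomain tissue simulation on 1D cables and 2D sheet lattices.

The tissue is a regular lattice of Courtemanche cells coupled by a 5-point
discrete Laplacian (no-flux boundaries).  Sheets may carry circular holes
(anatomical cavities) and conduction-block masks (virtual ablation lines).
The solver is the explicit Rush-Larsen/Euler scheme from
:mod:`atriatopo.sim.courtemanche`.

Recording convention: transmembrane voltage sampled on a fixed output grid
(5 ms analysis step by default), matching the mapping-system-style data the
analysis modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import courtemanche as crn
from .courtemanche import (CellSolver, RemodelingParams, initial_state,
                           N_STATES, IV)


def _crossing_time(t: np.ndarray, v: np.ndarray, thr: float) -> float:
    """First upward threshold crossing, linearly interpolated; nan if none."""
    above = v >= thr
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    if idx.size == 0:
        return np.nan
    i = idx[0]
    frac = (thr - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


def cable_cv(params: RemodelingParams, diffusion: float, n_cells: int = 100,
             dx: float = 0.25, dt: float = 0.02, stim_amp: float = -30.0,
             t_max: float = 200.0) -> float:
    """Conduction velocity (m/s) on a 1D cable at coupling ``diffusion``
    (mm^2/ms), from a linear fit of activation time vs distance over the
    central half of the cable."""
    if n_cells < 20:
        raise ValueError("cable too short for a central-half fit")
    n = n_cells
    solver = CellSolver(n, dt)
    S = np.repeat(initial_state()[:, None], n, axis=1)
    nb = np.tile(np.arange(n, dtype=np.int64), (4, 1))
    nb[0, 1:] = np.arange(n - 1)
    nb[1, :-1] = np.arange(1, n)
    coupling = np.zeros((4, n))
    coupling[0, 1:] = diffusion / dx ** 2
    coupling[1, :-1] = diffusion / dx ** 2

    stim = np.zeros(n)
    stim[:3] = stim_amp
    none = np.zeros(n)
    gna, gto, gkur, gcal = solver.scales(params)

    out_step = 0.2
    rec_every = int(round(out_step / dt))
    n_out = int(round(t_max / out_step))
    vm = np.empty((n_out, n))
    n_stim = int(round(2.0 / dt))
    done = 0
    for k in range(n_out):
        vm[k] = S[IV]
        cur = stim if done < n_stim else none
        crn.advance(S, nb, coupling, gna, gto, gkur, gcal, cur, dt, rec_every,
                    solver.tab, solver.exp_fca, solver.exp_u)
        done += rec_every
    t = np.arange(n_out) * out_step

    lo, hi = n // 4, 3 * n // 4
    lat = np.array([_crossing_time(t, vm[:, i], -40.0) for i in range(lo, hi)])
    if np.any(np.isnan(lat)):
        raise RuntimeError("propagation failure: cable not fully activated")
    x = np.arange(lo, hi) * dx
    slope = np.polyfit(x, lat, 1)[0]  # ms/mm
    if slope <= 0:
        raise RuntimeError("non-positive activation-time slope")
    return 1.0 / slope  # mm/ms == m/s


def calibrate_diffusion(params: RemodelingParams, target_cv: float,
                        n_cells: int = 100, dx: float = 0.25,
                        dt: float = 0.02, tol: float = 0.005,
                        d_lo: float = 0.005, d_hi: float = 1.0) -> float:
    """Bisection on the 1D cable so that ``params`` tissue conducts at
    ``target_cv`` m/s.  CV grows monotonically with diffusion."""
    for _ in range(40):
        d_mid = np.sqrt(d_lo * d_hi)
        try:
            cv = cable_cv(params, d_mid, n_cells=n_cells, dx=dx, dt=dt)
        except RuntimeError:
            d_lo = d_mid
            continue
        if abs(cv - target_cv) <= tol:
            return d_mid
        if cv < target_cv:
            d_lo = d_mid
        else:
            d_hi = d_mid
    return np.sqrt(d_lo * d_hi)


def limit_cycle(params: RemodelingParams, bcl: float = 300.0, beats: int = 12,
                dt: float = 0.02, n_samples: int = 300) -> np.ndarray:
    """Paced limit-cycle trajectory of the cell model.

    Pre-paces ``beats`` beats at basic cycle length ``bcl`` and stores the
    state over the final cycle, sampled at ``n_samples`` points with t=0 at
    the stimulus onset.  Used to seed reentry by phase distribution.
    """
    solver = CellSolver(1, dt)
    S = initial_state()[:, None].copy()
    nb = np.tile(np.arange(1, dtype=np.int64), (4, 1))
    coupling = np.zeros((4, 1))
    stim = np.array([-20.0])
    none = np.zeros(1)
    n_stim = int(round(2.0 / dt))
    n_rest = int(round(bcl / dt)) - n_stim
    for _ in range(beats - 1):
        solver.run(S, nb, coupling, params, stim, n_stim)
        solver.run(S, nb, coupling, params, none, n_rest)
    traj = np.empty((n_samples, N_STATES))
    steps = np.linspace(0, n_stim + n_rest, n_samples + 1).astype(int)
    done = 0
    for k in range(n_samples):
        traj[k] = S[:, 0]
        target = steps[k + 1]
        while done < target:
            cur = stim if done < n_stim else none
            chunk = min(target - done,
                        (n_stim - done) if done < n_stim else (target - done))
            solver.run(S, nb, coupling, params, cur, chunk)
            done += chunk
    return traj


@dataclass
class SheetGeometry:
    """Regular 2D lattice with optional circular holes. Lengths in mm."""

    width: float = 40.0
    height: float = 40.0
    dx: float = 0.5
    holes: tuple = ()  # ((cx, cy, radius), ...)

    nx: int = field(init=False)
    ny: int = field(init=False)
    active: np.ndarray = field(init=False)     # (ny, nx) bool
    node_of: np.ndarray = field(init=False)    # (ny, nx) -> flat id or -1
    positions: np.ndarray = field(init=False)  # (n, 2) mm

    def __post_init__(self):
        self.nx = int(round(self.width / self.dx)) + 1
        self.ny = int(round(self.height / self.dx)) + 1
        xs = np.arange(self.nx) * self.dx
        ys = np.arange(self.ny) * self.dx
        X, Y = np.meshgrid(xs, ys)
        active = np.ones((self.ny, self.nx), bool)
        for cx, cy, r in self.holes:
            active &= (X - cx) ** 2 + (Y - cy) ** 2 > r ** 2
        self.active = active
        self.node_of = np.full((self.ny, self.nx), -1, np.int64)
        self.node_of[active] = np.arange(active.sum())
        self.positions = np.column_stack([X[active], Y[active]])

    @property
    def n_nodes(self) -> int:
        return int(self.active.sum())

    def neighbors4(self):
        """(4, n) neighbor ids (self = missing) for the active lattice."""
        n = self.n_nodes
        nb = np.tile(np.arange(n, dtype=np.int64), (4, 1))
        idx = self.node_of
        iy, ix = np.nonzero(self.active)
        me = idx[iy, ix]
        shifts = ((0, -1), (0, 1), (-1, 0), (1, 0))
        for k, (dy, dxs) in enumerate(shifts):
            y2, x2 = iy + dy, ix + dxs
            valid = (y2 >= 0) & (y2 < self.ny) & (x2 >= 0) & (x2 < self.nx)
            tgt = np.where(valid, idx[np.clip(y2, 0, self.ny - 1),
                                      np.clip(x2, 0, self.nx - 1)], -1)
            good = tgt >= 0
            nb[k, me[good]] = tgt[good]
        return nb


class TissueSim:
    """Monodomain simulation state on a :class:`SheetGeometry`.

    Tracks the block mask (virtual ablation), supports state snapshots and
    records Vm on a fixed output grid plus the global max-Vm trace used for
    termination detection.
    """

    def __init__(self, geometry: SheetGeometry, params: RemodelingParams,
                 diffusion: float, dt: float = 0.05):
        self.geometry = geometry
        self.params = params
        self.diffusion = diffusion
        self.dt = dt
        n = geometry.n_nodes
        self.solver = CellSolver(n, dt)
        self.S = np.repeat(initial_state()[:, None], n, axis=1)
        self.nb = geometry.neighbors4()
        self.coupling = np.where(self.nb != np.arange(n),
                                 diffusion / geometry.dx ** 2, 0.0)
        self.blocked = np.zeros(n, bool)
        self.time = 0.0
        g = self.solver.scales(params)
        self._gna, self._gto, self._gkur, self._gcal = g

    # -- initial conditions ------------------------------------------------
    def induce_phases(self, theta: np.ndarray, trajectory: np.ndarray):
        """Set each node's state from the paced limit cycle at the cycle
        fraction prescribed by the angular phase ``theta`` in [-pi, pi].

        theta = +pi maps to the activation instant (cycle time 0), -pi to the
        end of the cycle, matching the sawtooth phase convention.
        """
        n_samp = trajectory.shape[0]
        frac = (np.pi - np.asarray(theta)) / (2.0 * np.pi)
        k = np.clip((frac * n_samp).astype(int), 0, n_samp - 1)
        self.S = trajectory[k].T.copy()

    def stimulate(self, node_ids: np.ndarray, amp: float = -30.0,
                  duration: float = 2.0):
        """Queue a stimulus applied at the next :meth:`run` call start."""
        self._stim_nodes = np.asarray(node_ids)
        self._stim_amp = amp
        self._stim_left = duration

    _stim_nodes = None
    _stim_amp = 0.0
    _stim_left = 0.0

    # -- block lines -------------------------------------------------------
    def apply_block(self, node_ids) -> None:
        """Decouple the listed nodes (non-conductive): zero all their
        diffusive links, both directions."""
        node_ids = np.asarray(node_ids, dtype=np.int64)
        if node_ids.size == 0:
            return
        self.blocked[node_ids] = True
        blocked = self.blocked
        self.coupling[blocked[self.nb]] = 0.0
        self.coupling[:, blocked] = 0.0

    # -- integration -------------------------------------------------------
    def run(self, duration: float, out_step: float = 5.0,
            record_ids: np.ndarray | None = None,
            checkpoints: tuple = (),
            early_stop: float | None = None):
        """Advance ``duration`` ms.

        Returns (times, vm, vmax, snaps): Vm sampled at ``record_ids`` (all
        nodes if None) every ``out_step`` ms, the per-step global Vm maximum,
        and full state snapshots at the requested absolute ``checkpoints``.
        Samples are taken at the *start* of each output interval.

        ``early_stop`` (mV): end the run once the global max Vm has stayed
        below this level for 3 consecutive outputs -- deeply resting tissue
        without stimulus cannot reactivate.  Outputs are truncated.
        """
        n = self.geometry.n_nodes
        if record_ids is None:
            record_ids = np.arange(n)
        rec_every = int(round(out_step / self.dt))
        n_out = int(round(duration / out_step))
        times = self.time + np.arange(n_out) * out_step
        vm = np.empty((n_out, len(record_ids)))
        vmax = np.empty(n_out)
        snaps = {}
        istim = np.zeros(n)
        for k in range(n_out):
            for tc in checkpoints:
                if abs(self.time - tc) < 0.5 * out_step and tc not in snaps:
                    snaps[tc] = self.S.copy()
            vm[k] = self.S[IV, record_ids]
            vmax[k] = self.S[IV].max()
            istim[:] = 0.0
            if self._stim_nodes is not None and self._stim_left > 0:
                istim[self._stim_nodes] = self._stim_amp
                self._stim_left -= out_step
            crn.advance(self.S, self.nb, self.coupling, self._gna, self._gto,
                        self._gkur, self._gcal, istim, self.dt, rec_every,
                        self.solver.tab, self.solver.exp_fca,
                        self.solver.exp_u)
            self.time += out_step
            if (early_stop is not None and k >= 2
                    and np.all(vmax[k - 2:k + 1] < early_stop)):
                return times[:k + 1], vm[:k + 1], vmax[:k + 1], snaps
        return times, vm, vmax, snaps

    def snapshot(self) -> np.ndarray:
        return self.S.copy()

    def restore(self, S: np.ndarray, time: float):
        self.S = S.copy()
        self.time = time


def detect_termination(times: np.ndarray, vmax: np.ndarray,
                       threshold: float = -40.0) -> float | None:
    """Earliest time after which every node stays below ``threshold`` mV.

    ``vmax`` is the per-output-step maximum Vm over all nodes (a (nt, n)
    voltage matrix is reduced along its point axis first).  Returns None if
    activity persists to the end of the recording.
    """
    vmax = np.asarray(vmax)
    if vmax.ndim == 2:
        vmax = vmax.max(axis=1)
    below = vmax < threshold
    if not below[-1]:
        return None
    # last index where activity was present
    above = np.nonzero(~below)[0]
    if above.size == 0:
        return float(times[0])
    i = above[-1] + 1
    return float(times[i])
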