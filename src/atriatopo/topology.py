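"""Topological charge by signed phase-jump counting, and Index-Theorem
adherence metrics.

The topological charge of a node is the net number of phase jumps around
its cyclically ordered neighbor ring: a raw phase difference above +pi
contributes +1, below -pi contributes -1.  On a closed surface the charges
summed over all nodes (cavity nodes included) must cancel -- the Index
Theorem -- so the fraction of time the cluster-index sum is zero (``f0``)
and the mean signed sum (``mind``) measure how faithfully the discrete
detection honors it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MeshStructureError
from .mesh import SampledGraph


def jump_sign(delta_phi: float) -> int:
    """Signed phase-jump classification: -1 if x < -pi, +1 if x > pi, else 0
    (strict inequalities)."""
    if delta_phi > np.pi:
        return 1
    if delta_phi < -np.pi:
        return -1
    return 0


@dataclass
class ChargeField:
    """Integer topological charge per node per analysis timestep."""

    times: np.ndarray          # (nt,)
    tc: np.ndarray             # (nt, n_nodes) int
    flagged: np.ndarray        # (nt, n_nodes) bool: masked/degenerate ring


def topological_charge(phi_t: np.ndarray, defined_t: np.ndarray,
                       graph: SampledGraph):
    """One timestep of charge detection.

    ``phi_t``/``defined_t`` are indexed by sample id (cavity nodes carry no
    phase of their own).  Ring members without a phase -- cavity nodes and
    masked samples (functionally blocked tissue) -- are dropped and the ring
    closes over the remaining members: the loop deforms around the obstacle,
    which keeps the sum an integer winding.  A ring left with fewer than 3
    phased members is flagged with TC = 0.
    """
    n = graph.n_nodes
    tc = np.zeros(n, np.int64)
    flagged = np.zeros(n, bool)
    for p in range(n):
        ring = graph.neighbors[p]
        if len(ring) < 3 or graph.flagged[p]:
            flagged[p] = True
            continue
        ring_s = [q for q in ring
                  if q < graph.n_samples and defined_t[q]]
        if len(ring_s) < 3:
            flagged[p] = True
            continue
        total = 0
        m = len(ring_s)
        for k in range(m):
            d = phi_t[ring_s[(k + 1) % m]] - phi_t[ring_s[k]]
            if d > np.pi:
                total += 1
            elif d < -np.pi:
                total -= 1
        tc[p] = total
    return tc, flagged


def charge_field(phase, graph: SampledGraph) -> ChargeField:
    """Topological charge at every analysis timestep.

    ``phase`` is a :class:`atriatopo.phase.PhaseField` whose columns follow
    ``graph`` sample ids 0..n_samples-1.
    """
    if any(len(nb) == 0 for nb in graph.neighbors):
        raise MeshStructureError("graph contains an isolated node")
    nt = len(phase.times)
    tc = np.zeros((nt, graph.n_nodes), np.int64)
    flagged = np.zeros((nt, graph.n_nodes), bool)
    for it in range(nt):
        tc[it], flagged[it] = topological_charge(
            phase.phi[it], phase.defined[it], graph)
    return ChargeField(phase.times, tc, flagged)


@dataclass
class IndexMetrics:
    f0: float                  # fraction of analyzed timesteps with sum 0
    mind: float                # time-mean signed cluster-index sum
    n_steps: int


def index_metrics(cluster_sums: np.ndarray, times: np.ndarray,
                  t_start: float = 50.0,
                  t_stop: float | None = None) -> IndexMetrics:
    """f0 and mind over the analyzed span [t_start, t_stop]."""
    times = np.asarray(times, float)
    sums = np.asarray(cluster_sums)
    sel = times >= t_start
    if t_stop is not None:
        sel &= times <= t_stop
    if not np.any(sel):
        raise ValueError("empty analysis span")
    s = sums[sel]
    return IndexMetrics(float(np.mean(s == 0)), float(np.mean(s)), int(s.size))
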