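"""Virtual ablation planning: pair opposite-chirality singularities and
connect them with conduction-block lines.

Three strategies share the same pairing machinery and differ only in the
edge weight driving the path search:

* ``heuristic`` -- weight d_euc(x,y) (phi_x + 1.1 pi)(phi_y + 1.1 pi): cheap
  through resting tissue about to be activated (phase near -pi), expensive
  through freshly activated tissue, so lines preferentially block the wave
  path in front of the wavefront.  Cavity-node links cost 0, prioritizing
  paths through anatomical obstacles.
* ``straight`` -- plain geodesic distance (shortest path on the surface).
* ``random`` -- geodesic lines between random point pairs drawn from the
  same geodesic-distance decile as the corresponding singularity pair.

Pairing minimizes the total line cost with an exact assignment solve.
A virtual ablation succeeds if all activity ceases within 400 ms of block
creation, with spontaneous-termination tie-break rules.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import PlanningFailureError
from .mesh import SampledGraph, project_to_full_mesh
from .tracking import Cluster, cluster_timestep
from .topology import ChargeField

log = logging.getLogger(__name__)

ABLATION_WINDOW = 400.0   # ms between block creation and the outcome check


def heuristic_weight(d_euc: float, phi_x: float, phi_y: float) -> float:
    """Phase-aware edge weight d_euc (phi_x + 1.1 pi)(phi_y + 1.1 pi);
    strictly positive for phases in [-pi, pi]."""
    return d_euc * (phi_x + 1.1 * np.pi) * (phi_y + 1.1 * np.pi)


def make_heuristic_weights(graph: SampledGraph, phi_t: np.ndarray,
                           defined_t: np.ndarray):
    """Edge-weight function from the phase snapshot at the ablation time.
    Cavity nodes carry no phase; all their links get weight 0.  A masked
    sample phase falls back to 0 (mid-repolarization, neutral cost)."""
    ns = graph.n_samples

    def phi(i):
        if i >= ns or not defined_t[i]:
            return 0.0
        return float(phi_t[i])

    def w(i, j):
        if i >= ns or j >= ns:
            return 0.0
        return heuristic_weight(graph.euclidean(i, j), phi(i), phi(j))

    return w


def geodesic_weights(graph: SampledGraph):
    return lambda i, j: graph.geodesic(i, j)


# ---------------------------------------------------------------------------
# weighted shortest paths (single source, deterministic tie-break)
# ---------------------------------------------------------------------------

def dijkstra_tree(graph: SampledGraph, src: int, weights,
                  no_transit=frozenset()):
    """Single-source shortest paths.  Nodes in ``no_transit`` may terminate
    a path but are never expanded (used to keep surface-geodesic lines from
    shortcutting through anatomical cavities)."""
    n = graph.n_nodes
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, np.int64)
    dist[src] = 0.0
    heap = [(0.0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u] + 1e-12:
            continue
        if u in no_transit and u != src:
            continue
        for v in graph.neighbors[u]:
            v = int(v)
            nd = d + float(weights(u, v))
            if nd < dist[v] - 1e-12:
                dist[v], pred[v] = nd, u
                heapq.heappush(heap, (nd, v))
    return dist, pred


def _extract(pred, src, dst):
    path = [dst]
    while path[-1] != src:
        p = int(pred[path[-1]])
        if p < 0:
            raise PlanningFailureError("unreachable node in plan")
        path.append(p)
    return path[::-1]


# ---------------------------------------------------------------------------
# snapshot balancing
# ---------------------------------------------------------------------------

def plan_snapshot(charge: ChargeField, graph: SampledGraph, t: float,
                  max_retries: int = 100):
    """Clusters at the first analysis timestep >= t whose cluster-index sum
    is zero, advancing one 5 ms step at a time (up to ``max_retries``)."""
    times = charge.times
    it = int(np.searchsorted(times, t - 1e-9))
    if it >= len(times):
        raise PlanningFailureError(f"snapshot time {t} beyond recording")
    for k in range(max_retries + 1):
        if it + k >= len(times):
            raise PlanningFailureError("recording ended before index balance")
        tc = charge.tc[it + k]
        nz = np.nonzero(tc != 0)[0]
        clusters = cluster_timestep(nz, tc, graph) if nz.size else []
        if sum(c.index for c in clusters) == 0:
            return float(times[it + k]), clusters
    raise PlanningFailureError(
        f"index sum not balanced within {max_retries} retries after {t} ms")


# ---------------------------------------------------------------------------
# pairing and line construction
# ---------------------------------------------------------------------------

@dataclass
class AblationPlan:
    strategy: str
    t_abl: float                         # ms (possibly advanced for balance)
    pairs: list = field(default_factory=list)   # (pos Cluster, neg Cluster)
    node_lines: list = field(default_factory=list)  # sampled-node paths
    loops: list = field(default_factory=list)       # closed node cycles
    costs: list = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs))

    def block_vertices(self, graph: SampledGraph) -> np.ndarray:
        """All full-mesh vertices covered by the plan's lines and loops."""
        verts = []
        for path in list(self.node_lines) + list(self.loops):
            verts.append(project_to_full_mesh(graph, path))
        return np.unique(np.concatenate(verts)) if verts else \
            np.array([], np.int64)

    def to_json_obj(self):
        return {
            "strategy": self.strategy,
            "t_abl": self.t_abl,
            "pairs": [[c.members.tolist(), d.members.tolist()]
                      for c, d in self.pairs],
            "lines": [list(map(int, p)) for p in self.node_lines],
            "loops": [list(map(int, p)) for p in self.loops],
            "costs": self.costs,
        }


def match_pairs(cost: np.ndarray):
    """Exact minimum-total-cost perfect matching (assignment problem).
    Rows are positive slots, columns negative slots."""
    cost = np.asarray(cost, float)
    if cost.shape[0] != cost.shape[1]:
        raise PlanningFailureError("unbalanced pairing problem")
    if not np.all(np.isfinite(cost.min(axis=1))):
        raise PlanningFailureError("no finite cost for some singularity")
    big = np.nan_to_num(cost, posinf=1e30)
    rows, cols = linear_sum_assignment(big)
    if not np.all(np.isfinite(cost[rows, cols])):
        raise PlanningFailureError("no finite perfect matching")
    return list(zip(rows.tolist(), cols.tolist()))


def cluster_loop(cluster: Cluster, graph: SampledGraph, weights,
                 no_transit=frozenset()) -> list:
    """Closed conduction-block cycle through every member of a multi-point
    cluster: nearest-neighbor tour (by path cost) plus the closing segment."""
    members = sorted(int(m) for m in cluster.members)
    if len(members) < 2:
        return []
    nt = frozenset(no_transit) - set(members)
    tour = [members[0]]
    rest = set(members[1:])
    segs = []
    while rest:
        dist, pred = dijkstra_tree(graph, tour[-1], weights, nt)
        nxt = min(rest, key=lambda m: (dist[m], m))
        segs.append(_extract(pred, tour[-1], nxt))
        tour.append(nxt)
        rest.discard(nxt)
    dist, pred = dijkstra_tree(graph, tour[-1], weights, nt)
    segs.append(_extract(pred, tour[-1], tour[0]))
    loop = [tour[0]]
    for seg in segs:
        loop.extend(seg[1:])
    return loop


def _expand_slots(clusters):
    """One matching slot per unit of charge (a |index| = 2 cluster hosts two
    reentries and appears twice)."""
    slots = []
    for c in clusters:
        slots.extend([c] * abs(c.index))
    return slots


def plan_lines(strategy: str, graph: SampledGraph, clusters: list,
               weights, t_abl: float,
               no_transit=frozenset()) -> AblationPlan:
    """Pair up opposite-chirality clusters at minimum total cost under the
    given edge weights and build the connecting lines and cluster loops.

    ``no_transit`` nodes (anatomical cavities under surface-geodesic
    strategies) can be line endpoints but are never crossed."""
    pos = _expand_slots([c for c in clusters if c.sign > 0])
    neg = _expand_slots([c for c in clusters if c.sign < 0])
    plan = AblationPlan(strategy, t_abl)
    if len(pos) != len(neg):
        raise PlanningFailureError("unequal positive/negative slot counts")
    if not pos:
        return plan

    # all-source shortest paths from every positive-cluster member
    trees = {}
    for c in pos:
        for m in c.members:
            m = int(m)
            if m not in trees:
                trees[m] = dijkstra_tree(graph, m, weights, no_transit)
    cost = np.empty((len(pos), len(neg)))
    best_ep = {}
    for i, cp in enumerate(pos):
        for j, cn in enumerate(neg):
            options = [(trees[int(a)][0][int(b)], int(a), int(b))
                       for a in cp.members for b in cn.members]
            d, a, b = min(options)
            cost[i, j] = d
            best_ep[i, j] = (a, b)
    pairs = match_pairs(cost)

    seen_lines = set()
    for i, j in pairs:
        a, b = best_ep[i, j]
        plan.pairs.append((pos[i], neg[j]))
        key = (a, b)
        if key in seen_lines:   # duplicated slot of a multi-charge cluster
            continue
        seen_lines.add(key)
        path = _extract(trees[a][1], a, b)
        plan.node_lines.append(path)
        plan.costs.append(float(trees[a][0][b]))
    for c in {id(c): c for c in pos + neg}.values():
        loop = cluster_loop(c, graph, weights, no_transit)
        if loop:
            plan.loops.append(loop)
    return plan


def _cavity_ids(graph: SampledGraph):
    return frozenset(range(graph.n_samples, graph.n_nodes))


def straight_lines(graph: SampledGraph, clusters: list,
                   t_abl: float) -> AblationPlan:
    return plan_lines("straight", graph, clusters, geodesic_weights(graph),
                      t_abl, no_transit=_cavity_ids(graph))


def heuristic_lines(graph: SampledGraph, clusters: list, phi_t, defined_t,
                    t_abl: float) -> AblationPlan:
    w = make_heuristic_weights(graph, phi_t, defined_t)
    return plan_lines("heuristic", graph, clusters, w, t_abl)


def random_lines(reference: AblationPlan, graph: SampledGraph,
                 rng) -> AblationPlan:
    """Random geodesic lines length-matched to a reference plan.

    All sample pairs are binned into geodesic-distance deciles; for each
    reference line a pair is drawn uniformly from the decile of that line's
    endpoint distance and connected by the geodesic path.
    """
    rng = np.random.default_rng(rng)
    ns = graph.n_samples
    iu, ju = np.triu_indices(ns, k=1)
    d_all = graph.dist[:ns, :ns][iu, ju]
    edges = np.quantile(d_all, np.linspace(0, 1, 11))
    plan = AblationPlan("random", reference.t_abl)
    gw = geodesic_weights(graph)
    for path in reference.node_lines:
        a, b = path[0], path[-1]
        d_ref = graph.geodesic(a, b)
        k = int(np.clip(np.searchsorted(edges, d_ref, side="right") - 1,
                        0, 9))
        sel = (d_all >= edges[k]) & (d_all <= edges[k + 1])
        width = 0
        while not np.any(sel):
            width += 1
            lo, hi = max(0, k - width), min(10, k + 1 + width)
            sel = (d_all >= edges[lo]) & (d_all <= edges[hi])
            log.warning("empty distance decile %d widened to [%d, %d]",
                        k, lo, hi)
        pick = rng.choice(np.nonzero(sel)[0])
        a2, b2 = int(iu[pick]), int(ju[pick])
        dist, pred = dijkstra_tree(graph, a2, gw, _cavity_ids(graph))
        rpath = _extract(pred, a2, b2)
        plan.node_lines.append(rpath)
        plan.costs.append(float(dist[b2]))
    return plan


# ---------------------------------------------------------------------------
# outcome bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class OutcomeRecord:
    t_abl: float
    t_end: float
    t_sp: float | None         # spontaneous termination (no-ablation run)
    t_ai: float | None         # termination of the ablated run
    performed: bool
    success: bool


def evaluate_outcome(t_abl: float, t_sp: float | None,
                     t_ai: float | None,
                     window: float = ABLATION_WINDOW,
                     sample_step: float = 10.0) -> OutcomeRecord:
    """Success rules for a virtual ablation delivered at ``t_abl``.

    * spontaneous termination before the ablation time: no ablation is
      performed;
    * otherwise, if spontaneous termination does not occur inside the
      window, success means the ablated run terminates strictly inside
      (t_abl, t_abl + window);
    * if spontaneous termination falls inside the window, success requires
      termination at least one output step (10 ms) before it.
    """
    t_end = t_abl + window
    if t_sp is not None and t_sp < t_abl:
        return OutcomeRecord(t_abl, t_end, t_sp, None, False, False)
    if t_sp is None or t_end < t_sp:
        ok = t_ai is not None and t_abl < t_ai < t_end
    else:
        ok = t_ai is not None and t_abl < t_ai <= t_sp - sample_step
    return OutcomeRecord(t_abl, t_end, t_sp, t_ai, True, bool(ok))
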