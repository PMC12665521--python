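"""Triangulated surface meshes and their subsampled analysis graphs.

The analysis in this package runs on a coarse graph of approximately
even-spaced points sampled from a full-resolution triangulated surface.
Neighborhood structure comes from a geodesic Voronoi diagram: two samples
are neighbors when their Voronoi cells share at least one full-mesh edge.
Each boundary loop of the surface (an anatomical cavity such as a valve or
vein ostium, or the outer rim of a sheet) contributes one synthetic *cavity
node* at the loop centroid, so that rotation around an anatomical obstacle
is detected by the same machinery as a functional rotor.

All lengths are millimetres.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .errors import MeshStructureError, NoPathError, ParameterError


# ---------------------------------------------------------------------------
# surface mesh
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangle mesh with consistent winding and explicit boundary loops."""

    vertices: np.ndarray                 # (nv, 3)
    faces: np.ndarray                    # (nf, 3) int
    boundary_loops: list = field(default=None)  # list of ordered vertex arrays

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.shape[1] == 2:   # planar fixtures
            self.vertices = np.column_stack(
                [self.vertices, np.zeros(len(self.vertices))])
        self.faces = np.asarray(self.faces, np.int64)
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshStructureError("face references an invalid vertex")
        if self.boundary_loops is None:
            self.boundary_loops = self._trace_boundary_loops()

    # -- connectivity ------------------------------------------------------
    def _edge_counts(self):
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        und = np.sort(e, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        if counts.max(initial=0) > 2:
            raise MeshStructureError("non-manifold edge (shared by >2 faces)")
        return e, uniq, counts

    def _trace_boundary_loops(self):
        e, uniq, counts = self._edge_counts()
        bnd = {tuple(x) for x in uniq[counts == 1]}
        # directed boundary half-edges, as they appear in faces
        nxt = {}
        for u, v in e:
            if tuple(sorted((u, v))) in bnd:
                if u in nxt:
                    raise MeshStructureError("inconsistent boundary winding")
                nxt[int(u)] = int(v)
        loops = []
        seen = set()
        for start in sorted(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                cur = nxt[cur]
            # deterministic representation: rotate to smallest vertex first
            k = int(np.argmin(loop))
            loops.append(np.array(loop[k:] + loop[:k], np.int64))
        loops.sort(key=lambda l: int(l[0]))
        return loops

    def edge_graph(self) -> sparse.csr_matrix:
        """Sparse symmetric graph of full-mesh edges weighted by length."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                           axis=1)
        n = len(self.vertices)
        g = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
        g = g.maximum(g.T)
        return g.tocsr()

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals from face winding (outward when the
        winding is consistent and outward)."""
        v = self.vertices
        f = self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for k in range(3):
            np.add.at(normals, f[:, k], fn)
        lens = np.linalg.norm(normals, axis=1)
        ok = lens > 1e-12
        normals[ok] /= lens[ok, None]
        return normals

    def mean_edge_length(self) -> float:
        g = self.edge_graph().tocoo()
        return float(g.data.mean())

    def flipped(self) -> "SurfaceMesh":
        """Mirror-orientation copy (reversed face winding)."""
        return SurfaceMesh(self.vertices.copy(), self.faces[:, ::-1].copy())


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_sheet_mesh(width: float = 40.0, height: float = 40.0,
                    dx: float = 0.5, holes: tuple = ()) -> SurfaceMesh:
    """Flat rectangular sheet in the z=0 plane, triangulated lattice, +z
    normals.  ``holes`` is a sequence of (cx, cy, radius)."""
    from .sim.tissue import SheetGeometry
    geo = SheetGeometry(width=width, height=height, dx=dx, holes=tuple(holes))
    return sheet_mesh_from_geometry(geo)


def sheet_mesh_from_geometry(geo) -> SurfaceMesh:
    """Triangulate a :class:`atriatopo.sim.tissue.SheetGeometry`; vertex ids
    equal simulation node ids."""
    pos3 = np.column_stack([geo.positions, np.zeros(geo.n_nodes)])
    idx = geo.node_of
    faces = []
    for y in range(geo.ny - 1):
        for x in range(geo.nx - 1):
            v00, v10 = idx[y, x], idx[y, x + 1]
            v01, v11 = idx[y + 1, x], idx[y + 1, x + 1]
            if min(v00, v10, v01, v11) < 0:
                continue
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return SurfaceMesh(pos3, np.array(faces, np.int64))


def make_sphere_mesh(radius: float = 20.0, subdivisions: int = 4) -> SurfaceMesh:
    """Closed icosphere (no boundary loops)."""
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def make_punctured_sphere(radius: float = 20.0, subdivisions: int = 4,
                          holes: tuple = ((np.array([0, 0, 1.0]), 0.4),)
                          ) -> SurfaceMesh:
    """Sphere with circular caps removed: one boundary loop (anatomical
    cavity) per hole.  ``holes`` entries are (axis unit vector, angular
    radius in radians)."""
    mesh = make_sphere_mesh(radius, subdivisions)
    keep = np.ones(len(mesh.faces), bool)
    centers = mesh.vertices[mesh.faces].mean(axis=1)
    cn = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    for axis, ang in holes:
        a = np.asarray(axis, float)
        a = a / np.linalg.norm(a)
        keep &= cn @ a < np.cos(ang)
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(len(mesh.vertices), np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces])


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------

def load_mesh(path: str) -> SurfaceMesh:
    """Load PLY (ascii), OFF or VTK legacy ascii polydata."""
    p = str(path)
    if p.lower().endswith(".vtk"):
        return _read_vtk_polydata(p)
    import trimesh
    m = trimesh.load(p, process=False, force="mesh")
    return SurfaceMesh(np.asarray(m.vertices, float), np.asarray(m.faces))


def _read_vtk_polydata(path: str) -> SurfaceMesh:
    # minimal reader for legacy ascii POLYDATA with POINTS + POLYGONS
    with open(path) as fh:
        tokens = fh.read().split()
    t = [x.upper() for x in tokens]
    ip = t.index("POINTS")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3:ip + 3 + 3 * n], float).reshape(n, 3)
    ig = t.index("POLYGONS")
    ncell = int(tokens[ig + 1])
    data = tokens[ig + 3:]
    faces = []
    k = 0
    for _ in range(ncell):
        c = int(data[k])
        if c != 3:
            raise MeshStructureError("only triangle POLYGONS supported")
        faces.append([int(data[k + 1]), int(data[k + 2]), int(data[k + 3])])
        k += c + 1
    return SurfaceMesh(coords, np.array(faces, np.int64))


def write_vtk_polydata(path: str, vertices: np.ndarray,
                       faces: np.ndarray | None = None,
                       lines: list | None = None) -> None:
    """Write legacy ascii VTK polydata (triangles and/or polylines)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natriatopo export\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for p in np.asarray(vertices, float):
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        if faces is not None and len(faces):
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if lines:
            total = sum(len(l) + 1 for l in lines)
            fh.write(f"LINES {len(lines)} {total}\n")
            for l in lines:
                fh.write(" ".join([str(len(l))] + [str(int(i)) for i in l])
                         + "\n")


# ---------------------------------------------------------------------------
# sampled analysis graph
# ---------------------------------------------------------------------------

@dataclass
class SampledGraph:
    """Subsampled surface with cavity nodes and ordered neighborhoods.

    Node ids 0..n_samples-1 are surface samples (``sample_ids`` maps them to
    full-mesh vertices); ids n_samples.. are cavity nodes, one per boundary
    loop of the mesh.
    """

    mesh: SurfaceMesh
    sample_ids: np.ndarray               # (ns,) full-mesh vertex ids
    positions: np.ndarray                # (ns + nc, 3)
    neighbors: list                      # per node: cyclically ordered ids
    cavity_loops: list                   # per cavity node: loop vertex array
    mu_d: float
    dist: np.ndarray                     # (nt, nt) geodesic distances
    voronoi_assignment: np.ndarray       # (nv,) vertex -> sample id
    flagged: np.ndarray                  # (nt,) degenerate-normal mask

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def is_cavity(self, i: int) -> bool:
        return i >= self.n_samples

    def geodesic(self, i: int, j: int) -> float:
        return float(self.dist[i, j])

    def euclidean(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    def edges(self):
        """Unique symmetric adjacency pairs (i < j)."""
        out = []
        for i, nbr in enumerate(self.neighbors):
            for j in nbr:
                if i < j:
                    out.append((i, int(j)))
        return out

    def to_json(self, path: str) -> None:
        obj = {
            "sample_ids": self.sample_ids.tolist(),
            "positions": self.positions.tolist(),
            "neighbors": [list(map(int, nb)) for nb in self.neighbors],
            "cavity": [{"loop": loop.tolist()} for loop in self.cavity_loops],
            "mu_d": self.mu_d,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def subsample_mesh(mesh: SurfaceMesh, spacing: float = 2.0,
                   start_vertex: int = 0) -> SampledGraph:
    """Subsample to approximately even spacing and build the
    cavity-augmented geodesic Voronoi neighbor graph.

    Farthest-point sampling on geodesic distance guarantees pairwise sample
    spacing >= ``spacing`` and coverage radius < ``spacing``; neighbor lists
    are sorted counterclockwise around the outward vertex normal.
    """
    if spacing <= mesh.mean_edge_length():
        raise ParameterError("spacing must exceed the mesh edge length")
    g = mesh.edge_graph()
    nv = len(mesh.vertices)

    # farthest-point sampling
    samples = [int(start_vertex)]
    mind = dijkstra(g, indices=start_vertex, min_only=False)
    if np.isinf(mind).any():
        raise MeshStructureError("mesh is not connected")
    while True:
        far = int(np.argmax(mind))
        if mind[far] < spacing:
            break
        samples.append(far)
        mind = np.minimum(mind, dijkstra(g, indices=far))
    sample_ids = np.array(sorted(samples), np.int64)
    ns = len(sample_ids)

    # geodesic Voronoi assignment (ties -> lowest sample index)
    dmat = dijkstra(g, indices=sample_ids)        # (ns, nv)
    assignment = np.argmin(dmat, axis=0)

    # sample-sample adjacency: Voronoi cells sharing >= 1 full-mesh edge
    coo = sparse.triu(g.tocoo())
    a, b = assignment[coo.row], assignment[coo.col]
    adj = [set() for _ in range(ns)]
    for i, j in zip(a[a != b], b[a != b]):
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))

    # cavity nodes, one per boundary loop
    loops = mesh.boundary_loops
    nc = len(loops)
    positions = np.vstack([mesh.vertices[sample_ids]] +
                          [mesh.vertices[loop].mean(axis=0)[None]
                           for loop in loops]) if nc else \
        mesh.vertices[sample_ids].copy()
    for c, loop in enumerate(loops):
        cid = ns + c
        adj.append(set())
        for s in np.unique(assignment[loop]):
            adj[cid].add(int(s))
            adj[int(s)].add(cid)

    # geodesic distance matrix over samples + cavity nodes
    nt = ns + nc
    dist = np.zeros((nt, nt))
    dist[:ns, :ns] = 0.5 * (dmat[:, sample_ids] + dmat[:, sample_ids].T)
    for c, loop in enumerate(loops):
        dfield = dijkstra(g, indices=loop, min_only=True)
        dist[ns + c, :ns] = dfield[sample_ids]
        dist[:ns, ns + c] = dfield[sample_ids]
        for c2, loop2 in enumerate(loops[:c]):
            dcc = float(dfield[loop2].min())
            dist[ns + c, ns + c2] = dist[ns + c2, ns + c] = dcc

    # mean neighbor distance over sample-sample links
    pair_d = [dist[i, j] for i in range(ns) for j in adj[i]
              if j < ns and i < j]
    mu_d = float(np.mean(pair_d)) if pair_d else 0.0

    graph = SampledGraph(
        mesh=mesh, sample_ids=sample_ids, positions=positions,
        neighbors=[np.array(sorted(s), np.int64) for s in adj],
        cavity_loops=[loop.copy() for loop in loops], mu_d=mu_d, dist=dist,
        voronoi_assignment=assignment,
        flagged=np.zeros(nt, bool),
    )
    return order_neighbors(graph, mesh)


def _ccw_order(center: np.ndarray, normal: np.ndarray,
               pts: np.ndarray) -> np.ndarray:
    """Indices sorting ``pts`` counterclockwise around ``normal`` as seen
    from the normal side (right-handed tangent basis)."""
    n = normal / np.linalg.norm(normal)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(n)))] = 1.0
    e1 = np.cross(ref, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = pts - center
    ang = np.arctan2(rel @ e2, rel @ e1)
    return np.argsort(ang, kind="stable")


def order_neighbors(graph: SampledGraph, mesh: SurfaceMesh) -> SampledGraph:
    """Sort each node's neighbor list counterclockwise as seen from outside
    the surface.  Nodes with degenerate normals are flagged and excluded
    from singularity detection."""
    normals = mesh.vertex_normals()
    ns = graph.n_samples
    ordered = []
    for i in range(graph.n_nodes):
        nbr = np.asarray(graph.neighbors[i], np.int64)
        if len(nbr) < 2:
            ordered.append(nbr)
            continue
        if i < ns:
            nrm = normals[graph.sample_ids[i]]
            if np.linalg.norm(nrm) < 1e-12:
                graph.flagged[i] = True
                ordered.append(nbr)
                continue
            order = _ccw_order(graph.positions[i], nrm, graph.positions[nbr])
            ordered.append(nbr[order])
        else:
            # Cavity ring: order neighbor samples by first appearance along
            # the boundary loop, then reverse.  The loop direction inherited
            # from face winding runs counterclockwise around the *surface*;
            # the virtual cap closing the hole is oriented the other way, so
            # its ring (counterclockwise as seen from outside the cap) is the
            # reversed traversal.  This keeps cavity charges consistent with
            # sample charges and flips with mesh orientation.
            loop = graph.cavity_loops[i - ns]
            owner = graph.voronoi_assignment[loop]
            first = {}
            for k, s in enumerate(owner):
                first.setdefault(int(s), k)
            ring = sorted((int(s) for s in nbr), key=lambda s: first.get(s, 0))
            ordered.append(np.array(ring[::-1], np.int64))
    graph.neighbors = ordered
    return graph


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

def geodesic_path(graph: SampledGraph, src: int, dst: int,
                  weights=None) -> list:
    """Lowest-cost path on the sampled graph under an edge-weight function
    ``weights(i, j)`` (geodesic edge length if None).  Equal-cost ties
    resolve deterministically by heap order (lowest node id settles
    first)."""
    if src == dst:
        raise ParameterError("src and dst must differ")
    if weights is None:
        weights = lambda i, j: graph.geodesic(i, j)
    n = graph.n_nodes
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, np.int64)
    dist[src] = 0.0
    heap = [(0.0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u] + 1e-12:
            continue
        for v in graph.neighbors[u]:
            v = int(v)
            nd = d + float(weights(u, v))
            if nd < dist[v] - 1e-12:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    if not np.isfinite(dist[dst]):
        raise NoPathError(f"no path from {src} to {dst}")
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def path_cost(graph: SampledGraph, path, weights=None) -> float:
    if weights is None:
        weights = lambda i, j: graph.geodesic(i, j)
    return float(sum(weights(path[k], path[k + 1])
                     for k in range(len(path) - 1)))


def _full_mesh_segment(mesh: SurfaceMesh, g: sparse.csr_matrix,
                       u: int, v: int) -> list:
    _, pred = dijkstra(g, indices=u, return_predecessors=True)
    if pred[v] < 0 and u != v:
        raise NoPathError("full mesh disconnected along projection")
    seg = [v]
    while seg[-1] != u:
        seg.append(int(pred[seg[-1]]))
    return seg[::-1]


def project_to_full_mesh(graph: SampledGraph, path) -> np.ndarray:
    """Translate a sampled-node path into a connected full-mesh vertex
    polyline.  Cavity-node hops are routed through the nearest boundary-loop
    vertex."""
    mesh = graph.mesh
    g = mesh.edge_graph()
    ns = graph.n_samples

    def anchor(node, other_vertex):
        """Full-mesh vertex standing for ``node`` on a hop toward
        ``other_vertex``."""
        if node < ns:
            return int(graph.sample_ids[node])
        loop = graph.cavity_loops[node - ns]
        d = dijkstra(g, indices=other_vertex)
        return int(loop[np.argmin(d[loop])])

    verts = []
    for k in range(len(path) - 1):
        a, b = int(path[k]), int(path[k + 1])
        if a < ns:
            va = int(graph.sample_ids[a])
            vb = anchor(b, va)
        else:
            vb = int(graph.sample_ids[b]) if b < ns else None
            if vb is None:  # cavity-to-cavity hop: bridge nearest rim points
                loop_b = graph.cavity_loops[b - ns]
                loop_a = graph.cavity_loops[a - ns]
                d = dijkstra(g, indices=loop_a, min_only=True)
                vb = int(loop_b[np.argmin(d[loop_b])])
            va = anchor(a, vb)
        seg = _full_mesh_segment(mesh, g, va, vb)
        if verts and verts[-1] == seg[0]:
            seg = seg[1:]
        verts.extend(seg)
    return np.array(verts, np.int64)
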