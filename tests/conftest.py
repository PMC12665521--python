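import numpy as np
import pytest

from atriatopo.mesh import make_sheet_mesh, make_sphere_mesh, subsample_mesh


def wrap(a):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


@pytest.fixture(scope="session")
def grid_mesh():
    return make_sheet_mesh(20.0, 20.0, 0.5)


@pytest.fixture(scope="session")
def grid_graph(grid_mesh):
    return subsample_mesh(grid_mesh, 2.0)


@pytest.fixture(scope="session")
def sphere_graph():
    return subsample_mesh(make_sphere_mesh(20.0, 4), 2.0)


# ---------------------------------------------------------------------------
# analytic phase fields and the independent winding-number oracle
# ---------------------------------------------------------------------------

def planar_field(cores):
    """phi(x, y) = wrap(sum q_i atan2(y - y_i, x - x_i)) for cores
    [(x, y, q), ...]; evaluated on 3D positions, z ignored."""
    def phi(p):
        p = np.atleast_2d(p)
        total = np.zeros(len(p))
        for (cx, cy, q) in cores:
            total += q * np.arctan2(p[:, 1] - cy, p[:, 0] - cx)
        return wrap(total)
    return phi


def sphere_field(axes):
    """Sum of longitudes about the given axes: each term has winding +1 at
    one pole of its axis and -1 at the other, so singularities come in
    balanced pairs.  ``axes`` is [(unit_axis, q), ...]."""
    def phi(p):
        p = np.atleast_2d(p)
        total = np.zeros(len(p))
        for a, q in axes:
            a = np.asarray(a, float)
            a = a / np.linalg.norm(a)
            ref = np.zeros(3)
            ref[int(np.argmin(np.abs(a)))] = 1.0
            e1 = np.cross(ref, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(a, e1)
            total += q * np.arctan2(p @ e2, p @ e1)
        return wrap(total)
    return phi


def ring_winding(phi_fn, graph, node, n_dense=400):
    """Continuous winding number of an analytic phase field along a node's
    neighbor-ring polygon, by dense numerical line integral of the wrapped
    phase increments (independent of the jump-counting implementation)."""
    ring = [q for q in graph.neighbors[node] if q < graph.n_samples]
    pts = graph.positions[ring]
    poly = np.vstack([pts, pts[:1]])
    dense = []
    for k in range(len(poly) - 1):
        t = np.linspace(0.0, 1.0, n_dense, endpoint=False)[:, None]
        dense.append(poly[k] + t * (poly[k + 1] - poly[k]))
    dense = np.vstack(dense + [poly[:1]])
    vals = phi_fn(dense)
    total = wrap(np.diff(vals)).sum()
    w = total / (2.0 * np.pi)
    assert abs(w - round(w)) < 1e-6, "oracle integral not quantized"
    return int(round(w))
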