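"""Diagnostic plots: phase snapshots with singularity detections, and
singularity-count (hot-spot) maps.  Matplotlib only; intended for quick
visual checks of fixture runs, not publication figures."""

from __future__ import annotations

import numpy as np


def plot_phase_snapshot(analysis, it: int, ax=None):
    """Scatter the sampled phase field at timestep ``it`` with singular
    detections circled (red +, blue -)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    g = analysis.graph
    ns = g.n_samples
    pos = g.positions[:ns]
    phi = np.where(analysis.phase.defined[it], analysis.phase.phi[it], np.nan)
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=phi, cmap="twilight",
                    vmin=-np.pi, vmax=np.pi, s=14)
    tc = analysis.charge.tc[it]
    for sign, color in ((1, "red"), (-1, "blue")):
        sel = np.nonzero(np.sign(tc) == sign)[0]
        sel = sel[sel < ns]
        ax.scatter(pos[sel, 0], pos[sel, 1], facecolors="none",
                   edgecolors=color, s=90, linewidths=1.6)
    ax.set_aspect("equal")
    ax.set_title(f"phase @ t={analysis.phase.times[it]:.0f} ms")
    return sc


def plot_sc_map(analysis, ax=None):
    """Singularity-count hot-spot map Sc(p)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    g = analysis.graph
    ns = g.n_samples
    pos = g.positions[:ns]
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=analysis.sc_map.sc[:ns],
                    cmap="inferno", s=14)
    ax.set_aspect("equal")
    ax.set_title("singularity count Sc(p)")
    return sc


def plot_plan(plan, graph, ax=None):
    """Overlay a plan's lines and loops on the sample layout."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    pos = graph.positions
    ax.scatter(pos[:graph.n_samples, 0], pos[:graph.n_samples, 1],
               s=4, color="0.8")
    for path in plan.node_lines:
        p = pos[np.asarray(path)]
        ax.plot(p[:, 0], p[:, 1], "-", color="crimson", lw=2)
    for loop in plan.loops:
        p = pos[np.asarray(list(loop) + [loop[0]])]
        ax.plot(p[:, 0], p[:, 1], "-", color="darkorange", lw=2)
    ax.set_aspect("equal")
    ax.set_title(f"{plan.strategy} plan @ {plan.t_abl:.0f} ms")
    return ax
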