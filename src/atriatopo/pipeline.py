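"""End-to-end orchestration: simulate -> phase -> detect -> track ->
metrics -> plan -> ablate -> evaluate.

The library modules stay independent; this module wires them together for
scripted runs and the command line, and owns the report formats (metrics
CSV, plan JSON, outcome table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import ablation as abl
from .mesh import SampledGraph, project_to_full_mesh
from .phase import (VmRecording, cycle_length_stats, detect_activations,
                    sawtooth_phase)
from .scenarios import (DEFAULT_DIFFUSION, DEFAULT_DT, DEFAULT_PRE_ROLL,
                        FixtureRun, SheetGeometry, build_sheet_graph,
                        lattice_connect, run_spiral_fixture)
from .sim.tissue import detect_termination
from .topology import charge_field, index_metrics
from .tracking import (complexity_metrics, morans_i, report_frame,
                       singularity_count_map, track_singularities)

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    graph: SampledGraph
    recording: VmRecording
    activations: object
    phase: object
    charge: object
    tracks: list
    clusters_by_time: list
    index_sums: np.ndarray
    metrics: object                # IndexMetrics
    complexity: object             # ComplexityMetrics
    cl_stats: object               # CycleLengthStats
    sc_map: object                 # SingularityCountMap


def analyze_recording(rec: VmRecording, graph: SampledGraph,
                      analysis_start: float = 50.0,
                      analysis_stop: float | None = None,
                      t_sp: float | None = None) -> AnalysisResult:
    """Run the full detection chain on a Vm recording sampled on ``graph``.

    The index metrics span [analysis_start, min(analysis_stop, t_sp)].
    """
    acts = detect_activations(rec)
    ph = sawtooth_phase(acts, rec.times)
    cf = charge_field(ph, graph)
    tracks, cbt, sums = track_singularities(cf, graph)
    stop = rec.times[-1] if analysis_stop is None else analysis_stop
    if t_sp is not None:
        stop = min(stop, t_sp)
    if stop <= analysis_start:     # terminated before the analysis window
        im = index_metrics(sums, rec.times, rec.times[0], stop)
    else:
        im = index_metrics(sums, rec.times, analysis_start, stop)
    cm = complexity_metrics(tracks, rec.times)
    try:
        cl = cycle_length_stats(acts)
    except Exception:
        cl = None
    return AnalysisResult(graph, rec, acts, ph, cf, tracks, cbt, sums, im,
                          cm, cl, singularity_count_map(cf))


def plan_all_strategies(analysis: AnalysisResult, t_abl: float,
                        strategies=("heuristic", "straight", "random"),
                        seed: int = 0):
    """Build the requested plans at (balanced) time ``t_abl``.

    Random plans are length-matched to the straight plan (both use plain
    geodesic lines); if only ``random`` is requested the straight plan is
    still built internally as its reference.
    """
    graph = analysis.graph
    t_bal, clusters = abl.plan_snapshot(analysis.charge, graph, t_abl)
    it = int(np.searchsorted(analysis.phase.times, t_bal))
    phi_t = analysis.phase.phi[it]
    def_t = analysis.phase.defined[it]
    plans = {}
    straight = None
    if not clusters:
        for s in strategies:
            plans[s] = abl.AblationPlan(s, t_bal)
        return plans
    if "heuristic" in strategies:
        plans["heuristic"] = abl.heuristic_lines(graph, clusters, phi_t,
                                                 def_t, t_bal)
    if "straight" in strategies or "random" in strategies:
        straight = abl.straight_lines(graph, clusters, t_bal)
        if "straight" in strategies:
            plans["straight"] = straight
    if "random" in strategies:
        plans["random"] = abl.random_lines(straight, graph, seed)
    return plans


def plan_block_nodes(plan: abl.AblationPlan, graph: SampledGraph,
                     geo: SheetGeometry | None = None) -> np.ndarray:
    """Full-mesh vertices to block for a plan; on lattice fixtures the
    polylines are made 4-connected so they actually stop conduction."""
    verts = []
    for path in list(plan.node_lines) + list(plan.loops):
        v = project_to_full_mesh(graph, path)
        if geo is not None:
            v = lattice_connect(geo, v)
        verts.append(v)
    return np.unique(np.concatenate(verts)) if verts else np.array([], np.int64)


@dataclass
class AblationExperiment:
    """Outcome of one strategy at one ablation time on one fixture."""

    strategy: str
    t_abl: float
    outcome: abl.OutcomeRecord
    n_block: int
    plan: abl.AblationPlan


def ablate_and_evaluate(run: FixtureRun, analysis: AnalysisResult,
                        t_abl: float, strategies=("heuristic", "straight",
                                                  "random"),
                        seed: int = 0, dt_record: float = 10.0):
    """Apply each strategy's block at ``t_abl`` (from the stored snapshot)
    and simulate 400 ms forward to judge success.

    The fixture must carry a state snapshot at ``t_abl``.  Returns a list of
    :class:`AblationExperiment` (empty if spontaneous termination precedes
    the ablation time: no ablation is performed).
    """
    from .sim.tissue import TissueSim

    if run.t_sp is not None and run.t_sp < t_abl:
        return [AblationExperiment(s, t_abl,
                                   abl.evaluate_outcome(t_abl, run.t_sp, None),
                                   0, None)
                for s in strategies]
    if t_abl not in run.snapshots:
        raise KeyError(f"no state snapshot at {t_abl} ms")
    plans = plan_all_strategies(analysis, t_abl, strategies, seed=seed)
    out = []
    for s in strategies:
        plan = plans[s]
        block = plan_block_nodes(plan, run.graph, run.geo)
        sim = TissueSim(run.geo, run.sim.params, run.sim.diffusion,
                        run.sim.dt)
        sim.restore(run.snapshots[t_abl], t_abl)
        sim.apply_block(block)
        times, _, vmax, _ = sim.run(abl.ABLATION_WINDOW + dt_record,
                                    out_step=dt_record,
                                    record_ids=np.array([0]),
                                    early_stop=-70.0)
        t_ai = detect_termination(times, vmax)
        rec = abl.evaluate_outcome(t_abl, run.t_sp, t_ai)
        out.append(AblationExperiment(s, t_abl, rec, len(block), plan))
    return out


# ---------------------------------------------------------------------------
# scripted end-to-end runs
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a scripted fixture run (all times ms)."""

    seed: int = 0
    width: float = 50.0
    height: float = 50.0
    dx: float = 0.5
    holes: tuple = ()
    variant: str = "af"
    diffusion: float = DEFAULT_DIFFUSION
    dt: float = DEFAULT_DT
    spacing: float = 1.5
    pre_roll: float = DEFAULT_PRE_ROLL
    duration: float = 1050.0
    analysis_start: float = 450.0
    analysis_stop: float = 1200.0
    ablation_times: tuple = (900.0,)
    strategies: tuple = ("heuristic", "straight", "random")
    induction: str = "pair"        # "pair" | "none" (quiescent control)
    outdir: str = "runs/out"

    def __post_init__(self):
        if list(self.ablation_times) != sorted(self.ablation_times):
            raise ValueError("ablation times must be strictly increasing")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        if path.endswith((".yml", ".yaml")):
            import yaml
            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
        obj["holes"] = tuple(tuple(h) for h in obj.get("holes", ()))
        return cls(**obj)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, analyze, plan and evaluate one fixture; write reports.

    Produces in ``config.outdir``: metrics.csv (summary row), tracks.csv,
    plan_<strategy>_<t>.json, outcomes.csv and provenance.json.  Returns the
    summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo = SheetGeometry(config.width, config.height, config.dx,
                        tuple(config.holes))
    graph = build_sheet_graph(geo, config.spacing)
    theta = None
    if config.induction == "none":   # quiescent control: end-of-cycle state
        theta = np.full(geo.n_nodes, -np.pi)
    run = run_spiral_fixture(config.seed, geo=geo, graph=graph,
                             variant=config.variant,
                             diffusion=config.diffusion, dt=config.dt,
                             pre_roll=config.pre_roll,
                             duration=config.duration,
                             checkpoints=config.ablation_times,
                             theta=theta)
    rec = VmRecording(run.times, run.vm, np.arange(graph.n_samples))
    analysis = analyze_recording(rec, graph, config.analysis_start,
                                 config.analysis_stop, run.t_sp)

    sc = analysis.sc_map.sc[:graph.n_samples].astype(float)
    moran_self = None
    if sc.std() > 0:
        moran_self = morans_i(sc, sc,
                              graph.dist[:graph.n_samples,
                                         :graph.n_samples]).value

    import pandas as pd
    summary = {
        "seed": config.seed,
        "t_sp": run.t_sp,
        "f0": analysis.metrics.f0,
        "mind": analysis.metrics.mind,
        "median_duration_ms": (float(np.median(analysis.complexity.durations))
                               if analysis.complexity.total_count else 0.0),
        "total_singularities": analysis.complexity.total_count,
        "max_simultaneous": analysis.complexity.max_simultaneous,
        "cl_median_ms": analysis.cl_stats.median_cl if analysis.cl_stats
        else np.nan,
        "cl_iqr_ms": analysis.cl_stats.iqr_cl if analysis.cl_stats
        else np.nan,
        "moran_self": moran_self,
    }
    pd.DataFrame([summary]).to_csv(outdir / "metrics.csv", index=False)
    report_frame(analysis.tracks,
                 analysis.complexity).to_csv(outdir / "tracks.csv",
                                             index=False)

    rows = []
    for t_abl in config.ablation_times:
        exps = ablate_and_evaluate(run, analysis, t_abl, config.strategies,
                                   seed=config.seed)
        for e in exps:
            rows.append({"strategy": e.strategy, "t_abl": e.t_abl,
                         "performed": e.outcome.performed,
                         "t_ai": e.outcome.t_ai, "t_sp": e.outcome.t_sp,
                         "success": e.outcome.success,
                         "n_block_vertices": e.n_block})
            if e.plan is not None:
                with open(outdir / f"plan_{e.strategy}_{int(t_abl)}.json",
                          "w") as fh:
                    json.dump(e.plan.to_json_obj(), fh)
    pd.DataFrame(rows).to_csv(outdir / "outcomes.csv", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"config": {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in vars(config).items()}}, fh)
    summary["outcomes"] = rows
    return summary
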