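"""Local activation times, sawtooth phase and cycle-length statistics.

Activation is the upward crossing of a voltage threshold (default -40 mV,
the same threshold used for termination detection), with linear sub-step
interpolation.  The sawtooth phase assigns +pi at the activation instant
and falls linearly to -pi just before the next activation; phase is
undefined (masked) before a point's first and after its last activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError


@dataclass
class VmRecording:
    """Uniformly sampled transmembrane-voltage traces (ms, mV)."""

    times: np.ndarray          # (nt,)
    vm: np.ndarray             # (nt, npoints)
    point_ids: np.ndarray      # (npoints,) sample or vertex ids

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.vm = np.asarray(self.vm, float)
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("recording time grid is not uniform")
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("non-finite voltage in recording")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ActivationSeries:
    """Strictly increasing activation times (ms) per recorded point."""

    activations: list          # list of (k_i,) float arrays
    point_ids: np.ndarray


@dataclass
class PhaseField:
    """Sawtooth phase phi(p, t) in [-pi, pi] with a defined-mask."""

    times: np.ndarray          # (nt,)
    phi: np.ndarray            # (nt, npoints)
    defined: np.ndarray        # (nt, npoints) bool
    point_ids: np.ndarray


@dataclass
class CycleLengthStats:
    median_cl: float           # ms
    iqr_cl: float              # 75th - 25th percentile, ms
    n_intervals: int


def detect_activations(rec: VmRecording, threshold: float = -40.0,
                       min_interval: float = 50.0) -> ActivationSeries:
    """Upward threshold crossings with linear interpolation; crossings within
    ``min_interval`` ms of the previous accepted activation are discarded."""
    t = rec.times
    acts = []
    for p in range(rec.vm.shape[1]):
        v = rec.vm[:, p]
        up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
        times = t[up] + (threshold - v[up]) / (v[up + 1] - v[up]) * rec.step
        kept = []
        for ta in times:
            if not kept or ta - kept[-1] >= min_interval:
                kept.append(float(ta))
        acts.append(np.array(kept))
    return ActivationSeries(acts, np.asarray(rec.point_ids))


def sawtooth_phase(acts: ActivationSeries, times: np.ndarray,
                   extend: str = "backward",
                   mask_long_intervals: float | None = 1.6) -> PhaseField:
    """Map activation times to sawtooth phase on the analysis time grid.

    For t in [t_k, t_{k+1}): phi = pi - 2 pi (t - t_k) / (t_{k+1} - t_k).
    Points with fewer than two activations are fully undefined.

    With ``extend="backward"`` (default) the sawtooth is extended one
    estimated cycle before the first activation, using the first observed
    interval as the cycle length.  Recordings start mid-activity (reentry is
    seeded by phase distribution), so every point is between activations at
    t=0 and a purely interpolated phase would leave the first cycle masked.
    ``extend="none"`` keeps phase undefined outside [t_1, t_last].

    ``mask_long_intervals`` masks the phase inside any activation interval
    longer than that multiple of the pooled median cycle length.  A point
    that skips activations sits in functionally blocked tissue (typically a
    rotor core); interpolating its phase across several cycles fabricates
    values with no electrophysiological meaning.  Such points are treated
    like anatomical obstacles by the charge computation.  None disables the
    mask.
    """
    if extend not in ("backward", "none"):
        raise ValueError("extend must be 'backward' or 'none'")
    times = np.asarray(times, float)
    n_p = len(acts.activations)
    phi = np.zeros((len(times), n_p))
    defined = np.zeros((len(times), n_p), bool)
    max_len = np.inf
    if mask_long_intervals is not None:
        pooled = np.concatenate([np.diff(a) for a in acts.activations
                                 if len(a) >= 2] or [np.array([])])
        if pooled.size:
            max_len = mask_long_intervals * float(np.median(pooled))
    for p, ta in enumerate(acts.activations):
        if len(ta) < 2:
            continue
        if extend == "backward":
            ta = np.concatenate([[2.0 * ta[0] - ta[1]], ta])
        k = np.searchsorted(ta, times, side="right") - 1
        ok = (k >= 0) & (k < len(ta) - 1)
        # exact hit on the final activation: phase is +pi there
        last = times == ta[-1]
        kk = np.clip(k, 0, len(ta) - 2)
        frac = (times - ta[kk]) / (ta[kk + 1] - ta[kk])
        phi[:, p] = np.where(ok, np.pi - 2.0 * np.pi * frac, 0.0)
        phi[last, p] = np.pi
        defined[:, p] = ok | last
        if np.isfinite(max_len):
            stalled = (ta[kk + 1] - ta[kk]) > max_len
            defined[ok & stalled, p] = False
    return PhaseField(times, phi, defined, acts.point_ids)


def cycle_length_stats(acts: ActivationSeries) -> CycleLengthStats:
    """Median and interquartile range of all per-point consecutive
    activation-time differences, pooled over points."""
    diffs = np.concatenate([np.diff(a) for a in acts.activations
                            if len(a) >= 2] or [np.array([])])
    if diffs.size == 0:
        raise UndefinedStatisticError("no activation intervals available")
    q25, q50, q75 = np.percentile(diffs, [25, 50, 75])
    return CycleLengthStats(float(q50), float(q75 - q25), int(diffs.size))
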