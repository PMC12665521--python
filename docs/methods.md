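# Methods

## Overview

`atriatopo` analyses reentry-driven activity on cardiac surfaces through the
topology of its phase field, and plans virtual ablation lines that connect
counter-rotating reentries.  The Index Theorem is the organizing principle:
on a closed surface the winding numbers (topological charges) of a phase
field must sum to zero, so reentries — functional rotors and rotation around
anatomical obstacles alike — exist only in balanced pairs of opposite
chirality.  The package implements the whole chain on synthetic data it
generates itself: a human atrial ionic model with arrhythmogenic remodeling,
monodomain sheet simulations that host spiral-wave pairs, phase mapping,
charge detection, spatiotemporal tracking, and three ablation strategies
with outcome bookkeeping.

## Ionic model and remodeling

The cell model is the Courtemanche–Ramirez–Nattel human atrial model
(21 state variables).  Two remodeled variants are built in, expressed as
multipliers on baseline maximal conductances:

| variant | G_Kur | G_to | G_CaL | G_Na | APD90 @ 2 Hz |
|---|---|---|---|---|---|
| AF-remodeled | 0.5 | 0.5 | 0.3 | 1.0 | ≈ 192 ms |
| fibrotic     | 0.5 | 0.5 | 0.5 | 0.7 | ≈ 230 ms |

APD90 is measured on the final beat after 20 paced beats (basic cycle
length 500 ms, −20 pA/pF stimulus for 2 ms), from the maximum-upstroke time
to 90 % repolarization toward the pre-stimulus diastolic potential.  At
equal coupling the G_Na reduction slows conduction of the fibrotic variant
by ≈ 13 % relative to the AF-remodeled variant on a 1-D cable (0.25 mm
spacing, CV from a linear activation-time fit over the central half).

Integration is Rush–Larsen for the twelve voltage-dependent gates (steady
states and rate factors pre-tabulated on a 0.05 mV grid with linear
interpolation) and forward Euler for Vm, the Ca-release gates and the
concentrations.  Single-cell and cable protocols use dt = 0.02 ms; sheet
fixtures use dt = 0.1 ms, which changes cable CV by < 1 % relative to
dt = 0.05 ms.  The stimulus current is not added to the K+ bookkeeping;
over ≤ 20 beats the resulting drift is negligible.

## Tissue model and desk-scale fixtures

Tissue is a monodomain 5-point-Laplacian lattice with no-flux boundaries;
circular holes stand in for anatomical cavities (valve or vein ostia).
Conduction block (virtual ablation) decouples the listed nodes in both
directions; blocked cells keep their membrane dynamics.

The default reentry fixture is a 50 × 50 mm sheet, dx = 0.5 mm,
AF-remodeled tissue, coupling D = 0.06 mm²/ms.  Two deliberate departures
from a full-scale atrial simulation keep it desk-sized:

* **Coupling is reduced** so CV ≈ 0.23 m/s and one reentry wavelength
  (CV × CL ≈ 45 mm) fits the sheet.  At full-scale CV (0.8 m/s) the
  wavelength is ~150 mm and no 2-D spiral fits any desk-scale domain.
  Wavefronts are consequently under-resolved at dx = 0.5 mm; this adds
  lattice-scale jitter to activation times but leaves rotor-scale topology
  intact.
* **Analysis subsampling is 1.5 mm** on these sheets rather than the 2 mm
  used for atrium-scale meshes, keeping the sample-spacing-to-wavelength
  ratio near the full-scale regime in which jump-counting detection
  operates reliably.  The 2 mm default applies to meshes at anatomical
  scale.

Reentry is induced by phase distribution: a paced limit-cycle trajectory of
the cell model (12 pre-pacing beats, cycle length 300 ms) is sampled at the
cycle fraction prescribed by an angular phase pattern — a ±2π winding
about two cores for a counter-rotating spiral pair, or a single winding for
an anatomical reentry around a hole.  Each seed randomizes core separation
(0.40–0.56 of the sheet width), axis orientation, global phase offset and
chirality.  A 400 ms unrecorded pre-roll lets the analytic pattern organize
into true rotors before analysis, standing in for the pre-pacing beats a
full-scale protocol applies before its recordings.  Recordings are Vm at
5 ms steps on the analysis samples (10 ms for post-ablation outcome runs),
and run one cycle past the analysis window so the sawtooth phase is defined
by interpolation throughout the analyzed span.

What the fixtures do *not* emulate: anatomical fiber anisotropy,
MRI-derived heterogeneity, atrial geometry, and epi–endo structure.
Passing tests therefore show the detection and planning machinery is
correct on controlled spiral/anatomical reentry, not that the full-scale
physiological conclusions transfer.

## Phase mapping

Local activation times are upward crossings of −40 mV (the same threshold
used for termination detection) with linear sub-step interpolation;
crossings within 50 ms of the previous activation are discarded.  The
sawtooth phase is +π at activation, falling linearly to −π at the next
activation.  Two edge rules matter in practice:

* **Backward extension** (default): phase is extended one estimated cycle
  before a point's first activation, using the first observed interval.
  Recordings start mid-activity, and without the extension the first cycle
  of the analysis window is largely masked, producing asymmetric detection
  failures.
* **Stalled-interval masking** (default factor 1.6): phase inside any
  activation interval longer than 1.6 × the pooled median cycle length is
  masked.  A point that skips activations sits in functionally blocked
  tissue — typically a rotor core — and interpolating its phase across
  several cycles fabricates values with no electrophysiological meaning.

## Topological charge and the Index Theorem

Each sample's neighbors (geodesic-Voronoi adjacency on the subsampled
surface) are sorted counterclockwise around the outward normal; the charge
is the sum over consecutive ring pairs of J(Δφ) with J = +1 for Δφ > π,
−1 for Δφ < −π.  Ring members without a phase — cavity nodes and masked
samples — are dropped and the ring closes over the remaining members: the
loop deforms around the obstacle, which preserves integer winding.  Rings
left with fewer than three phased members are flagged and contribute zero.

Every boundary loop of the surface carries a synthetic cavity node at its
centroid.  Its ring is the set of samples owning loop vertices, ordered by
the *reversed* loop traversal: the loop direction inherited from face
winding runs counterclockwise around the surface, and the virtual cap that
would close the hole is oriented the other way.  This single convention
makes anatomical charges cancel functional ones exactly and flip correctly
under mirror reflection.

Sign convention: with the sawtooth orientation above, jump counting yields
TC = −w where w is the winding number of the phase along the
counterclockwise ring.  Chirality labels are a convention; they are applied
uniformly, and orientation flips invert every charge.

Detections are clustered per chirality with DBSCAN (ε = 2 μ_d,
min_samples = 1, geodesic distances), so a ring of detections around one
core counts once; a cluster contributes sign × max |TC| of its members.
Same-chirality clusters in consecutive timesteps are linked when any
member pair lies within ε; splits continue the parent track through the
fragment sharing the most members.  f0 is the fraction of analyzed
timesteps with zero cluster-index sum and m_ind the mean signed sum.  On
the seeded spiral ensembles the median fixture reaches f0 ≈ 0.99; residual
errors are short episodes of co-located spurious ± detections at a rotor
core, the same error class jump-counting detection exhibits on full-scale
atrial simulations; individual cases are not parameter-fixed.

Hot-spot maps sum |TC| per point over time and are compared across runs
with global bivariate Moran's I under a Gaussian geodesic kernel
w_ij = exp(−d_ij²/(2R²)), R = 2 mm, w_ii = 0 (the kernel denominator is
configurable between 2R² and R²; 2R² is the default reading of the
typeset formula).

## Ablation planning

At each requested ablation time the detection snapshot is advanced in 5 ms
steps (at most 100) until the cluster-index sum is zero.  Cluster pairs of
opposite chirality are then matched by an exact assignment solve on
pairwise path costs (cost between clusters = cheapest member-to-member
path; a cluster of |index| > 1 occupies that many matching slots).
Multi-member clusters additionally receive a closed block loop through all
members (nearest-neighbor tour under the strategy's weights).

* *Heuristic* weights: d_euc × (φ_x + 1.1π)(φ_y + 1.1π) with the phase
  frozen at the (balanced) ablation time; cavity links cost zero, so lines
  preferentially run in front of wavefronts and through anatomical
  obstacles.  Masked phases fall back to 0 (neutral cost).
* *Straight* weights: geodesic edge lengths.  Cavity nodes may terminate a
  line but are never transited — a surface geodesic cannot shortcut
  through a hole.
* *Random*: for each singularity line, a uniformly drawn sample pair from
  the same geodesic-distance decile (of all sample pairs), connected by
  its geodesic path; seeded and reproducible.

Planned node paths are projected to the full mesh via per-segment shortest
paths; hops through a cavity node enter and leave the hole at the nearest
rim vertices (no tissue is ablated inside a hole).  On lattice fixtures
polylines are additionally made 4-connected, because the 5-point stencil
does not couple diagonal neighbors.

An ablation at t_abl succeeds if all activity ceases within 400 ms.  When
spontaneous termination (t_sp) interacts with the window: no ablation is
performed if t_sp < t_abl; if t_sp falls inside the window, success
requires termination at least one 10 ms output step before t_sp.

## Numerical and design choices

* Subsampling is farthest-point sampling on graph geodesics (Dijkstra over
  full-mesh edges), started from vertex 0: deterministic, pairwise spacing
  ≥ target, coverage radius < target.  Neighboring samples are those whose
  geodesic Voronoi cells share a full-mesh edge.
* Shortest-path ties resolve by heap order (lowest node id first); all
  planning is deterministic given (config, seed).
* The assignment solve is exact (Jonker–Volgenant via
  `scipy.optimize.linear_sum_assignment`); brute-force permutation search
  is used as a test oracle only.
* Ensemble sizes and run lengths (20 seeds, 1300 ms simulated per seed,
  analysis window 450–1050 ms) were chosen to give stable success-rate
  orderings at desk scale.
* Degenerate inputs: quiescent recordings yield empty activation series,
  fully masked phase, zero charges, empty plans and undefined cycle-length
  statistics (an explicit error, caught by the pipeline and reported as
  NaN).

## Known limitations

* Under-resolved wavefronts on desk-scale lattices add detection noise;
  single fixtures can dip to f0 ≈ 0.92 during brief core-artifact
  episodes.
* The monodomain sheet has no fiber anisotropy (the API accepts per-node
  conductance scaling but fixtures are isotropic).
* Spiral pairs near the sheet rim interact with the no-flux boundary; the
  outer rim is treated as an anatomical boundary with its own cavity node,
  which is correct topologically but has no direct anatomical analogue.
* Success-rate magnitudes at desk scale are not comparable to full-scale
  atrial values; only the ordering of strategies is expected to transfer.
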