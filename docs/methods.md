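# Methods

This note documents the models, estimators, parameter choices, and numerical
conventions used by `gridcoord`, and what the synthetic-data generator does
and does not emulate.

## Synthetic sessions

**Arena.** A disk of radius 75 cm (the standard 150-cm-diameter circular
open field). A torus variant wraps both coordinates on [0, 150) cm and
serves as a boundary-free control: a global translation is an exact symmetry
there, so any residual effect of *identical* map shifts on the disk can be
attributed to walls.

**Trajectory.** Foraging is modeled as an Ornstein–Uhlenbeck velocity
process: per-component stationary SD `speed_scale` = 20 cm/s, relaxation
time `persistence_time` = 1 s, sampled at Δt = 1/120 s, with specular
reflection at the disk wall (wrapping on the torus). The resulting speed is
Rayleigh-like with median ≈ 23 cm/s and >90% of time above the 3-cm/s
movement threshold — chosen once as qualitatively realistic foraging
statistics; the real animals' speed process was not fit. Coverage is
near-uniform: the radial occupancy profile is flat to ±10%. The
coefficient of variation of a 10-cm-bin occupancy histogram has a
revisit-sampling floor of roughly 0.25 at 30 min for any smooth ~20 cm/s
walk and decays as 1/√duration (< 0.2 from ~50 min); the uniformity test
therefore runs a 90-min simulation.

**Tuning curves.** Idealized grid cells are sums of circular Gaussian blobs
on a perfect hexagonal lattice: spacing λ per module, blob variance
0.015·λ² cm² per dimension, peak rate 30 Hz. Within a module all cells share
spacing and orientation; phases are uniform on the unit cell; module
orientations are independent uniform draws. Blobs are narrow (SD ≈ 0.12 λ),
so evaluation sums only the four lattice nodes surrounding a point's unit
cell — exact to ~1e-10 Hz; a 4×4 node neighborhood is used automatically if
a caller widens the blobs beyond SD = 0.15 λ. In torus mode positions are
wrapped before evaluation, making the realized field exactly periodic (at
the cost of a field discontinuity at the seam, irrelevant to the analyses).

**Spikes and ground-truth (in)coordination.** Per-bin counts are Poisson
with mean f_i(x_t + d_m(t))·Δt, independent across neurons given the
trajectory. The per-module offset series d_m(t) moves the *encoded*
position: zero offsets mean perfect coordination by construction; a shared
random walk models coordinated internal drift (the darkness analog);
independent per-module walks model uncoordinated modules. Random-walk drift
is parameterized by its per-axis SD at the end of the session. A darkness
firing-rate reduction is emulated by binomial thinning.

Not emulated: head-direction/speed/border/conjunctive coding, theta
modulation, non-Poisson spiking, and attractor dynamics proper (drift is
injected kinematically). Passing tests therefore demonstrate correctness and
sensitivity of the *analysis* under its own generative assumptions, not that
real MEC data satisfy those assumptions.

## Rate maps and single-cell metrics

Rate maps divide a Gaussian-kernel-smoothed spike histogram by the equally
smoothed occupancy (kernel variance 25 cm² per dimension), using only bins
with speed ≥ 3 cm/s; speed is obtained from central differences smoothed
with a 100-ms boxcar. Classification maps use 9-cm bins; decoding maps and
tuning-curve evaluation use 3-cm bins (both configurable); the decoding
resolution is finer than the smallest blob SD (≈5.5 cm at λ = 45).
Unvisited bins are NaN in maps and floored at ε = 1e-3 Hz wherever maps
enter logs.

The spatial autocorrelogram is the Pearson correlation of the map with its
shifted copy per displacement (≥ 20 overlapping bins). Gridness correlates
the autocorrelogram with copies rotated 30°…150° within annuli: inner
radius just outside the 3-bin center disk, outer radius expanded by 1 bin
per step to the matrix edge; each annulus scores
min(r60, r120) − max(r30, r90, r150), and the score is the mean of the best
step and its two neighbors, giving the theoretical range [−2, 2]. The exact
annulus geometry is a convention of this implementation, recorded here
rather than asserted as canonical. Spatial information is
Σ p_i (λ_i/λ̄) log2(λ_i/λ̄) bits/spike with 0·log 0 = 0.

## Module classification

Features are the vectorized masked autocorrelograms (center 3-bin disk and
out-of-inscribed-circle corners removed), embedded to 2-D with UMAP
(n_neighbors = 15, min_dist = 0.1) and clustered with DBSCAN (eps = 0.8,
min_samples = 5) on the embedding. The hyperparameters are config entries
validated by the synthetic recovery test (≥ 95% agreement, three modules +
untuned cells). Clusters are annotated with gridness statistics and with
spacing/orientation from the six inner peaks of the cluster-mean
autocorrelogram (median distance; median angle mod 60°). The grid/non-grid
rule is mean gridness ≥ 0.4 — the midpoint of the empirical gap between
non-grid (≤ 0.13) and grid (≥ 0.66) clusters — and is configurable. Cluster
quality is scored by a from-scratch implementation of the density-based
cluster validity index (DBCV; all-points core distances,
mutual-reachability MSTs, validity = (min separation − sparseness) /
max(·,·), size-weighted mean), computed with and without the noise points
as a cluster.

## Markov decoder and marginalized likelihood

The filter alternates a Gaussian displacement prior (Σ_ii = 4 cm² per
1/120-s step) with the independent-Poisson emission over 3-cm bins,
renormalizing each step; log Z(t) bookkeeping is exact, and
Σ_t log Z(t) = log p(S_t) (forward algorithm; verified against brute-force
path enumeration to ~1e-15 relative error). Conventions:

- The stated per-step Gaussian (4 cm²) is operative; a nominal diffusion
  coefficient quoted alongside it in the source conventions is treated as
  documentation, since the two disagree under the usual MSD = 4DΔt
  conversion.
- Boundary handling on the disk truncates the kernel at the wall and
  renormalizes per source bin (columns remain stochastic); the torus wraps.
  The kernel is implemented by separable Gaussian convolution truncated at
  6 SD, with a 1e-290 floor on propagated mass guarding truncation zeros.
- The initial prior is uniform over valid bins; the first 5 s are excluded
  from L (configurable burn-in) so the uninformative start does not bias it.
- All bins are decoded; only moving bins (speed ≥ 3 cm/s) enter L and MAE.
- Shift realizations are decoded in one batched pass (R map sets share the
  spike trains), which is mathematically identical to R separate runs.

Rate adjustment between two conditions thins, per neuron and separately for
still/moving strata, the condition with the higher mean rate by the rate
ratio. The permutation control permutes time-bin order either jointly
across neurons (preserving within-bin population synchrony) or per neuron;
both schemes are provided because the original description does not pin the
granularity, and neither is claimed as canonical.

## Kernel decoder and coordination distances

ν_i(t) follows the recursion ν(t) = ν(t−Δt)e^{−Δt/τ} + n(t) with
τ = 100 ms (discrete-time mean r·Δt/(1−e^{−Δt/τ}) ≈ r·τ). The position
field is c + Σ_i ν_i log f_i(r), dropping the occupancy term as a constant
under the dense-translation-invariant-fields assumption; each cell uses its
own map f_i. m̂ is the argmax over valid bins (ties broken to the first
index and counted); û_i is the argmax of module i's field within the disk
of diameter exactly 0.90 × spacing centered on m̂ (the "~90%" convention
pinned for testability), evaluated on the raw log field at bin resolution.
The disk is clipped to the arena; if it contains no bin center the nearest
valid bin is used and the event flagged. δ_i ≤ 0.45 × spacing holds by
construction; the chance level is E‖u‖ = (2/3)(0.45·spacing) = 0.3·spacing
for u uniform in the search disk. Estimates may be computed at a stride of
the tracking clock (kernel counts always run at full resolution first);
analyses here use stride 4 (30 Hz), which leaves the time-averaged
distances unchanged while cutting cost.

At large independent shifts δ saturates toward its chance ceiling (the
search disk caps it), so mean δ(α) flattens near α ≈ 20–25 cm in the
synthetic regime; growth is strictly monotone below that. On the disk,
*identical* shifts at α ≥ 20 cm produce a small (~0.3 cm) systematic rise
in δ from boundary zero-fill — invisible at recorded-data SEM scales,
resolvable at synthetic Monte-Carlo precision, and absent on the torus
where invariance is exact.

Per-bin δ_i and per-bin decoding error share the estimator noise of m̂ (both
are distances from m̂), which alone induces a positive per-bin correlation
of up to ~0.3. Conditional-independence statements are therefore evaluated
at the distribution level: mean δ per decoding-error quantile bin, which is
flat (< 1 cm spread) under shared drift and strongly graded (> 2 cm) under
independent drift.

## Statistics layer

- **MAE**: mean Euclidean distance between decoded and true positions over
  moving bins; its null replaces decoded positions with uniform draws in
  the arena (30 realizations; closed form 128R/(45π) ≈ 0.905R for uniform
  coverage).
- **SEM of correlated series**: Var = ACF0 + 2Σ ACF_i with the biased ACF
  estimator, truncated at the first lag with ACF_i ≤ 0.15·ACF0;
  SEM = √(Var/n). Sweep and drift comparisons use SEM across realizations
  instead when the signal's correlation time is comparable to the session.
- **Pair correlations**: Pearson coefficients of spike trains smoothed with
  a 50-ms Gaussian; the lagged variant averages |r| within ten
  module-stratified groups (stratified random split, fixed seed) and
  reports mean ± SEM over groups per lag.
- **Error segments**: the error series is smoothed with a 50-ms Gaussian;
  small segments are runs ≥ 1 s with smoothed error ≤ 10 cm, large segments
  runs ≥ 1 s within [20 cm, 80th-percentile cutoff], bins above the cutoff
  discarded.
- **Conditional distributions**: δ/Δ histograms per MAE quantile bin
  (5 bins by default), each normalized to unit mass.

## Problem sizes and determinism

Decoded study sessions are 2 minutes at 120 Hz with the full 205-cell,
three-module population; shift sweeps use 6 realizations per magnitude over
α ∈ {0, 5, 10, 15, 20, 25} cm, drift power checks 5 realizations, nulls 30
realizations. These sizes were chosen so every effect of interest is many
SEMs wide at desk scale; the effects (likelihood drops of several nats,
distance ratios of 3–5×) dwarf the realization noise. All stochastic stages
take explicit seeds (the pipeline derives per-stage seeds from one master
seed by hashing), and fixed seeds reproduce results bit-identically.

## Known limitations

- Idealized cells are noiseless hexagonal fields; real grid cells have
  field-to-field rate variability, elliptic distortions, and conjunctive
  tuning that the classifier and decoders are not stress-tested against.
- Drift is injected into the encoded position rather than arising from
  attractor dynamics, so it cannot capture drift-velocity statistics of
  real networks.
- The decoders assume the light-condition tuning curves throughout; that is
  the intended use (comparing conditions under one model), not a claim of
  optimality.
- DBCV is computed on the 2-D embedding (as in the source analysis), so its
  value depends on the embedding hyperparameters.
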