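# gridcoord

Population decoding and coordination analysis for grid-cell modules.

Grid cells in the medial entorhinal cortex fire on hexagonal lattices and are
organized in discrete modules, each with its own lattice spacing and
orientation. Each module's population state is a 2-D phase, so in principle
modules could drift apart when sensory input is poor — yet a coherent
position code requires their phases to move together. `gridcoord` implements
the analysis toolkit for asking, from simultaneous multi-module spike trains,
*do grid modules stay coordinated?* It is aimed at systems neuroscientists
working with large simultaneous MEC recordings (e.g. Neuropixels) or with
continuous-attractor models of the grid system.

The package simulates multi-module populations with controllable ground-truth
coordination, and quantifies coordination in recorded or simulated spike
trains in two complementary ways.

## The two measures

**Trajectory-marginalized likelihood.** With Poisson spiking from tuning
curves f_i and a random-walk prior over trajectories X_t, the likelihood of
the simultaneous spike trains S_t is

    p(S_t) = Σ_{X_t} p(X_t) p(S_t | X_t).

A recursive Bayesian filter with Gaussian displacement prior
(Σ_ii = 4 cm² per Δt = 1/120 s step) and emission
p_S(r;t) = Π_i (f_i(r)Δt)^{n_i} e^{−f_i(r)Δt}/n_i! computes this exactly:
p(S_t) equals the product of the filter's per-step normalizers Z(t), so the
average log likelihood per time bin is

    L = ⟨log Z(t)⟩_t.

L is large only when *some* continuous trajectory explains the whole
population at once — it measures inter-module coherence independently of the
animal's true position.

**Uni-module decoding distances.** An exponential-kernel ML decoder
(ν_i = Σ e^{−(t−t')/τ} ξ_i(t'), τ = 100 ms; r̂ = argmax_r Σ_i ν_i log f_i(r))
yields a multi-module estimate m̂ and, restricted to one module's cells
within a circular area of diameter 0.9 × spacing around m̂, per-module
estimates û_i. The distances δ_i = ‖m̂ − û_i‖ and Δ_ij = ‖û_i − û_j‖ are
direct per-time-bin coordination metrics, with chance level
0.3 × spacing for δ_i.

Decode-time controls dissociate coherence from accuracy: spatial shifts of
the rate maps applied **independently** per module destroy coherence (L
drops, δ/Δ grow), while **identical** shifts for all modules preserve it (L
and δ/Δ flat, decoding error grows all the same). Supporting machinery
includes idealized tuning curves, rate-map estimation, gridness and spatial
information, UMAP/DBSCAN module classification with a DBCV validity index,
spike-rate pair correlations, rate adjustment between conditions, time-bin
permutation controls, error segmentation, and autocorrelation-corrected
standard errors.

## Worked example

`examples/03_shift_sweep.py` simulates a 2-minute session (150-cm disk,
modules of 41/74/90 cells at spacings 45/65/95 cm, 30-Hz peak rates), then
decodes it against shifted rate maps:

```
mode         alpha         L  MAE (cm)
independent      0   -19.295      2.52
independent     10   -20.894      4.63
independent     20   -23.966     56.58
identical        0   -19.295      2.52
identical       10   -19.363      6.31
identical       20   -19.486     15.47
```

At a maximal shift of α = 20 cm, independent shifts cost ~4.7 nats of log
likelihood per time bin while identical shifts cost ~0.2; both inflate the
mean absolute error far above the intact 2.5 cm. The likelihood therefore
isolates *inter-module coherence* from mere misalignment with the true
position. `examples/04_uni_module_coordination.py` shows the same
dissociation in the δ_i/Δ_ij metrics (coordinated: δ ≈ 2–3 cm vs chance
13.5–28.5 cm; independent 10-cm drift: Δ_ij rises from 3.8 to 12.9 cm), and
`examples/01`, `02`, `05` cover decoding, module classification, and the
session container with rate-adjustment/permutation controls.

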