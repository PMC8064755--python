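# Methods

## The single-clock model

The clock state is the concentration vector (φ_T, φ_D, φ_S) of the three
phosphorylated KaiC forms (phospho-Thr432, doubly phosphorylated,
phospho-Ser431), with φ_U = C_tot − φ_T − φ_D − φ_S fixed by conservation of
total KaiC.  The eight interconversions U↔T, T↔D, D↔S, S↔U follow first-order
mass action with KaiA-modulated rates

    k_XY(A) = max(0, k⁰_XY + k^A_XY · A / (K½ + A))        [hr⁻¹]

Default constants are the in vitro values of Rust et al. (Science 2007),
shipped in `filaclock/data/kinetic_rates_invitro.json` (K½ = 0.43 µM,
C_tot = 3.4 µM).  Two of the k^A are negative (KaiA slows the D→S and S→U
dephosphorylations); inside the fitting box the raw law can dip below zero
for A ≳ 2 µM, so rates are clamped at zero.  The clamp is inactive at the
default parameter point.

S-KaiC sequesters KaiA (two KaiA monomers per S-KaiC via KaiB); the sharp
rule A = max(0, [KaiA] − 2 φ_S) is smoothed so the model is differentiable:

* `softplus` (default): A = ([KaiA]/γ) · log(1 + exp(γ(1 − 2φ_S/[KaiA])))
* `logistic`: A = [KaiA] / (1 + exp(γ(2φ_S − [KaiA])/[KaiA]))
* `sharp`: the ramp itself.

γ is dimensionless and controls the smoothing steepness.  The softplus form
is the default because it converges pointwise to the sharp ramp as γ grows
(its slope is an inverted sigmoid saturating at −2) and because it preserves
the dynamical structure the ramp generates: a Hopf bifurcation in the
(γ, [KaiA]) plane whose oscillatory region carries circadian periods near
the boundary, and a stable focus with a ~21.5 h quasi-period at the default
point (γ = 7.2, [KaiA] = 1.308 µM).  The logistic form, though superficially
similar, limits to a *step* function: its fixed point settles far below the
sequestration threshold, eigenvalues are real, and no oscillatory region
exists anywhere in the plane.  It is retained only for comparison.

Fixed points are found by a Powell-hybrid root solve with analytic Jacobian,
multistarted from eight simplex-interior points (warm-started from a caller
guess when available); residual tolerance 1e−10 µM/hr.  The regime is read
off the Jacobian eigenvalues: limit cycle iff max Re λ > 1e−9 hr⁻¹; a stable
focus reports the quasi-cycle period 2π/|Im λ|; a limit-cycle period is
measured on an ODE orbit (LSODA, rtol 1e−9) as mean peak-to-peak time of φ_T
after a 200 h transient.  `hopf_scan` tabulates regime, period and max Re λ
over a (γ, [KaiA]) grid; the 22–28 h circadian band is configurable.

In the plane scanned here (γ ∈ [1, 40], [KaiA] ∈ [0.5, 2.5] µM) the
oscillatory region is a band in [KaiA] roughly 0.7 µM wide; periods rise from
~13 h deep inside to beyond 28 h in a thin layer at the upper-[KaiA]
boundary, so the circadian sub-region is a ~0.1 µM-wide strip lying within
~0.25 µM of that boundary — a small strip near the stability boundary, with
the fitted point just outside it in the quasi-cycle domain.

## Demographic noise

Copy numbers n = (n_T, n_D, n_S) with system size N_tot (molecules of KaiC
per cell; 5000 by default, the value used for the array simulations)
evolve under the chemical master equation with propensities
a_XY = k_XY(A(φ_S)) · n_X.  The Gillespie direct method is implemented in
numba kernels; seeds are mandatory arguments and a fixed seed is
bit-reproducible.  Trajectories are recorded on a uniform grid by zero-order
hold (default 0.5 h, the imaging cadence the statistics assume).  Exactness
is tested via the exponential law of inter-event waiting times
(Kolmogorov–Smirnov on 10⁴ first-event times).

The van Kampen expansion around a stable fixed point gives Jacobian J and
diffusion matrix B = Σ_r ν_r ν_rᵀ a_r(φ*) (concentration propensity
densities, µM/hr).  With Ω = N_tot/C_tot molecules per µM:

* stationary covariance: J C + C Jᵀ + B/Ω = 0 (Lyapunov solve);
* one-sided spectral density of species i, against frequency f in hr⁻¹:
  S_i(f) = 2 [(−iωI − J)⁻¹ (B/Ω) (iωI − Jᵀ)⁻¹]_ii at ω = 2πf, so that
  ∫₀^∞ S_i df = Var(φ_i).  Periodograms (scipy, density scaling, mean or
  linear detrend) share this normalization, making SSA and LNA spectra
  directly comparable.

Spectra are refused when max Re λ > −1e−6 hr⁻¹ (LNA invalid in and at the
edge of the limit-cycle regime).  Near the Hopf point the LNA overestimates
the fluctuation variance — at the default point by a factor of a few, at
γ = 5 by ~10% — because large quasi-cycles saturate nonlinearly; the
covariance test therefore validates the machinery at a well-damped point
(γ = 2.5), while the spectral-shape agreement (peak position, log-spectrum
correlation) holds at the fitted point itself.

The Fig-style quasi-cycle contrast (deterministic amplitude below 1% of its
initial value within ten quasi-periods while the SSA spectrum keeps a
circadian peak) is demonstrated at γ = 5, [KaiA] = 1.3 µM, a stable focus
with 24.7 h quasi-period; at the default point |Re λ| ≈ 0.003 hr⁻¹ is so
small that deterministic decay takes tens of quasi-periods.

## Coupled filaments

Cell i's rates are evaluated at A(s̃_i) with

    s̃_i = (1 − ε) φ_S,i + ε Σ_{j≠i} w(|i−j|) φ_S,j

Kernels: exponential w(d) = e^{−d/ℓ} (default, cutoff 5ℓ), constant, and
power-law d^{−α}; weights are normalized to sum to one over neighbours
excluding self, so ε alone carries the coupling strength and ℓ alone the
spatial scale (identifiability of the two-parameter coherence fit).  ε = 0
reduces exactly to independent single-cell clocks.

On a ring the linearized 3n-dimensional system block-diagonalizes over
spatial Fourier modes q_m = 2πm/n: writing the single-cell Jacobian as
J = J0 + G, where G carries the feedback through A(·), the mode Jacobian is
J_m = J0 + c_m G with c_m = (1 − ε) + ε ŵ(q_m), while the noise matrix B is
mode-independent (reactions are cell-local).  Cross-spectra follow by
inverse transform, S_d(ω) = (1/n) Σ_m e^{i q_m d} P_m(ω), and the complex
coherence is S_d/S_0 (unity at d = 0 by construction, conjugate-symmetric,
magnitude ≤ 1).  The array SSA supports open filaments with truncated,
renormalized kernels; analytic predictions assume the ring.

The per-cell total KaiC is conserved separately in each cell: coupling acts
on the sensed input, not by transferring clock molecules.

## Trace statistics

All variances use the population convention (divisor N).  Conventions worth
noting:

* `sync_index`: R = Var_t(μ(t)) / mean_i Var_t(f_i), the variance-ratio
  order parameter (1 for identical traces, ~1/N for independent ones); the
  square-root variant is available via `sqrt=True`.  Cell-selection helpers
  implement contiguous groups (default 9 cells), cells spaced 10 apart, and
  one-cell-per-filament averaging.
* `spatial_autocorr`: c_k = (1/N) Σ_{i≤N−k} (f_i − f̄)(f_{i+k} − f̄),
  g_k = c_k/c_0 — divisor N and the overall mean at every lag, so g_0 = 1
  exactly.  This estimator is biased low by the mean subtraction
  (≈ −(1+2Σg)/N); on 50-cell filaments the bias on a 3-cell decay length is
  substantial, which is why the recovery test uses 200-cell filaments.
* `binomial_partition_null`: before each of the three division rounds the
  cell order is reshuffled, then each cell of (integerized) value n becomes
  two adjacent daughters Binomial(n, ½) and its complement, doubled to
  conserve the mean.  The per-round reshuffle disperses sibling blocks, so
  inheritance alone leaves only immediate-sister correlation and the null
  autocorrelation vanishes from the second neighbour on.
* `coherence_estimate`: within non-overlapping segments (default 35 cells)
  the cross-periodogram at the chosen frequency bin is averaged over all
  pairs at each distance and normalized by the averaged auto-periodogram.
  In strongly coupled filaments the reshuffle control does not fall to zero
  but to the mean inter-cell coherence level, flat in distance — the
  signature that distance-dependence, not correlation per se, was destroyed.
* Minima for division phases: 5-h moving-average smoothing, 12-h minimum
  separation; divisions outside complete cycles are excluded and counted.

## Oscillation detection by persistent homology

Series are mean-normalized, linearly interpolated to a 10× finer grid (4-h
expression sampling leaves quarter-period delays off-grid), and the
embedding delay τ is the first minimum of the histogram-estimated
auto-mutual information (equal-width bins, ⌈√n⌉ by default).  Two estimator
quirks are handled explicitly: the MI curve is jittery along its broad basin,
so the pipeline smooths it with a 3-h moving average and requires a minimum
to win over a ±1 h window; and the point cloud is denoised with a 2-h
moving average *after* delay selection (coverage-normalized at the edges).
The cloud (x(t), x(t+τ)), z-scored per axis, is subsampled to 60 points by a
deterministic farthest-point rule, and its Vietoris–Rips H1 persistence is
computed by a built-in Z/2 boundary-matrix reduction (columns as integer
bitmasks; union-find pairs the cycle-creating edges, triangle reduction pairs
their deaths).  A brute-force Betti-1 oracle validates the reduction on tiny
clouds.  The verdict score is max H1 persistence / cloud diameter ∈ [0, 1];
the 0.3 default threshold was calibrated on the seeded white-noise null
(false-positive rate ≤ 5/100) before being applied to signals.  The implied
period is 4τ with the delay-grid resolution as uncertainty.

## Model fitting

Stage 1 (`ClockSpectrumModel`): least squares between the analytic LNA
spectrum and an empirical averaged spectrum on the linear scale over
f ∈ [1/60, 1/10] hr⁻¹, with the overall amplitude profiled out analytically
(s* = ⟨m,e⟩/⟨m,m⟩).  Candidate (γ, [KaiA]) points outside the stable-focus
domain are inadmissible.  Because the good-fit basin hugs the Hopf boundary
and is narrow, the optimizer is a dense 40×40 grid prescan over the box
(γ ∈ [1, 50], [KaiA] ∈ [0.1, 10] µM) followed by Nelder–Mead from the best
distinct grid points; boundary-pinned results are flagged, not hidden.
Fixed-point solves are warm-started along the search path.

The bootstrap redraws every kinetic constant from a Gaussian centred on its
nominal value with SD = 10% of nominal (sign-flipping draws are redrawn, a
truncation that preserves positivity without a point mass at zero), refits
each replicate with a coarser 15×15 rescan (a purely local restart can
strand a replicate on the flat plateau when its basin shifts), and reports
means and SDs over converged replicates; every retained replicate is, by
the admissibility guard, inside the quasi-cycle domain of its own perturbed
kinetics.  Replicate seeds derive from the master seed by counter.

Stage 2 (`CoherenceModel`): with (γ, [KaiA]) fixed, least squares on the
coherence magnitude versus distance at the quasi-cycle peak frequency; the
linearization is cached (it does not depend on ε, ℓ) and each evaluation
costs one frequency point per spatial mode.  A coherence curve that decays
by less than 0.05 across d ≥ 1 (e.g. reshuffled data) flags the kernel range
as unidentifiable.

## Synthetic data generator

`synth_filament` chains: coupled-array SSA (ground truth) → reporter relay
dG/dt = α n_T − β G (α = 1 hr⁻¹, β = 0.2 hr⁻¹, a ~5 h transduction delay;
integrated exactly under zero-order hold) → divisions → a clock-independent
initial decay envelope 1 + exp(−t/8 h) (the illumination-shift transient of
the first day of a movie) → multiplicative log-normal noise (CV 10%, mean
1).  Defaults are the measurement conditions the statistics assume: 50
cells, 6 days at 0.5 h sampling, N_tot = 5000, exponential kernel with
ℓ = 2 cells and ε = 0.3.

Divisions are a per-cell renewal process (mean 24 h, SD 3 h), optionally
gated to a ±π/2 phase window around the circadian minima (proposals outside
the window are deferred to the next window entry).  A division keeps the
filament length fixed: the cell's slot is taken over by one daughter whose
reporter count is a Binomial(G, ½) draw while the clock state is inherited
unchanged; the lineage table records (cell, parent, division time).  This
deliberately avoids physical elongation — inserting daughters would change
the coupling topology mid-run — at the cost of one realism feature: in real
filaments both daughters remain adjacent, so division noise is itself
spatially correlated at lag 1, whereas here it is independent across slots
and therefore *whitens* snapshot autocorrelation.  Tests that probe the
spatial signature of clock coupling consequently use division-free
configurations or the clock ground truth; passing them shows the estimators
detect input coupling, not that division noise is modelled in full.

`synth_qpcr` produces mean-normalized noisy sinusoid replicates at 4-h
sampling; `synth_snapshot` produces AR(1) filament snapshots with exact
exponential autocorrelation exp(−k/ℓ).

## Problem sizes and numerical defaults

The test suite and the acceptance script run exact simulations at the full
system size (N_tot = 5000) but with durations and replicate counts chosen
for a single CPU: 40–60 periodograms of 500–1000 h runs for spectral
equivalence and recovery, three 35-cell × 850 h arrays for coherence, a
40×40 Hopf grid with ODE-measured limit-cycle periods, 100 bootstrap
replicates, and 100 white-noise seeds for the detector null.  ODE work uses
LSODA with rtol 1e−9 (1e−8 for the long verification integrations);
spectral fits use the [1/60, 1/10] hr⁻¹ band throughout.

## Known limitations

* KaiA and KaiB are not explicit state variables; they act only through the
  activity function, and no transcription–translation feedback is modelled.
* The smoothed activity function is this package's construction constrained
  by the sharp-limit rule, the "inverted sigmoidal" shape and the fitted
  magnitude of γ; other smoothings meeting the same constraints would shift
  the quantitative position of the Hopf boundary.
* LNA spectra are biased upward near the Hopf boundary (nonlinear
  saturation); fitted parameters inherit a corresponding small bias when the
  data-generating point is very weakly damped.
* The coherence of strongly coupled arrays decays slowly, so ε and ℓ are
  correlated in the fit; recovery of ℓ is reliable to about one cell at the
  tested sizes, ε less so.
* Kinetics are homogeneous along the filament; no branched or 2-D
  topologies; no photobleaching or heterocyst differentiation in the
  generator.
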