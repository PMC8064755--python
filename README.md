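# filaclock

Stochastic models and analysis tools for coupled circadian clocks in
cyanobacterial filaments.

Cyanobacterial circadian clocks are driven by the KaiABC post-translational
oscillator: KaiC cycles through four phosphoforms (U → T → D → S → U), KaiA
accelerates the phosphorylation branch, and S-KaiC shuts KaiA down (via KaiB),
closing a delayed negative feedback.  In multicellular filaments such as
*Anabaena*, every cell carries such a clock at low molecular copy number, and
neighbouring cells communicate through septal junctions.  Two questions drive
this package:

1. **Can demographic noise sustain circadian rhythms where the deterministic
   clock cannot?**  Outside the Hopf region of the deterministic model, finite
   copy number turns damped oscillations into sustained *quasi-cycles* with a
   finite-width circadian spectral peak.
2. **What does cell–cell coupling do to noisy clocks along a filament?**
   Kernel coupling of the clock input synchronizes quasi-cycles and produces a
   complex coherence that decays with cell distance — a measurable signature
   of communication.

`filaclock` implements, with exact stochastic simulation and analytic
linear-noise theory side by side:

* the three-phosphoform KaiC model
  dφ_X/dt = Σ_Y k_YX(A) φ_Y − Σ_Y k_XY(A) φ_X, with rate laws
  k_XY(A) = max(0, k⁰_XY + k^A_XY · A/(K½ + A)) (in vitro constants of
  Rust et al., *Science* 2007) and a smoothed KaiA-sequestration function
  A(φ_S) = ([KaiA]/γ) · log(1 + exp(γ(1 − 2φ_S/[KaiA]))) → max(0, [KaiA] − 2φ_S) as γ → ∞;
* fixed points, stability, and Hopf scans of the (γ, [KaiA]) plane;
* the chemical master equation: Gillespie simulation (numba) of single clocks
  and 1-D coupled arrays, and van Kampen linear-noise spectra
  S_T(f) = 2[(−iωI − J)⁻¹ (B/Ω) (iωI − Jᵀ)⁻¹]_TT, ω = 2πf;
* ring-LNA cross-spectra and the complex coherence versus cell distance for
  exponential / constant / power-law coupling kernels;
* the filament trace statistics: synchronization index
  R = Var_t(μ)/⟨Var_t(f_i)⟩, spatial autocorrelation g_k = c_k/c_0,
  CV²(t), the binomial-partitioning division null, division-phase histograms,
  averaged power spectra, coherence estimation, reshuffle controls;
* persistent-homology oscillation detection (auto-mutual-information delay,
  2-D embedding, built-in Vietoris–Rips H1, period = 4τ);
* statsmodels-style model fitting: `ClockSpectrumModel(...).fit()` for
  (γ, [KaiA]) with a kinetic-perturbation bootstrap, and `CoherenceModel`
  for the coupling strength ε and kernel range ℓ;
* a synthetic filament-movie generator with reporter relay, initial
  clock-independent decay, divisions with binomial reporter partitioning and
  circadian gating, and measurement noise — so the full analysis pipeline is
  testable end to end without any external data.

## Worked example

```python
import numpy as np
from filaclock import default_params
from filaclock.kai_core import stability_and_period
from filaclock.stochastic import (gillespie_single, periodogram_from_trajectory,
                                  average_spectra)
from filaclock.fitting import ClockSpectrumModel

p = default_params()                # gamma = 7.2, [KaiA] = 1.308 uM
rep = stability_and_period(p)
print(rep.regime, round(rep.max_re_lambda, 4), round(rep.period_hr, 2))

specs = [periodogram_from_trajectory(
             gillespie_single(p, N_tot=5000, t_end=550.0, seed=s), "T",
             discard_initial_hr=50.0) for s in range(40)]
avg = average_spectra(specs)
print(round(avg.peak_period_hr, 2))

res = ClockSpectrumModel.from_spectrum(avg).fit()
print(res.summary())
```

prints

```
stable_focus -0.0033 21.48
22.75
Quasi-cycle spectrum fit
========================
  gamma               6.208
  [KaiA] (uM)         1.295
  scale           1.195e+00
  SSE             3.091e-02
  band (hr^-1)   [0.0167, 0.1000]
  evaluations          1979
  converged      True
```

Reading: at the fitted parameters the deterministic clock is a *stable focus*
(max Re λ = −0.0033 hr⁻¹ — no limit cycle), yet exact simulation of 5000 KaiC
molecules shows a clear spectral peak near 23 h: a demographic-noise
quasi-cycle.  Refitting the simulated spectra recovers the generating
parameters (γ within ~14%, [KaiA] within 1%).  `res.bootstrap(n_reps=200,
sigma_frac=0.10, seed=0)` perturbs every kinetic constant by ~10% and refits,
yielding γ and [KaiA] distributions with roughly 20% spread whose replicates
all remain in the quasi-cycle domain.

A command-line interface mirrors the library:

```bash
filaclock scan --gamma-min 1 --gamma-max 40 --kaia-min 0.5 --kaia-max 2.5 --n 40 --out map.csv
filaclock simulate --cells 10 --ntot 5000 --hours 500 --seed 1 --out traj.csv
filaclock synth filament --seed 7 --out traces.csv
filaclock pipeline --seed 7 --out run/
```

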