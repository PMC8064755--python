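"""Synthetic filament movies and expression time series with known ground truth.

The generator emulates the statistical structure of single-cell fluorescence
measurements on filamentous cyanobacteria so that every analysis in the
package can be exercised without any external data:

* per-cell quasi-cyclic clock dynamics from the coupled-array SSA
  (circadian spectral peak, nearest-neighbour-decaying spatial correlation);
* a reporter relay dG/dt = alpha*n_T - beta*G modelling the transduction
  delay from KaiC phosphorylation state to promoter activity;
* a clock-independent multiplicative decay over the first ~24 h (the
  illumination-shift transient seen at the start of movie acquisitions);
* cell divisions with binomial partitioning of reporter molecules and
  faithful inheritance of the clock state, optionally gated to a phase
  window around the circadian minima;
* multiplicative log-normal measurement noise.

Ground truth (the clock ArrayTrajectory and all division events) is always
returned alongside the observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filament import ArrayTrajectory, CouplingKernel, gillespie_array
from .params import ModelParams, default_params
from .stats import FilamentTraces, detect_minima

__all__ = ["SynthConfig", "synth_filament", "synth_qpcr", "synth_snapshot"]


@dataclass
class SynthConfig:
    """Study-condition defaults for the synthetic filament generator.

    Defaults follow the measurement protocol the statistics assume: 50
    contiguous cells followed for 6 days at 30-min sampling, system size
    5000 KaiC molecules per cell, exponential input coupling over ~2 cells,
    a ~5 h reporter relay (alpha/beta), a clock-independent initial decay
    with ~8 h time constant (gone within the first day), 10% multiplicative
    measurement noise, and divisions roughly once per day gated to the
    circadian minima.
    """

    params: ModelParams = field(default_factory=default_params)
    kernel: CouplingKernel = field(default_factory=lambda: CouplingKernel(
        kind="exponential", range_cells=2.0, strength=0.3))
    n_cells: int = 50
    duration_hr: float = 144.0
    dt_hr: float = 0.5
    n_tot: int = 5000
    boundary: str = "ring"
    reporter_gain: float = 1.0          # alpha, hr^-1
    reporter_decay: float = 0.2         # beta, hr^-1
    noise_cv: float = 0.10
    initial_decay_amplitude: float = 1.0
    initial_decay_tau_hr: float = 8.0
    mean_division_hr: float = 24.0
    division_sd_hr: float = 3.0
    gating: bool = True
    gating_halfwidth_rad: float = np.pi / 2
    divisions: bool = True

    def validate(self) -> None:
        if self.dt_hr <= 0 or self.duration_hr <= 0:
            raise ValueError("dt_hr and duration_hr must be positive")
        if min(self.reporter_gain, self.reporter_decay) < 0:
            raise ValueError("reporter rates must be non-negative")
        if self.noise_cv < 0 or self.initial_decay_amplitude < 0:
            raise ValueError("noise and decay amplitudes must be non-negative")
        if self.divisions and self.mean_division_hr <= 0:
            raise ValueError("mean_division_hr must be positive")


def _reporter_relay(n_T: np.ndarray, dt: float, alpha: float, beta: float) -> np.ndarray:
    """Integrate dG/dt = alpha*n_T - beta*G exactly under zero-order hold."""
    G = np.empty_like(n_T, dtype=float)
    G[:, 0] = alpha * n_T[:, 0] / max(beta, 1e-12)
    if beta > 0:
        decay = np.exp(-beta * dt)
        gain = (1.0 - decay) / beta * alpha
    else:
        decay, gain = 1.0, alpha * dt
    for k in range(1, n_T.shape[1]):
        G[:, k] = G[:, k - 1] * decay + gain * n_T[:, k - 1]
    return G


def _division_times(rng: np.random.Generator, cfg: SynthConfig,
                    phase_of_time) -> list[list[float]]:
    """Per-cell division times from a renewal process, optionally gated.

    With gating on, a proposed division outside the allowed phase window
    (centred on the circadian minima, phase 0/2*pi) is deferred until the
    window is next entered.
    """
    out = []
    t_end = cfg.duration_hr
    for _ in range(cfg.n_cells):
        times = []
        t = rng.uniform(0, cfg.mean_division_hr)
        while True:
            t += max(cfg.dt_hr, rng.normal(cfg.mean_division_hr, cfg.division_sd_hr))
            if t >= t_end:
                break
            if cfg.gating:
                # defer to the next time the phase enters the window
                tt = t
                while tt < t_end:
                    ph = phase_of_time(tt)
                    if ph <= cfg.gating_halfwidth_rad or \
                       ph >= 2 * np.pi - cfg.gating_halfwidth_rad:
                        break
                    tt += cfg.dt_hr
                if tt >= t_end:
                    break
                t = tt
            times.append(t)
        out.append(times)
    return out


def synth_filament(config: SynthConfig | None = None, seed: int = 0,
                   ) -> tuple[FilamentTraces, ArrayTrajectory]:
    """Generate one synthetic filament movie plus its clock ground truth.

    Pipeline: coupled-array SSA -> reporter relay -> divisions (binomial
    reporter partitioning, clock state inherited) -> initial-decay envelope
    -> multiplicative log-normal noise.  The lineage (cell, parent, division
    time) is recorded; a division replaces the cell in its position by one
    of its daughters, keeping the filament length fixed.
    """
    cfg = config if config is not None else SynthConfig()
    cfg.validate()
    rng = np.random.default_rng((int(seed), 0xFACADE))

    truth = gillespie_array(cfg.params, cfg.n_cells, cfg.kernel, cfg.n_tot,
                            cfg.duration_hr, seed=int(seed) * 2 + 1,
                            boundary=cfg.boundary, record_dt=cfg.dt_hr)
    t = truth.time_hr
    n_T = truth.counts[:, :, 0].astype(float)
    G = _reporter_relay(n_T, cfg.dt_hr, cfg.reporter_gain, cfg.reporter_decay)

    lineage_rows = []
    if cfg.divisions:
        # circadian phase reference from the mean clock output
        mu = n_T.mean(axis=0)
        minima = detect_minima(mu, t)
        if minima.size >= 2:
            def phase_of_time(tt: float) -> float:
                k = np.searchsorted(minima, tt, side="right") - 1
                if k < 0:
                    return np.pi  # before first minimum: treat as mid-cycle
                if k >= minima.size - 1:
                    per = minima[-1] - minima[-2]
                    return 2 * np.pi * ((tt - minima[-1]) / per % 1.0)
                return 2 * np.pi * (tt - minima[k]) / (minima[k + 1] - minima[k])
        else:
            def phase_of_time(tt: float) -> float:
                return 0.0
        div_times = _division_times(rng, cfg, phase_of_time)
        next_id = cfg.n_cells
        current_id = list(range(cfg.n_cells))
        events = sorted((tt, i) for i, ts in enumerate(div_times) for tt in ts)
        for tt, i in events:
            k = int(np.searchsorted(t, tt))
            if k >= t.size:
                continue
            g = max(0.0, G[i, k])
            daughter = rng.binomial(int(round(g)), 0.5)
            # the tracked slot keeps one daughter; reporter continues to relax
            # from the partitioned level while the clock state is inherited
            drop = daughter - g
            decay_tail = np.exp(-cfg.reporter_decay * (t[k:] - t[k]))
            G[i, k:] += drop * decay_tail
            lineage_rows.append(dict(cell_id=next_id, parent_id=current_id[i],
                                     position=i, division_time_hr=float(t[k])))
            current_id[i] = next_id
            next_id += 1

    envelope = 1.0 + cfg.initial_decay_amplitude * np.exp(-t / cfg.initial_decay_tau_hr)
    obs = np.maximum(G, 0.0) * envelope[None, :]
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
        obs = obs * rng.lognormal(-0.5 * sigma ** 2, sigma, size=obs.shape)

    lineage = pd.DataFrame(lineage_rows,
                           columns=["cell_id", "parent_id", "position",
                                    "division_time_hr"])
    traces = FilamentTraces(values=obs, time_hr=t,
                            positions=np.arange(cfg.n_cells),
                            cell_ids=np.arange(cfg.n_cells),
                            filament_id=f"synth-{seed}", lineage=lineage)
    return traces, truth


def synth_qpcr(period_hr: float = 26.0, rel_amplitude: float = 0.3,
               noise_cv: float = 0.10, *, sampling_hr: float = 4.0,
               duration_hr: float = 72.0, n_replicates: int = 3,
               genes: dict[str, float] | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Mean-normalized noisy sinusoid replicates emulating short RT-qPCR series.

    ``genes`` maps gene name -> phase offset (radians); default is a single
    gene at phase 0.  Columns are ``{gene}_rep{r}``; each series is divided
    by its temporal mean, matching the normalization convention for relative
    expression curves.
    """
    if duration_hr < 2 * period_hr:
        raise ValueError("duration must cover at least two periods")
    rng = np.random.default_rng((int(seed), 0x9C9))
    t = np.arange(0.0, duration_hr + 0.5 * sampling_hr, sampling_hr)
    if genes is None:
        genes = {"gene": 0.0}
    data = {"time_hr": t}
    for name, phase in genes.items():
        for r in range(n_replicates):
            x = 1.0 + rel_amplitude * np.sin(2 * np.pi * t / period_hr + phase)
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv ** 2))
                x = x * rng.lognormal(-0.5 * sigma ** 2, sigma, size=t.size)
            x = np.maximum(x, 1e-9)
            data[f"{name}_rep{r}"] = x / x.mean()
    return pd.DataFrame(data)


def synth_snapshot(n_cells: int, correlation_length: float, seed: int = 0, *,
                   mean: float = 100.0, sd: float = 20.0) -> np.ndarray:
    """Stationary per-cell snapshot with exponential spatial autocorrelation.

    First-order autoregressive construction with coefficient
    rho = exp(-1/ell), so the autocorrelation at lag k is exp(-k/ell);
    ell -> 0 gives i.i.d. values.  Values are shifted/scaled to the given
    mean and SD and clipped at zero (fluorescence-like).
    """
    if n_cells < 10:
        raise ValueError("n_cells must be at least 10")
    rng = np.random.default_rng((int(seed), 0x5A9))
    rho = np.exp(-1.0 / correlation_length) if correlation_length > 0 else 0.0
    x = np.empty(n_cells)
    x[0] = rng.normal()
    innov = np.sqrt(1.0 - rho ** 2)
    for i in range(1, n_cells):
        x[i] = rho * x[i - 1] + innov * rng.normal()
    return np.maximum(0.0, mean + sd * x)
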