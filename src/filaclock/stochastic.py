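"""Single-clock demographic noise: exact SSA and linear-noise-approximation spectra.

The chemical master equation over the eight phosphoform transitions is
simulated exactly (Gillespie direct method, numba-compiled).  Around a stable
fixed point the van Kampen system-size expansion gives Gaussian fluctuations
with Jacobian J and diffusion matrix B; the resulting one-sided power
spectral density of the concentration fluctuation of species i is

    S_i(f) = 2 * [ (-i w I - J)^-1 (B / Omega) (i w I - J^T)^-1 ]_ii,   w = 2 pi f

with Omega = N_tot / C_tot molecules per uM, f in hr^-1, S in uM^2 hr.  At a
stable focus this spectrum has a finite-width peak near |Im lambda| / 2 pi —
the demographic-noise quasi-cycle — even though the deterministic orbit decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.linalg import solve_continuous_lyapunov

from . import _kernels
from .kai_core import (FixedPointError, active_kaiA, find_fixed_point,
                       jacobian, transition_rates)
from .params import SOURCE_SPECIES, STOICHIOMETRY, ModelParams

__all__ = [
    "ClockState", "Trajectory", "SpectrumResult", "LNAValidityError",
    "propensities", "gillespie_single", "gillespie_waiting_times",
    "lna_matrices", "stationary_covariance", "analytic_power_spectrum",
    "periodogram_from_trajectory", "average_spectra",
]

_SPECIES_INDEX = {"T": 0, "D": 1, "S": 2}
_FORM_ID = {"softplus": 0, "logistic": 1, "sharp": 2}


class LNAValidityError(RuntimeError):
    """LNA spectrum requested outside the stable-focus (quasi-cycle) domain."""


@dataclass(frozen=True)
class ClockState:
    """Integer phosphoform copy numbers of one cell."""

    n_T: int
    n_D: int
    n_S: int
    N_tot: int

    def __post_init__(self):
        if min(self.n_T, self.n_D, self.n_S) < 0 or self.n_U < 0:
            raise ValueError("copy numbers must be non-negative and sum <= N_tot")

    @property
    def n_U(self) -> int:
        return self.N_tot - self.n_T - self.n_D - self.n_S

    def concentrations(self, C_tot: float) -> np.ndarray:
        """(phi_T, phi_D, phi_S) in uM."""
        return np.array([self.n_T, self.n_D, self.n_S]) * C_tot / self.N_tot


@dataclass
class Trajectory:
    """SSA sample path recorded on a uniform time grid (zero-order hold)."""

    time_hr: np.ndarray
    counts: np.ndarray          # (nt, 3) int, columns (n_T, n_D, n_S)
    N_tot: int
    params: ModelParams
    seed: int
    n_events: int = 0
    absorbed: bool = False

    def species_counts(self, species: str = "T") -> np.ndarray:
        return self.counts[:, _SPECIES_INDEX[species]]

    def species_concentration(self, species: str = "T") -> np.ndarray:
        return self.species_counts(species) * self.params.C_tot / self.N_tot


@dataclass
class SpectrumResult:
    """One-sided power spectral density on a positive frequency grid."""

    freq_per_hr: np.ndarray
    psd: np.ndarray
    provenance: str             # 'analytic' | 'periodogram'
    n_averaged: int = 1
    species: str = "T"
    units: str = "uM^2 hr"

    def __post_init__(self):
        if np.any(np.diff(self.freq_per_hr) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("spectral density must be non-negative")

    @property
    def peak_freq_per_hr(self) -> float:
        return float(self.freq_per_hr[np.argmax(self.psd)])

    @property
    def peak_period_hr(self) -> float:
        return 1.0 / self.peak_freq_per_hr


def propensities(state: ClockState, params: ModelParams) -> np.ndarray:
    """Eight reaction propensities (hr^-1): a_XY = k_XY(A) * n_X."""
    phi = state.concentrations(params.C_tot)
    A = active_kaiA(phi[2], params, check=False)
    k = transition_rates(A, params.kinetics)
    ns = np.array([state.n_U, state.n_T, state.n_D, state.n_S], dtype=float)
    return k * ns[SOURCE_SPECIES]


def _initial_counts(params: ModelParams, N_tot: int,
                    initial_state: ClockState | None) -> np.ndarray:
    if initial_state is not None:
        return np.array([initial_state.n_T, initial_state.n_D,
                         initial_state.n_S], dtype=np.int64)
    try:
        fp = find_fixed_point(params)
        frac = fp.as_array() / params.C_tot
    except FixedPointError:
        frac = np.array([0.25, 0.25, 0.25])
    counts = np.floor(frac * N_tot).astype(np.int64)
    return counts


def _kernel_args(params: ModelParams):
    kin = params.kinetics
    return (np.ascontiguousarray(kin.k0), np.ascontiguousarray(kin.kA),
            kin.K_half, kin.C_tot, params.gamma, params.kaiA_total,
            _FORM_ID[params.activity_form])


def gillespie_single(params: ModelParams, N_tot: int, t_end: float, seed: int,
                     *, record_dt: float = 0.5, max_steps: int | None = None,
                     initial_state: ClockState | None = None) -> Trajectory:
    """Statistically exact sample of the single-clock master equation.

    Records (n_T, n_D, n_S) every ``record_dt`` hours by zero-order hold.
    A fixed seed is bit-reproducible.  If the system reaches a state of zero
    total propensity the run terminates cleanly with ``absorbed=True``.
    """
    if N_tot < 1:
        raise ValueError("N_tot must be >= 1")
    if seed is None:
        raise ValueError("seed is a mandatory argument")
    counts0 = _initial_counts(params, N_tot, initial_state)
    grid = np.arange(0.0, t_end + 0.5 * record_dt, record_dt)
    if max_steps is None:
        max_steps = int(5e8)
    rec, n_events, absorbed, _t = _kernels.ssa_single(
        *_kernel_args(params), counts0, N_tot, grid, max_steps, int(seed))
    return Trajectory(time_hr=grid, counts=rec, N_tot=N_tot, params=params,
                      seed=int(seed), n_events=int(n_events), absorbed=bool(absorbed))


def gillespie_waiting_times(params: ModelParams, N_tot: int, n_events: int,
                            seed: int,
                            initial_state: ClockState | None = None):
    """Event-resolved run: (event times, per-event counts).  Used to test
    exactness of the waiting-time law."""
    counts0 = _initial_counts(params, N_tot, initial_state)
    times, states = _kernels.ssa_single_events(
        *_kernel_args(params), counts0, N_tot, int(n_events), int(seed))
    return times, states


# ---------------------------------------------------------------------------
# linear noise approximation

def lna_matrices(params: ModelParams,
                 fp_guess: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(J, B): Jacobian at the fixed point and the diffusion matrix.

    B = sum_r nu_r nu_r^T a_r(phi*) over the eight reactions, with propensity
    densities a_r = k_r(A*) phi_X* in uM/hr; B is symmetric PSD.  Division by
    Omega = N_tot/C_tot yields the concentration-fluctuation noise intensity.
    """
    fp = find_fixed_point(params, initial_guess=fp_guess)
    y = fp.as_array()
    J = jacobian(y, params)
    A = active_kaiA(y[2], params, check=False)
    k = transition_rates(A, params.kinetics)
    phis = np.array([fp.phi_U, fp.phi_T, fp.phi_D, fp.phi_S])
    a = k * phis[SOURCE_SPECIES]
    nu = STOICHIOMETRY.astype(float)
    B = (nu.T * a) @ nu
    return J, B


def stationary_covariance(params: ModelParams, N_tot: int) -> np.ndarray:
    """Stationary concentration covariance C solving J C + C J^T + B/Omega = 0."""
    J, B = lna_matrices(params)
    omega = N_tot / params.C_tot
    return solve_continuous_lyapunov(J, -B / omega)


def analytic_power_spectrum(params: ModelParams, N_tot: int,
                            species: str = "T",
                            freq_per_hr: np.ndarray | None = None,
                            *, stability_tol: float = -1e-6,
                            fp_guess: np.ndarray | None = None) -> SpectrumResult:
    """LNA power spectrum of concentration fluctuations at a stable focus.

    Refuses to evaluate when max Re(lambda) > ``stability_tol`` (the expansion
    around the fixed point is invalid in the limit-cycle regime).
    """
    J, B = lna_matrices(params, fp_guess=fp_guess)
    ev = np.linalg.eigvals(J)
    if ev.real.max() > stability_tol:
        raise LNAValidityError(
            f"fixed point not stable enough for LNA (max Re lambda = {ev.real.max():.3g})")
    if freq_per_hr is None:
        freq_per_hr = np.linspace(1e-4, 0.25, 600)
    omega_sys = N_tot / params.C_tot
    Bn = B / omega_sys
    i = _SPECIES_INDEX[species]
    eye = np.eye(3)
    psd = np.empty_like(freq_per_hr, dtype=float)
    for m, f in enumerate(np.asarray(freq_per_hr, dtype=float)):
        w = 2.0 * np.pi * f
        P = np.linalg.solve(-1j * w * eye - J, Bn) @ np.linalg.inv(1j * w * eye - J.T)
        psd[m] = 2.0 * P[i, i].real
    psd = np.maximum(psd, 0.0)
    return SpectrumResult(freq_per_hr=np.asarray(freq_per_hr, dtype=float),
                          psd=psd, provenance="analytic", species=species)


# ---------------------------------------------------------------------------
# periodograms

def periodogram_from_trajectory(traj: Trajectory, species: str = "T",
                                *, detrend: str = "mean",
                                discard_initial_hr: float = 0.0,
                                min_duration_hr: float = 96.0) -> SpectrumResult:
    """Standard periodogram of a concentration series on the uniform grid.

    ``detrend='mean'`` removes the mean (default); ``'linear'`` also removes a
    linear trend.  Raises on trajectories shorter than ``min_duration_hr``
    (about four circadian periods).
    """
    x = traj.species_concentration(species)
    t = traj.time_hr
    keep = t >= discard_initial_hr
    x, t = x[keep], t[keep]
    if t[-1] - t[0] < min_duration_hr:
        raise ValueError(
            f"trajectory spans {t[-1]-t[0]:.1f} hr < required {min_duration_hr} hr")
    dt = float(t[1] - t[0])
    det = "constant" if detrend == "mean" else "linear"
    f, p = signal.periodogram(x, fs=1.0 / dt, detrend=det, window="boxcar")
    keep = f > 0
    return SpectrumResult(freq_per_hr=f[keep], psd=p[keep],
                          provenance="periodogram", species=species)


def average_spectra(spectra: list[SpectrumResult]) -> SpectrumResult:
    """Average periodograms computed on identical frequency grids."""
    f0 = spectra[0].freq_per_hr
    for s in spectra[1:]:
        if not np.allclose(s.freq_per_hr, f0):
            raise ValueError("spectra must share a common frequency grid")
    psd = np.mean([s.psd for s in spectra], axis=0)
    n = sum(s.n_averaged for s in spectra)
    return SpectrumResult(freq_per_hr=f0, psd=psd,
                          provenance=spectra[0].provenance,
                          n_averaged=n, species=spectra[0].species)
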