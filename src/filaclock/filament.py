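"""One-dimensional arrays of coupled noisy clocks.

Cells along a filament exchange small molecules through septal junctions; the
model represents this as kernel coupling of the clock *input*: the S-KaiC
concentration sensed by cell i's KaiA-sequestration function is

    s_tilde_i = (1 - eps) * phi_S_i + eps * sum_{j != i} w(|i-j|) * phi_S_j

with kernel weights w normalized to sum to one over neighbours within a
cutoff.  eps in [0,1] carries all the coupling strength, the kernel range
shapes the spatial decay.  On a ring the linearized 3n-dimensional system
block-diagonalizes over spatial Fourier modes, giving analytic per-mode
spectra, cell-pair cross-spectra and the complex coherence versus distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .kai_core import find_fixed_point, jacobian_parts
from .params import ModelParams
from .stochastic import (LNAValidityError, Trajectory, _initial_counts,
                         _kernel_args, lna_matrices)

__all__ = [
    "CouplingKernel", "ArrayTrajectory", "CoherenceResult",
    "coupled_propensities", "gillespie_array", "coupled_lna_spectra",
    "coherence_from_cross_spectra",
]

_SPECIES_INDEX = {"T": 0, "D": 1, "S": 2}


@dataclass(frozen=True)
class CouplingKernel:
    """Spatial interaction kernel between clocks.

    kind: 'exponential' w(d) = exp(-d/ell), 'constant' w(d) = 1, or
    'power_law' w(d) = d**(-ell) (range_cells doubles as the exponent).
    strength eps is the fraction of the sensed S signal drawn from neighbours;
    cutoff defaults to ceil(5*ell) cells (or 10 for non-exponential kinds).
    """

    kind: str = "exponential"
    range_cells: float = 2.0
    strength: float = 0.3
    cutoff: int | None = None

    def __post_init__(self):
        if self.kind not in ("exponential", "constant", "power_law"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        if self.range_cells <= 0:
            raise ValueError("range_cells must be positive")

    @property
    def cutoff_cells(self) -> int:
        if self.cutoff is not None:
            return int(self.cutoff)
        if self.kind == "exponential":
            return max(1, int(np.ceil(5.0 * self.range_cells)))
        return 10

    def raw_weight(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.kind == "exponential":
            w = np.exp(-d / self.range_cells)
        elif self.kind == "constant":
            w = np.ones_like(d)
        else:
            w = np.where(d > 0, d ** (-self.range_cells), 0.0)
        return np.where((d >= 1) & (d <= self.cutoff_cells), w, 0.0)

    def weight_matrix(self, n_cells: int, boundary: str = "ring") -> np.ndarray:
        """Row-normalized weights W (zero diagonal).  On a ring the distance
        is the circle distance; on an open filament truncated rows are
        renormalized."""
        i = np.arange(n_cells)
        if boundary == "ring":
            d = np.abs(i[:, None] - i[None, :])
            d = np.minimum(d, n_cells - d)
        elif boundary == "open":
            d = np.abs(i[:, None] - i[None, :])
        else:
            raise ValueError("boundary must be 'ring' or 'open'")
        W = self.raw_weight(d)
        np.fill_diagonal(W, 0.0)
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return W / rs

    def fourier_factors(self, n_cells: int) -> np.ndarray:
        """Eigenvalues w_hat(q_m) of the ring weight matrix, m = 0..n-1.

        For a symmetric circulant these are real; combined with the strength,
        the per-mode coupling factor is c_m = (1-eps) + eps*w_hat_m.
        """
        W = self.weight_matrix(n_cells, "ring")
        return np.real(np.fft.fft(W[0]))


@dataclass
class ArrayTrajectory:
    """Per-cell SSA sample paths on a shared uniform time grid."""

    time_hr: np.ndarray
    counts: np.ndarray          # (n_cells, nt, 3)
    N_tot: int
    params: ModelParams
    kernel: CouplingKernel
    boundary: str
    seed: int
    n_events: int = 0
    absorbed: bool = False

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def species_concentration(self, species: str = "T") -> np.ndarray:
        """(n_cells, nt) concentration matrix in uM."""
        i = _SPECIES_INDEX[species]
        return self.counts[:, :, i] * self.params.C_tot / self.N_tot

    def cell(self, i: int) -> Trajectory:
        return Trajectory(time_hr=self.time_hr, counts=self.counts[i],
                          N_tot=self.N_tot, params=self.params, seed=self.seed)


@dataclass
class CoherenceResult:
    """Complex coherence vs cell distance at a stated frequency."""

    distances: np.ndarray
    values: np.ndarray          # complex
    freq_per_hr: float
    provenance: str             # 'analytic' | 'estimated'
    n_averaged: int = 1

    def __post_init__(self):
        if not np.isclose(abs(self.values[0]), 1.0, atol=1e-6):
            raise ValueError("coherence at distance 0 must be 1")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def effective_sensed_S(phi_S: np.ndarray, kernel: CouplingKernel,
                       W: np.ndarray | None = None,
                       boundary: str = "ring") -> np.ndarray:
    """s_tilde_i = (1-eps) phi_S_i + eps (W phi_S)_i."""
    phi_S = np.asarray(phi_S, dtype=float)
    if W is None:
        W = kernel.weight_matrix(len(phi_S), boundary)
    eps = kernel.strength
    return (1.0 - eps) * phi_S + eps * (W @ phi_S)


def coupled_propensities(counts: np.ndarray, N_tot: int, params: ModelParams,
                         kernel: CouplingKernel,
                         boundary: str = "ring") -> np.ndarray:
    """(n_cells, 8) propensities with rates evaluated at A(s_tilde_i).

    With eps = 0 this equals the per-cell single-clock propensities exactly.
    """
    from .kai_core import active_kaiA, transition_rates
    from .params import SOURCE_SPECIES
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("counts must have shape (n_cells, 3)")
    C = params.C_tot
    phi_S = counts[:, 2] * C / N_tot
    s_tilde = effective_sensed_S(phi_S, kernel, boundary=boundary)
    out = np.empty((counts.shape[0], 8))
    for i in range(counts.shape[0]):
        A = active_kaiA(float(s_tilde[i]), params, check=False)
        k = transition_rates(A, params.kinetics)
        nU = N_tot - counts[i].sum()
        ns = np.array([nU, counts[i, 0], counts[i, 1], counts[i, 2]], dtype=float)
        out[i] = k * ns[SOURCE_SPECIES]
    return out


def gillespie_array(params: ModelParams, n_cells: int, kernel: CouplingKernel,
                    N_tot: int, t_end: float, seed: int, *,
                    boundary: str = "ring", record_dt: float = 0.5,
                    max_steps: int | None = None,
                    initial_counts: np.ndarray | None = None) -> ArrayTrajectory:
    """Exact SSA over the 8*n_cells coupled reactions."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if initial_counts is None:
        c0 = _initial_counts(params, N_tot, None)
        initial_counts = np.tile(c0, (n_cells, 1))
    initial_counts = np.ascontiguousarray(initial_counts, dtype=np.int64)
    W = np.ascontiguousarray(kernel.weight_matrix(n_cells, boundary))
    grid = np.arange(0.0, t_end + 0.5 * record_dt, record_dt)
    if max_steps is None:
        max_steps = int(1e9)
    rec, n_events, absorbed, _t = _kernels.ssa_array(
        *_kernel_args(params), initial_counts, N_tot, kernel.strength, W,
        grid, max_steps, int(seed))
    return ArrayTrajectory(time_hr=grid, counts=rec, N_tot=N_tot, params=params,
                           kernel=kernel, boundary=boundary, seed=int(seed),
                           n_events=int(n_events), absorbed=bool(absorbed))


# ---------------------------------------------------------------------------
# spatially extended LNA (ring)

def coupled_lna_spectra(params: ModelParams, kernel: CouplingKernel,
                        n_cells: int, N_tot: int,
                        freq_per_hr: np.ndarray | None = None,
                        species: str = "T", *, d_max: int = 10,
                        stability_tol: float = -1e-6):
    """Analytic per-distance cross-spectra and coherence on a ring.

    Linearizes the homogeneous system about the (shared) single-cell fixed
    point and block-diagonalizes over spatial Fourier modes: per mode m,
    J_m = J0 + c_m G with c_m = (1-eps) + eps*w_hat_m, and the per-cell noise
    matrix B is mode-independent.  Cross-spectra follow by inverse transform,
    S_d(f) = (1/n) sum_m e^{i q_m d} P_m(f), and coherence(d) = S_d/S_0.

    Returns (freq, S_d complex array of shape (d_max+1, nf), CoherenceResult
    at the peak frequency of S_0).
    """
    fp = find_fixed_point(params)
    y = fp.as_array()
    J0, G = jacobian_parts(y, params)
    Jsingle = J0 + G
    if np.linalg.eigvals(Jsingle).real.max() > stability_tol:
        raise LNAValidityError("homogeneous fixed point is not stable")
    _, B = lna_matrices(params)
    omega_sys = N_tot / params.C_tot
    Bn = B / omega_sys
    if freq_per_hr is None:
        freq_per_hr = np.linspace(1e-4, 0.25, 400)
    freq_per_hr = np.asarray(freq_per_hr, dtype=float)
    eps = kernel.strength
    what = kernel.fourier_factors(n_cells)
    cm = (1.0 - eps) + eps * what
    i = _SPECIES_INDEX[species]
    eye = np.eye(3)

    # stability of every spatial mode
    for c in cm:
        ev = np.linalg.eigvals(J0 + c * G)
        if ev.real.max() > stability_tol:
            raise LNAValidityError(
                f"spatial mode with coupling factor {c:.3f} is unstable")

    Pm = np.empty((n_cells, freq_per_hr.size), dtype=float)
    for m, c in enumerate(cm):
        Jm = J0 + c * G
        for kf, f in enumerate(freq_per_hr):
            w = 2.0 * np.pi * f
            P = np.linalg.solve(-1j * w * eye - Jm, Bn) @ np.linalg.inv(1j * w * eye - Jm.T)
            Pm[m, kf] = 2.0 * P[i, i].real
    d_max = min(d_max, n_cells // 2)
    q = 2.0 * np.pi * np.arange(n_cells) / n_cells
    S_d = np.empty((d_max + 1, freq_per_hr.size), dtype=complex)
    for d in range(d_max + 1):
        phase = np.exp(1j * q * d)
        S_d[d] = phase @ Pm / n_cells
    kpk = int(np.argmax(S_d[0].real))
    coh = CoherenceResult(distances=np.arange(d_max + 1),
                          values=S_d[:, kpk] / S_d[0, kpk],
                          freq_per_hr=float(freq_per_hr[kpk]),
                          provenance="analytic")
    return freq_per_hr, S_d, coh


def coherence_from_cross_spectra(freq_per_hr: np.ndarray, S_d: np.ndarray,
                                 frequency: float) -> CoherenceResult:
    """Coherence at the stated frequency (nearest grid bin)."""
    k = int(np.argmin(np.abs(freq_per_hr - frequency)))
    return CoherenceResult(distances=np.arange(S_d.shape[0]),
                           values=S_d[:, k] / S_d[0, k],
                           freq_per_hr=float(freq_per_hr[k]),
                           provenance="analytic")
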