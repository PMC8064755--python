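"""Deterministic three-phosphoform KaiC clock: fixed points, stability, Hopf scan.

The state is the concentration vector (phi_T, phi_D, phi_S) in uM, with
phi_U = C_tot - phi_T - phi_D - phi_S by conservation.  S-KaiC inactivates
KaiA (via KaiB); in the sharp source model the active KaiA concentration is
A = max(0, kaiA_total - 2*phi_S).  Here that rule is smoothed so that the
system is differentiable and amenable to linear-noise analysis:

* ``softplus`` (default):  A = (kaiA_total/gamma) * log(1 + exp(gamma*(kaiA_total - 2*phi_S)/kaiA_total))
* ``logistic``:            A = kaiA_total / (1 + exp(gamma*(2*phi_S - kaiA_total)/kaiA_total))
* ``sharp``:               A = max(0, kaiA_total - 2*phi_S)

The softplus form converges pointwise (away from the kink) to the sharp rule
as gamma grows and its slope is an inverted sigmoid in phi_S.  With the
in vitro kinetics it produces a Hopf bifurcation in the (gamma, [KaiA]) plane
with a circadian-period limit-cycle strip hugging the boundary; the logistic
form is retained for comparison but converges to a step function instead and
suppresses the oscillatory region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .params import TRANSITIONS, KineticParams, ModelParams

__all__ = [
    "ClockConcentrations",
    "StabilityReport",
    "active_kaiA",
    "activity_slope",
    "transition_rates",
    "rate",
    "ode_rhs",
    "jacobian",
    "jacobian_parts",
    "find_fixed_point",
    "FixedPointError",
    "stability_and_period",
    "measure_ode_period",
    "hopf_scan",
    "CIRCADIAN_BAND_HR",
]

#: Default circadian period band (hours), configurable in the scan helpers.
CIRCADIAN_BAND_HR = (22.0, 28.0)


class FixedPointError(RuntimeError):
    """Raised when no fixed point satisfies the residual tolerance; carries
    the best residual achieved."""

    def __init__(self, message: str, best_residual: float = np.inf):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class ClockConcentrations:
    """Concentrations (uM) of the three explicit phosphoforms."""

    phi_T: float
    phi_D: float
    phi_S: float
    C_tot: float

    @property
    def phi_U(self) -> float:
        return self.C_tot - self.phi_T - self.phi_D - self.phi_S

    def as_array(self) -> np.ndarray:
        return np.array([self.phi_T, self.phi_D, self.phi_S])

    def validate(self, tol: float = 1e-9) -> None:
        arr = np.array([self.phi_U, self.phi_T, self.phi_D, self.phi_S])
        if np.any(arr < -tol) or np.any(arr > self.C_tot + tol):
            raise ValueError(f"concentrations outside [0, C_tot]: {arr}")


@dataclass(frozen=True)
class StabilityReport:
    fixed_point: ClockConcentrations
    eigenvalues: np.ndarray
    regime: str                # 'limit_cycle' | 'stable_focus' | 'stable_node'
    period_hr: float | None    # ODE period (limit cycle) or 2*pi/|Im| (focus)
    max_re_lambda: float


# ---------------------------------------------------------------------------
# activity function and rate laws

def _check_phi_S(phi_S, C_tot):
    arr = np.asarray(phi_S, dtype=float)
    if np.any(arr < 0) or np.any(arr > C_tot):
        raise ValueError(f"phi_S must lie in [0, C_tot={C_tot}]")


def active_kaiA(phi_S, params: ModelParams, *, check: bool = True):
    """Effective active-KaiA concentration A(phi_S) in uM.

    Continuous, non-increasing in phi_S; A(0) ~ kaiA_total and, for the
    softplus/sharp forms, A -> max(0, kaiA_total - 2*phi_S) as gamma -> inf.
    """
    if check:
        _check_phi_S(phi_S, params.C_tot)
    a = params.kaiA_total
    if a == 0.0:
        return np.zeros_like(np.asarray(phi_S, dtype=float)) if np.ndim(phi_S) else 0.0
    phi_S = np.asarray(phi_S, dtype=float) if np.ndim(phi_S) else float(phi_S)
    g = params.gamma
    if params.activity_form == "sharp":
        return np.maximum(0.0, a - 2.0 * phi_S)
    x = g * (a - 2.0 * phi_S) / a
    if params.activity_form == "softplus":
        return (a / g) * np.logaddexp(0.0, x)
    # logistic
    return a / (1.0 + np.exp(-x))


def activity_slope(phi_S, params: ModelParams):
    """dA/dphi_S, needed by the analytic Jacobian."""
    a = params.kaiA_total
    if a == 0.0:
        return np.zeros_like(np.asarray(phi_S, dtype=float)) if np.ndim(phi_S) else 0.0
    g = params.gamma
    x = g * (a - 2.0 * phi_S) / a
    if params.activity_form == "sharp":
        return np.where(np.asarray(x) > 0, -2.0, 0.0)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    if params.activity_form == "softplus":
        return -2.0 * sig
    # logistic: A = a*sig(x), dA/dS = a*sig'(x)*dx/dS = -2*g*sig*(1-sig)
    return -2.0 * g * sig * (1.0 - sig)


def transition_rates(A, kin: KineticParams) -> np.ndarray:
    """All eight rates k_XY(A) (hr^-1) in :data:`TRANSITIONS` order, clamped at 0."""
    if np.any(np.asarray(A) < 0):
        raise ValueError("A must be non-negative")
    f = A / (kin.K_half + A)
    return np.maximum(0.0, kin.k0 + kin.kA * f)


def _rate_slopes(A, kin: KineticParams) -> np.ndarray:
    """d k_XY / dA, zero where the rate is clamped at 0."""
    f = A / (kin.K_half + A)
    raw = kin.k0 + kin.kA * f
    dk = kin.kA * kin.K_half / (kin.K_half + A) ** 2
    return np.where(raw > 0.0, dk, 0.0)


def rate(transition: str, A: float, params: ModelParams) -> float:
    """Single rate k_XY(A) by label (e.g. ``"UT"``)."""
    try:
        i = TRANSITIONS.index(transition)
    except ValueError:
        raise KeyError(f"unknown transition {transition!r}; expected one of {TRANSITIONS}")
    return float(transition_rates(A, params.kinetics)[i])


# ---------------------------------------------------------------------------
# ODE right-hand side and Jacobian

def ode_rhs(y: np.ndarray, params: ModelParams, A: float | None = None) -> np.ndarray:
    """d(phi_T, phi_D, phi_S)/dt (uM/hr) by mass action over the 8 transitions.

    If ``A`` is given it overrides active_kaiA(phi_S) — used by the coupled
    filament model where the sensed S concentration is a kernel average.
    """
    T, D, S = y
    U = params.C_tot - T - D - S
    if A is None:
        A = active_kaiA(S, params, check=False)
    k = transition_rates(A, params.kinetics)
    kUT, kTU, kTD, kDT, kDS, kSD, kSU, kUS = k
    dT = kUT * U + kDT * D - (kTU + kTD) * T
    dD = kTD * T + kSD * S - (kDT + kDS) * D
    dS = kUS * U + kDS * D - (kSU + kSD) * S
    return np.array([dT, dD, dS])


def jacobian_parts(y: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Split the Jacobian at state y into (J0, G).

    J0 holds A fixed (the linear mass-action part, including the implicit
    U dependence); G = (dF/dA) * A'(phi_S) e_S^T carries the feedback through
    KaiA sequestration.  The full single-clock Jacobian is J0 + G.  The split
    is what the spatially coupled model block-diagonalizes over Fourier modes.
    """
    T, D, S = y
    U = params.C_tot - T - D - S
    A = active_kaiA(S, params, check=False)
    k = transition_rates(A, params.kinetics)
    kUT, kTU, kTD, kDT, kDS, kSD, kSU, kUS = k

    J0 = np.array([
        [-kUT - (kTU + kTD), -kUT + kDT, -kUT],
        [kTD, -(kDT + kDS), kSD],
        [-kUS, -kUS + kDS, -kUS - (kSU + kSD)],
    ])

    dk = _rate_slopes(A, params.kinetics)
    dUT, dTU, dTD, dDT, dDS, dSD, dSU, dUS = dk
    dF_dA = np.array([
        dUT * U + dDT * D - (dTU + dTD) * T,
        dTD * T + dSD * S - (dDT + dDS) * D,
        dUS * U + dDS * D - (dSU + dSD) * S,
    ])
    G = np.outer(dF_dA * activity_slope(S, params), np.array([0.0, 0.0, 1.0]))
    return J0, G


def jacobian(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`ode_rhs` at state y."""
    J0, G = jacobian_parts(y, params)
    return J0 + G


# ---------------------------------------------------------------------------
# fixed points and stability

_FP_STARTS = np.array([
    [0.25, 0.25, 0.25], [0.1, 0.1, 0.1], [0.1, 0.1, 0.5], [0.5, 0.1, 0.1],
    [0.1, 0.5, 0.1], [0.35, 0.35, 0.15], [0.15, 0.35, 0.35], [0.3, 0.15, 0.4],
])  # fractions of C_tot, interior of the simplex


def find_fixed_point(params: ModelParams, initial_guess=None,
                     tol: float = 1e-10) -> ClockConcentrations:
    """Solve ode_rhs = 0 inside the physical simplex.

    Multistart root solve (Powell hybrid) from 8 simplex-interior points plus
    the optional caller guess; converged roots are de-duplicated and the root
    reached from the most starts is returned (ties: smallest residual).
    A converging caller guess short-circuits the multistart (warm-start fast
    path used by the fitting objectives, which move in small parameter steps).
    """
    C = params.C_tot

    def fun(y):
        return ode_rhs(y, params)

    if initial_guess is not None:
        sol = root(fun, np.asarray(initial_guess, dtype=float),
                   jac=lambda y: jacobian(y, params), method="hybr",
                   options={"xtol": 1e-13})
        res = float(np.max(np.abs(fun(sol.x))))
        y = sol.x
        if res < tol and np.all(y > -1e-9) and y.sum() < C + 1e-9:
            y = np.clip(y, 0.0, C)
            return ClockConcentrations(phi_T=y[0], phi_D=y[1], phi_S=y[2], C_tot=C)

    starts = list(_FP_STARTS * C)

    roots: list[np.ndarray] = []
    counts: list[int] = []
    resids: list[float] = []
    best_res = np.inf
    for y0 in starts:
        sol = root(fun, y0, jac=lambda y: jacobian(y, params), method="hybr",
                   options={"xtol": 1e-13})
        res = float(np.max(np.abs(fun(sol.x))))
        best_res = min(best_res, res)
        y = sol.x
        inside = np.all(y > -1e-9) and (y.sum() < C + 1e-9)
        if res < tol and inside:
            for i, r in enumerate(roots):
                if np.max(np.abs(r - y)) < 1e-6 * C:
                    counts[i] += 1
                    if res < resids[i]:
                        roots[i], resids[i] = y, res
                    break
            else:
                roots.append(y)
                counts.append(1)
                resids.append(res)
    if not roots:
        raise FixedPointError(
            f"no fixed point converged below tol={tol}; best residual {best_res:.2e}",
            best_residual=best_res)
    order = sorted(range(len(roots)), key=lambda i: (-counts[i], resids[i]))
    y = np.clip(roots[order[0]], 0.0, C)
    return ClockConcentrations(phi_T=y[0], phi_D=y[1], phi_S=y[2], C_tot=C)


def measure_ode_period(params: ModelParams, *, transient_hr: float = 200.0,
                       run_hr: float = 300.0, dt: float = 0.05,
                       y0: np.ndarray | None = None) -> tuple[float, float]:
    """(period, amplitude decay per period) of a converged phi_T orbit.

    Integrates past a transient, then measures successive maxima of phi_T.
    Returns (nan, 0) when fewer than three peaks are found.
    """
    if y0 is None:
        try:
            fp = find_fixed_point(params).as_array()
        except FixedPointError:
            fp = np.array([0.25, 0.25, 0.25]) * params.C_tot
        y0 = fp + np.array([0.05, -0.03, 0.04]) * params.C_tot

    f = lambda t, y: ode_rhs(y, params)
    jac = lambda t, y: jacobian(y, params)
    s1 = solve_ivp(f, (0.0, transient_hr), y0, method="LSODA", jac=jac,
                   rtol=1e-9, atol=1e-12)
    t_eval = np.arange(0.0, run_hr, dt)
    s2 = solve_ivp(f, (0.0, run_hr), s1.y[:, -1], method="LSODA", jac=jac,
                   t_eval=t_eval, rtol=1e-9, atol=1e-12)
    x = s2.y[0]
    span = x.max() - x.min()
    if span <= 1e-12 * params.C_tot:
        return np.nan, 0.0
    peaks, _ = find_peaks(x, prominence=0.01 * span)
    if len(peaks) < 3:
        return np.nan, 0.0
    period = float(np.mean(np.diff(t_eval[peaks])))
    amp = x[peaks] - x.min()
    n_per = max(len(peaks) - 1, 1)
    decay = float((amp[0] - amp[-1]) / max(amp[0], 1e-300) / n_per)
    return period, decay


def stability_and_period(params: ModelParams, *, period_method: str = "ode",
                         eig_tol: float = 1e-9) -> StabilityReport:
    """Classify the fixed point and report the (quasi-)period.

    regime is 'limit_cycle' iff max Re(lambda) > eig_tol.  For a limit cycle
    the period is measured on a converged ODE orbit (``period_method='ode'``)
    or approximated by 2*pi/|Im lambda| (``'linear'``); for a stable focus the
    quasi-cycle period 2*pi/|Im lambda| of the leading pair is reported.
    """
    fp = find_fixed_point(params)
    ev = np.linalg.eigvals(jacobian(fp.as_array(), params))
    lead = ev[np.argmax(ev.real)]
    max_re = float(lead.real)
    im = float(abs(lead.imag))
    if max_re > eig_tol:
        regime = "limit_cycle"
        if period_method == "ode":
            period, _ = measure_ode_period(params)
        else:
            period = 2.0 * np.pi / im if im > eig_tol else np.nan
    elif im > eig_tol:
        regime = "stable_focus"
        period = 2.0 * np.pi / im
    else:
        regime = "stable_node"
        period = None
    if period is not None and not np.isfinite(period):
        period = None
    return StabilityReport(fixed_point=fp, eigenvalues=ev, regime=regime,
                           period_hr=period, max_re_lambda=max_re)


def hopf_scan(gamma_grid: Sequence[float], kaiA_grid: Sequence[float],
              kinetics: KineticParams | None = None, *,
              activity_form: str = "softplus", period_method: str = "linear",
              circadian_band: tuple[float, float] = CIRCADIAN_BAND_HR) -> pd.DataFrame:
    """Regime and period over the (gamma, [KaiA]) plane.

    Returns a tidy frame with columns gamma, kaiA, regime, period_hr,
    max_re_lambda, circadian (period within ``circadian_band``), ok.  Grid
    points where the fixed-point solve fails are marked ok=False, not fatal.
    The Hopf boundary is the sign change of max_re_lambda.
    """
    if kinetics is None:
        from .params import default_kinetics
        kinetics = default_kinetics()
    rows = []
    for g in gamma_grid:
        for a in kaiA_grid:
            p = ModelParams(kinetics=kinetics, gamma=float(g), kaiA_total=float(a),
                            activity_form=activity_form)
            try:
                rep = stability_and_period(p, period_method=period_method)
            except FixedPointError:
                rows.append(dict(gamma=g, kaiA=a, regime="failed", period_hr=np.nan,
                                 max_re_lambda=np.nan, circadian=False, ok=False))
                continue
            per = rep.period_hr if rep.period_hr is not None else np.nan
            circ = (rep.regime == "limit_cycle" and np.isfinite(per)
                    and circadian_band[0] <= per <= circadian_band[1])
            rows.append(dict(gamma=g, kaiA=a, regime=rep.regime, period_hr=per,
                             max_re_lambda=rep.max_re_lambda, circadian=circ, ok=True))
    return pd.DataFrame(rows)
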