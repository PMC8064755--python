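"""Kinetic and model parameters for the KaiC phosphoform clock.

The clock model tracks the three phosphorylated forms of KaiC — T-KaiC
(phospho-Thr432), S-KaiC (phospho-Ser431) and D-KaiC (doubly phosphorylated) —
with U-KaiC fixed by conservation of total KaiC.  Interconversion between
forms follows first-order rate laws whose rates are modulated by the active
KaiA concentration A through a saturating (Michaelis-type) dependence,

    k_XY(A) = max(0, k0_XY + kA_XY * A / (K_half + A))      [hr^-1]

S-KaiC sequesters KaiA (via KaiB), closing the delayed negative feedback that
drives the oscillation.  Default constants are the in vitro values of
Rust et al. (Science, 2007), shipped as a versioned JSON data file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "TRANSITIONS",
    "SOURCE_SPECIES",
    "STOICHIOMETRY",
    "KineticParams",
    "ModelParams",
    "default_kinetics",
    "default_params",
]

#: Transition labels X->Y in the fixed order used throughout the package.
TRANSITIONS: tuple[str, ...] = ("UT", "TU", "TD", "DT", "DS", "SD", "SU", "US")

#: Index of the source phosphoform of each transition in the order (U, T, D, S).
SOURCE_SPECIES: np.ndarray = np.array([0, 1, 1, 2, 2, 3, 3, 0], dtype=np.int64)

#: Stoichiometric change of (n_T, n_D, n_S) for each transition.
STOICHIOMETRY: np.ndarray = np.array(
    [
        [+1, 0, 0],   # U -> T
        [-1, 0, 0],   # T -> U
        [-1, +1, 0],  # T -> D
        [+1, -1, 0],  # D -> T
        [0, -1, +1],  # D -> S
        [0, +1, -1],  # S -> D
        [0, 0, -1],   # S -> U
        [0, 0, +1],   # U -> S
    ],
    dtype=np.int64,
)

_ACTIVITY_FORMS = ("softplus", "logistic", "sharp")


def _load_default_table() -> dict:
    text = resources.files("filaclock.data").joinpath(
        "kinetic_rates_invitro.json"
    ).read_text()
    return json.loads(text)


@dataclass(frozen=True)
class KineticParams:
    """Eight phosphoform interconversion rate laws plus totals.

    Attributes
    ----------
    k0 : ndarray, shape (8,)
        Basal rates (hr^-1), ordered as :data:`TRANSITIONS`.
    kA : ndarray, shape (8,)
        KaiA-stimulated increments (hr^-1); negative entries are permitted
        (KaiA slows some dephosphorylation steps) and the resulting rate is
        clamped at zero.
    K_half : float
        Half-saturation constant of the KaiA dependence (uM).
    C_tot : float
        Total KaiC concentration (uM).
    """

    k0: np.ndarray
    kA: np.ndarray
    K_half: float
    C_tot: float

    def __post_init__(self):
        object.__setattr__(self, "k0", np.asarray(self.k0, dtype=float))
        object.__setattr__(self, "kA", np.asarray(self.kA, dtype=float))
        if self.k0.shape != (8,) or self.kA.shape != (8,):
            raise ValueError("k0 and kA must each have 8 entries")
        if np.any(self.k0 < 0):
            raise ValueError("basal rates k0 must be non-negative")
        if not self.K_half > 0:
            raise ValueError("K_half must be positive")
        if not self.C_tot > 0:
            raise ValueError("C_tot must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        rates = d["rates"]
        k0 = [rates[t]["k0"] for t in TRANSITIONS]
        kA = [rates[t]["kA"] for t in TRANSITIONS]
        return cls(k0=np.array(k0), kA=np.array(kA),
                   K_half=float(d["K_half_uM"]), C_tot=float(d["C_tot_uM"]))

    def to_dict(self) -> dict:
        return {
            "K_half_uM": self.K_half,
            "C_tot_uM": self.C_tot,
            "rates": {
                t: {"k0": float(self.k0[i]), "kA": float(self.kA[i])}
                for i, t in enumerate(TRANSITIONS)
            },
        }

    def perturbed(self, rng: np.random.Generator, sigma_frac: float = 0.1) -> "KineticParams":
        """Return a copy with every nonzero kinetic constant redrawn from a
        Gaussian centred on its nominal value with SD = nominal * sigma_frac.

        Draws that would flip the sign of a constant are redrawn (truncation),
        preserving positivity of basal rates without a point mass at zero.
        """
        def draw(v):
            if v == 0.0:
                return 0.0
            while True:
                x = rng.normal(v, abs(v) * sigma_frac)
                if x * v > 0:
                    return x

        k0 = np.array([draw(v) for v in self.k0])
        kA = np.array([draw(v) for v in self.kA])
        K = draw(self.K_half)
        return replace(self, k0=k0, kA=kA, K_half=K)


@dataclass(frozen=True)
class ModelParams:
    """Full single-clock parameter set.

    gamma is the dimensionless steepness of the smoothed KaiA-sequestration
    function; kaiA_total the total KaiA concentration (uM); activity_form
    selects the smoothing of the sequestration rule (see
    :func:`filaclock.kai_core.active_kaiA`).
    """

    kinetics: KineticParams = field(default_factory=lambda: default_kinetics())
    gamma: float = 7.2
    kaiA_total: float = 1.308
    activity_form: str = "softplus"

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.kaiA_total < 0:
            raise ValueError("kaiA_total must be non-negative")
        if self.activity_form not in _ACTIVITY_FORMS:
            raise ValueError(f"activity_form must be one of {_ACTIVITY_FORMS}")

    @property
    def C_tot(self) -> float:
        return self.kinetics.C_tot

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "kaiA_total_uM": self.kaiA_total,
            "activity_form": self.activity_form,
            "kinetics": self.kinetics.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kin = KineticParams.from_dict(d["kinetics"]) if "kinetics" in d else default_kinetics()
        return cls(kinetics=kin, gamma=float(d.get("gamma", 7.2)),
                   kaiA_total=float(d.get("kaiA_total_uM", d.get("kaiA_total", 1.308))),
                   activity_form=d.get("activity_form", "softplus"))


def default_kinetics() -> KineticParams:
    """In vitro rate constants of Rust et al. (2007), from the packaged table."""
    return KineticParams.from_dict(_load_default_table())


def default_params(gamma: float = 7.2, kaiA_total: float = 1.308,
                   activity_form: str = "softplus") -> ModelParams:
    """Default model: in vitro kinetics with the fitted (gamma, [KaiA]) point."""
    return ModelParams(kinetics=default_kinetics(), gamma=gamma,
                       kaiA_total=kaiA_total, activity_form=activity_form)
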