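"""Tumor–drug–toxicity dynamics.

The model couples a two-species logistic competition system of
drug-sensitive (``S``) and drug-resistant (``R``) tumor cells with
one-compartment drug pharmacokinetics (``C``) and a linearly-resolving
accumulated-toxicity variable (``T``)::

    S' = alpha_S * S * (1 - (S + R)/K) - delta * C * S
    R' = alpha_R * R * (1 - (beta*S + R)/K)
    C' = -lam * C          (doses enter as instantaneous impulses)
    T' = mu * C - gamma * T

Only sensitive cells are killed by the drug; resistance carries a
fitness cost, expressed by deriving the resistant growth rate as
``alpha_R = epsilon * alpha_S`` with ``0 < epsilon <= 1``.  Cell burdens
are measured as percentages of the shared carrying capacity ``K = 100``,
so a burden of 50 means the tumor sits at half of carrying capacity.

Because doses are impulses, the drug concentration between doses is an
exact exponential and the toxicity equation admits a closed-form
convolution solution; both closed forms are exposed here
(:func:`analytic_C`, :func:`analytic_T`) and serve as oracles for the
numerical integrator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "SystemState",
    "InitialCondition",
    "rhs",
    "apply_dose",
    "analytic_C",
    "analytic_T",
    "toxicity_kernel",
]

#: fields that must be strictly positive (delta may be zero: a drug with
#: no kill effect is a meaningful boundary case, not an invalid model)
_POSITIVE_FIELDS = ("alpha_S", "K", "beta", "lam", "mu", "gamma")

#: mapping from serialized (field-standard) names to attribute names;
#: "lambda" is a Python keyword so the attribute is called ``lam``.
_SERIAL_TO_ATTR = {
    "alpha_S": "alpha_S",
    "epsilon": "epsilon",
    "K": "K",
    "delta": "delta",
    "beta": "beta",
    "lambda": "lam",
    "mu": "mu",
    "gamma": "gamma",
}
_ATTR_TO_SERIAL = {v: k for k, v in _SERIAL_TO_ATTR.items()}


@dataclass(frozen=True)
class ModelParams:
    """The nine model parameters (eight stored, ``alpha_R`` derived).

    Defaults are the baseline parameterization: a generic
    chemotherapeutic agent acting on a tumor at half carrying capacity.

    Parameters
    ----------
    alpha_S : float
        Growth rate of sensitive cells (per day).
    epsilon : float
        Ratio of resistant to sensitive growth rate, in ``(0, 1]``.
        ``alpha_R`` is always ``epsilon * alpha_S``; epsilon is the
        single stored degree of freedom, which makes inconsistent
        (``alpha_R``, ``epsilon``) pairs unrepresentable.
    K : float
        Shared carrying capacity (dimensionless; burdens are expressed
        on a 0–100 scale by default).
    delta : float
        Drug-induced kill rate of sensitive cells (per day per unit
        drug concentration).
    beta : float
        Competitive suppression exerted by sensitive cells on resistant
        cells (dimensionless).  ``beta > 1`` means sensitive cells
        suppress resistant ones more strongly than they suppress
        themselves.
    lam : float
        Drug clearance rate (per day).  Serialized as ``"lambda"``.
    mu : float
        Toxicity accumulation rate (per day per unit drug).
    gamma : float
        Toxicity recovery rate (per day).
    """

    alpha_S: float = 1.0
    epsilon: float = 0.4
    K: float = 100.0
    delta: float = 1.0
    beta: float = 2.4
    lam: float = 0.693
    mu: float = 1.0
    gamma: float = 0.4

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive number, got {v!r}")
        if not (isinstance(self.delta, (int, float)) and math.isfinite(self.delta) and self.delta >= 0):
            raise ValueError(f"delta must be finite and non-negative, got {self.delta!r}")
        if not (isinstance(self.epsilon, (int, float)) and 0 < self.epsilon <= 1):
            raise ValueError(
                f"epsilon must lie in (0, 1] (resistant cells cannot outgrow "
                f"sensitive ones), got {self.epsilon!r}"
            )

    @property
    def alpha_R(self) -> float:
        """Resistant-cell growth rate, derived as ``epsilon * alpha_S``."""
        return self.epsilon * self.alpha_S

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields changed.

        Accepts ``alpha_R`` as a convenience: it is converted to an
        equivalent ``epsilon`` against the (possibly simultaneously
        updated) ``alpha_S``.
        """
        if "alpha_R" in changes:
            if "epsilon" in changes:
                raise ValueError("give either alpha_R or epsilon, not both")
            alpha_R = changes.pop("alpha_R")
            alpha_S = changes.get("alpha_S", self.alpha_S)
            changes["epsilon"] = alpha_R / alpha_S
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Flat mapping using the standard symbol names (``lambda``, not ``lam``)."""
        return {_ATTR_TO_SERIAL[f.name]: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        """Build from a flat mapping; unknown keys raise.

        ``alpha_R`` is rejected: it is derived, so supplying it
        independently could silently contradict ``epsilon``.
        """
        kwargs = {}
        for key, value in mapping.items():
            if key == "alpha_R":
                raise ValueError("alpha_R is derived from epsilon*alpha_S; set epsilon instead")
            attr = _SERIAL_TO_ATTR.get(key, key if key == "lam" else None)
            if attr is None:
                raise ValueError(f"unknown model parameter {key!r}")
            kwargs[attr] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous model state: time plus the four dynamic variables."""

    t: float
    S: float
    R: float
    C: float
    T: float

    @property
    def total(self) -> float:
        """Total tumor burden ``S + R``."""
        return self.S + self.R


@dataclass(frozen=True)
class InitialCondition:
    """State at ``t = 0``.

    Defaults: tumor at half carrying capacity with 1% pre-existing
    resistance (``S0 = 49.5``, ``R0 = 0.5``) and no drug or toxicity
    on board (the values just before the first dose).
    """

    S0: float = 49.5
    R0: float = 0.5
    C0: float = 0.0
    T0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S0", "R0", "C0", "T0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")

    def as_state(self) -> SystemState:
        return SystemState(t=0.0, S=self.S0, R=self.R0, C=self.C0, T=self.T0)


def rhs(state: SystemState, params: ModelParams) -> tuple[float, float, float, float]:
    """Time-derivatives ``(dS/dt, dR/dt, dC/dt, dT/dt)`` at a state.

    The drug source term is absent here: doses are instantaneous
    impulses applied via :func:`apply_dose`, so between doses the
    concentration simply clears exponentially.

    Raises
    ------
    ValueError
        If any state component is non-finite (numerical blow-up
        upstream) .
    """
    S, R, C, T = state.S, state.R, state.C, state.T
    if not all(map(math.isfinite, (S, R, C, T))):
        raise ValueError(f"non-finite state at t={state.t}: S={S}, R={R}, C={C}, T={T}")
    K = params.K
    dS = params.alpha_S * S * (1.0 - (S + R) / K) - params.delta * C * S
    dR = params.alpha_R * R * (1.0 - (params.beta * S + R) / K)
    dC = -params.lam * C
    dT = params.mu * C - params.gamma * T
    return (dS, dR, dC, dT)


def apply_dose(state: SystemState, dose: float) -> SystemState:
    """Instantaneously inject ``dose`` units of drug (``C += dose``)."""
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    return dataclasses.replace(state, C=state.C + dose)


def analytic_C(C0: float, lam: float, dt) -> float:
    """Drug concentration after ``dt`` days of pure clearance.

    Closed form ``C0 * exp(-lam * dt)``; the oracle for the integrated
    concentration between impulses.  ``dt`` may be an array.
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be non-negative")
    out = C0 * np.exp(-lam * dt)
    return float(out) if out.ndim == 0 else out


def toxicity_kernel(dt, lam: float, gamma: float):
    """Toxicity response at lag ``dt`` to a unit drug impulse at lag 0.

    ``(exp(-gamma*dt) - exp(-lam*dt)) / (lam - gamma)``, with the
    removable singularity at ``lam == gamma`` resolved by its limit
    ``dt * exp(-gamma*dt)``.  Vectorized over ``dt``.
    """
    dt = np.asarray(dt, dtype=float)
    if abs(lam - gamma) <= 1e-12 * max(abs(lam), abs(gamma)):
        out = dt * np.exp(-gamma * dt)
    else:
        out = (np.exp(-gamma * dt) - np.exp(-lam * dt)) / (lam - gamma)
    return float(out) if out.ndim == 0 else out


def analytic_T(dose_times, params: ModelParams, t: float) -> float:
    """Closed-form accumulated toxicity at time ``t`` for unit doses.

    Starting from ``C(0) = T(0) = 0`` with unit drug impulses at the
    given times, ``T(t) = mu * integral_0^t exp(-gamma (t-s)) C(s) ds``
    evaluates to a sum of :func:`toxicity_kernel` terms, one per dose
    administered at or before ``t``.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    if dose_times.size and np.any(np.diff(dose_times) < 0):
        raise ValueError("dose_times must be sorted ascending")
    if t < 0:
        raise ValueError("t must be non-negative")
    past = dose_times[dose_times <= t]
    if past.size == 0:
        return 0.0
    return float(params.mu * np.sum(toxicity_kernel(t - past, params.lam, params.gamma)))
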