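"""Virtual patients, threshold optimization and Kaplan–Meier summaries.

A virtual patient (VP) is a parameter tuple ``(alpha_S, alpha_R, delta,
beta, gamma)`` drawn from independent lognormal distributions whose
mode sits at the baseline parameterization and whose central 95%
interval approximately spans the range that parameter was given in the
global sensitivity analysis.  The carrying capacity ``K``, drug
clearance ``lam`` and toxicity accumulation rate ``mu`` are fixed
across patients: with burdens measured relative to ``K`` it cannot
affect TTP, and ``mu``/``lam`` trade off against ``gamma``/``delta``
(a faster-accumulating toxicity is indistinguishable from rescaled
thresholds, a faster-clearing drug from a stronger kill rate).

On a population, protocol thresholds can be swept
(:func:`mean_ttp_threshold_sweep`) or exhaustively optimized for mean
TTP (:func:`optimize_thresholds`, up to the four-dimensional
``rx_on``/``rx_off``/``tox_on``/``tox_off`` space of the dual-feedback
protocol), and per-patient progression times summarized as a
Kaplan–Meier curve (:func:`km_curve`).  Non-progressing patients carry
the sentinel TTP in means, but enter the Kaplan–Meier curve as
non-events through the end of study — the curve is simply the empirical
fraction not yet progressed, since the only censoring is administrative
at the horizon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import InitialCondition, ModelParams
from .protocols import Protocol, ProtocolSpec
from .simulator import time_to_progression, ttp_batch
from .sweeps import SweepResult, sweep_thresholds, threshold_feasible

__all__ = [
    "LognormalSpec",
    "VPopSpec",
    "VirtualPopulation",
    "KMCurve",
    "sample_vpop",
    "vpop_ttp",
    "mean_ttp_threshold_sweep",
    "optimize_thresholds",
    "km_curve",
]

#: z-quantile such that exp(log_mode ± z*sigma) spans the central 95%
_Z95 = 1.959963984540054

#: eFAST ranges used to set the lognormal widths (central 95% interval)
_DEFAULT_RANGES = {
    "alpha_S": (0.5, 1.5),
    "epsilon": (0.2, 1.0),
    "delta": (0.5, 1.5),
    "beta": (0.5, 3.5),
    "gamma": (0.2, 0.8),
}


@dataclass(frozen=True)
class LognormalSpec:
    """Location/scale of one parameter's lognormal on the log axis."""

    mu_log: float
    sigma_log: float

    def __post_init__(self) -> None:
        if not self.sigma_log > 0:
            raise ValueError(f"sigma_log must be positive, got {self.sigma_log}")

    @classmethod
    def from_mode_and_range(cls, mode: float, lo: float, hi: float) -> "LognormalSpec":
        """Shape parameters with the distribution mode at ``mode`` and the
        central 95% interval spanning roughly ``[lo, hi]``.

        The lognormal mode is ``exp(mu - sigma^2)``; the central 95%
        interval has log-width ``2 * z * sigma``, so ``sigma`` is set
        from the range ratio and ``mu`` back-solved from the mode.
        """
        if not (0 < lo < hi):
            raise ValueError("need 0 < lo < hi")
        sigma = math.log(hi / lo) / (2.0 * _Z95)
        return cls(mu_log=math.log(mode) + sigma**2, sigma_log=sigma)

    @property
    def mode(self) -> float:
        return math.exp(self.mu_log - self.sigma_log**2)


def _default_settings() -> dict[str, LognormalSpec]:
    base = ModelParams()
    return {
        name: LognormalSpec.from_mode_and_range(getattr(base, name), lo, hi)
        for name, (lo, hi) in _DEFAULT_RANGES.items()
    }


@dataclass(frozen=True)
class VPopSpec:
    """Sampling specification for a virtual population.

    ``settings`` maps each sampled parameter name to its lognormal;
    epsilon draws above 1 are rejected and redrawn (preserving the
    lognormal shape inside the admissible interval rather than piling
    mass at the boundary).  ``K``, ``lam`` and ``mu`` stay at baseline.
    """

    n_patients: int = 100
    settings: dict[str, LognormalSpec] = field(default_factory=_default_settings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name, ln in self.settings.items():
            if not isinstance(ln, LognormalSpec):
                raise ValueError(f"settings[{name!r}] must be a LognormalSpec")


@dataclass(frozen=True)
class VirtualPopulation:
    """Sampled patients plus the spec that (re)generates them."""

    patients: tuple[ModelParams, ...]
    spec: VPopSpec

    def __len__(self) -> int:
        return len(self.patients)

    def to_records(self) -> list[dict]:
        return [
            {
                "patient_id": i,
                "alpha_S": p.alpha_S,
                "epsilon": p.epsilon,
                "alpha_R": p.alpha_R,
                "delta": p.delta,
                "beta": p.beta,
                "gamma": p.gamma,
            }
            for i, p in enumerate(self.patients)
        ]


def sample_vpop(spec: VPopSpec, base: ModelParams | None = None) -> VirtualPopulation:
    """Draw a virtual population (deterministic under the spec's seed)."""
    if base is None:
        base = ModelParams()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    draws: dict[str, np.ndarray] = {}
    for name, ln in spec.settings.items():
        x = rng.lognormal(mean=ln.mu_log, sigma=ln.sigma_log, size=n)
        if name == "epsilon":
            bad = x > 1.0
            while bad.any():
                x[bad] = rng.lognormal(mean=ln.mu_log, sigma=ln.sigma_log, size=int(bad.sum()))
                bad = x > 1.0
        draws[name] = x
    patients = tuple(
        base.replace(**{name: float(draws[name][i]) for name in draws}) for i in range(n)
    )
    return VirtualPopulation(patients=patients, spec=spec)


def vpop_ttp(
    population: VirtualPopulation | list[ModelParams],
    spec: ProtocolSpec,
    init: InitialCondition | None = None,
    *,
    engine: str = "grid",
) -> np.ndarray:
    """Per-patient time to progression (sentinel for non-progressors)."""
    patients = list(population.patients if isinstance(population, VirtualPopulation) else population)
    if not patients:
        return np.empty(0)
    if engine == "grid":
        return ttp_batch(patients, spec, init)["ttp"]
    if engine != "event":
        raise ValueError(f"unknown engine {engine!r}")
    return np.array([time_to_progression(p, spec, init) for p in patients])


def _nanmean(a: np.ndarray, axis: int) -> np.ndarray:
    """nanmean that quietly returns NaN for all-NaN slices."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


def mean_ttp_threshold_sweep(
    population: VirtualPopulation | list[ModelParams],
    protocol,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    *,
    base_spec: ProtocolSpec | None = None,
    init: InitialCondition | None = None,
    engine: str = "grid",
) -> SweepResult:
    """Population-mean TTP over a 2-D threshold grid.

    Feasibility masking is identical to the single-patient
    :func:`~adaptox.sweeps.sweep_thresholds` (thresholds constrain the
    protocol, not the patient).  A single-patient population reduces to
    that function exactly.
    """
    patients = list(population.patients if isinstance(population, VirtualPopulation) else population)
    if not patients:
        raise ValueError("population must be non-empty")
    proto = Protocol.parse(protocol)

    if engine == "event" or len(patients) == 1:
        # per-patient reference path; a single patient reduces exactly to
        # the plain threshold sweep
        results = [
            sweep_thresholds(
                p, proto, axis1, axis2, base_spec=base_spec, init=init, engine=engine
            )
            for p in patients
        ]
        first = results[0]
        mean_ttp = np.mean([r.ttp[proto] for r in results], axis=0)
        mean_frac = _nanmean(np.stack([r.fraction_resistant[proto] for r in results]), axis=0)
        return SweepResult(
            axis_names=first.axis_names,
            axis_values=first.axis_values,
            protocols=[proto],
            ttp={proto: mean_ttp},
            fraction_resistant={proto: mean_frac},
            feasible=first.feasible,
            base_params=first.base_params,
            base_spec=first.base_spec,
        )

    # one vectorized run over feasible cells x patients
    if base_spec is None:
        base_spec = ProtocolSpec()
    (name1, grid1), (name2, grid2) = axis1, axis2
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    template = sweep_thresholds(  # reuses validation + masking on a cheap probe
        patients[0], proto, (name1, grid1), (name2, grid2),
        base_spec=base_spec.replace(horizon=base_spec.decision_interval), init=init,
        engine="grid",
    )
    feas = template.feasible
    flat_idx = [(i, j) for i in range(grid1.size) for j in range(grid2.size) if feas[i, j]]
    n_pat = len(patients)
    thr_arrays: dict[str, np.ndarray] = {}
    for key in ("rx_on", "rx_off", "tox_on", "tox_off"):
        vals = []
        for i, j in flat_idx:
            v = getattr(base_spec, key)
            if key == name1:
                v = grid1[i]
            elif key == name2:
                v = grid2[j]
            vals.append(float(v))
        thr_arrays[key] = np.repeat(vals, n_pat)
    out = ttp_batch(
        patients * len(flat_idx),
        base_spec.replace(protocol=proto),
        init,
        thresholds=thr_arrays,
    )
    ttp_cells = out["ttp"].reshape(len(flat_idx), n_pat).mean(axis=1)
    frac_mean = _nanmean(out["fraction_resistant"].reshape(len(flat_idx), n_pat), axis=1)
    mean_ttp = np.full(feas.shape, np.nan)
    mean_frac = np.full(feas.shape, np.nan)
    for m, (i, j) in enumerate(flat_idx):
        mean_ttp[i, j] = ttp_cells[m]
        mean_frac[i, j] = frac_mean[m]
    return SweepResult(
        axis_names=(name1, name2),
        axis_values=(grid1, grid2),
        protocols=[proto],
        ttp={proto: mean_ttp},
        fraction_resistant={proto: mean_frac},
        feasible=feas,
        base_params=patients[0],
        base_spec=base_spec.replace(protocol=proto),
    )


def optimize_thresholds(
    population: VirtualPopulation | list[ModelParams],
    protocol,
    grids: dict[str, np.ndarray],
    *,
    base_spec: ProtocolSpec | None = None,
    init: InitialCondition | None = None,
) -> dict:
    """Exhaustive search for the threshold tuple maximizing mean TTP.

    ``grids`` maps threshold names to candidate values; the dual
    feedback protocol admits all four axes, the single-feedback
    protocols at most their own two.  Infeasible combinations
    (``rx_on <= rx_off`` or ``tox_off <= tox_on``) are excluded.  Ties
    are broken by the first combination in lexicographic grid order;
    the number of tied optima is reported.

    Returns a dict with ``thresholds`` (name -> value), ``mean_ttp``,
    ``n_ties``, ``n_feasible`` and the per-patient ``ttps`` at the
    optimum.
    """
    patients = list(population.patients if isinstance(population, VirtualPopulation) else population)
    if not patients:
        raise ValueError("population must be non-empty")
    proto = Protocol.parse(protocol)
    if base_spec is None:
        base_spec = ProtocolSpec()

    allowed = set()
    if proto.uses_tumor:
        allowed |= {"rx_on", "rx_off"}
    if proto.uses_toxicity:
        allowed |= {"tox_on", "tox_off"}
    bad = set(grids) - allowed
    if bad:
        raise ValueError(
            f"threshold axes {sorted(bad)} are inactive under protocol {proto.value!r}"
        )
    names = list(grids)
    grids_f = [np.asarray(grids[n], dtype=float) for n in names]

    combos = []
    for values in itertools.product(*grids_f):
        thr = {
            "rx_on": base_spec.rx_on,
            "rx_off": base_spec.rx_off,
            "tox_on": base_spec.tox_on,
            "tox_off": base_spec.tox_off,
        }
        thr.update(dict(zip(names, map(float, values))))
        if threshold_feasible(**thr):
            combos.append(thr)
    if not combos:
        raise ValueError("no feasible threshold combination in the supplied grids")

    n_cells = len(combos)
    n_pat = len(patients)
    # batch layout: cell-major so each patient block is contiguous per cell
    thr_arrays = {
        key: np.repeat([c[key] for c in combos], n_pat) for key in combos[0]
    }
    params_flat = patients * n_cells
    out = ttp_batch(
        params_flat, base_spec.replace(protocol=proto), init, thresholds=thr_arrays
    )
    ttps = out["ttp"].reshape(n_cells, n_pat)
    means = ttps.mean(axis=1)
    best = int(np.argmax(means))  # first max = lexicographic tie-break
    n_ties = int(np.sum(means == means[best]))
    return {
        "protocol": proto,
        "thresholds": {n: combos[best][n] for n in names},
        "mean_ttp": float(means[best]),
        "n_ties": n_ties,
        "n_feasible": n_cells,
        "ttps": ttps[best],
    }


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier estimate of the fraction not yet progressed.

    With no censoring before the administrative end of study, the
    estimator coincides with the empirical survival function:
    ``survival[i]`` is the fraction still progression-free just after
    ``event_times[i]``; ``n_at_risk[i]`` counts patients at risk just
    before it.  The curve starts at 1 and extends flat to the horizon.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n: int
    horizon: float

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step-function evaluation."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        out = vals[idx]
        return float(out) if out.ndim == 0 else out


def km_curve(ttps, horizon: float = 100.0) -> KMCurve:
    """Kaplan–Meier curve from per-patient progression times.

    Sentinel values (progression beyond the horizon) never produce
    events; they are carried as at-risk non-events through the horizon.
    """
    ttps = np.asarray(ttps, dtype=float)
    if ttps.size == 0:
        raise ValueError("ttps must be non-empty")
    if np.any(ttps < 0):
        raise ValueError("negative time to progression")
    n = ttps.size
    event_mask = ttps <= horizon
    times = np.unique(ttps[event_mask])
    surv = []
    risk = []
    s = 1.0
    for t in times:
        at_risk = int(np.sum(ttps >= t))  # non-events stay at risk to the horizon
        d = int(np.sum(ttps == t))
        risk.append(at_risk)
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KMCurve(
        event_times=times,
        survival=np.asarray(surv),
        n_at_risk=np.asarray(risk, dtype=int),
        n=n,
        horizon=float(horizon),
    )
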