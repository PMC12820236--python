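"""Grid sweeps over model parameters and protocol thresholds.

Three views of the TTP landscape:

* :func:`sweep_params` — two model parameters varied on a grid, every
  protocol simulated per cell, with the per-cell set of protocols that
  maximize TTP (``alpha_R`` may be named as an axis; it is swept by
  varying ``epsilon``).
* :func:`sweep_thresholds` — two protocol thresholds varied for one
  protocol; cells violating ``rx_on > rx_off`` or ``tox_off > tox_on``
  are masked infeasible rather than silently skipped.
* :func:`gamma_bifurcation_scan` — a one-dimensional scan of the
  toxicity recovery rate classifying the *cause* of treatment failure
  (sensitive-driven vs resistant-driven vs no failure), which changes
  qualitatively with gamma even though TTP itself is fairly
  insensitive to it.

Every cell is an independent simulation; results are therefore
permutation-invariant in the grid ordering.  The ``engine`` argument
selects the integration backend: ``"event"`` (the reference
event-detecting solver; default) or ``"grid"`` (the vectorized
fixed-step engine, orders of magnitude faster for large grids).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import InitialCondition, ModelParams
from .protocols import Protocol, ProtocolSpec
from .simulator import simulate, ttp_batch

__all__ = [
    "SweepResult",
    "sweep_params",
    "sweep_thresholds",
    "gamma_bifurcation_scan",
]

_MODEL_AXES = {"alpha_S", "epsilon", "alpha_R", "K", "delta", "beta", "lam", "mu", "gamma"}
_THRESHOLD_AXES = {"rx_on", "rx_off", "tox_on", "tox_off"}


@dataclass
class SweepResult:
    """TTP matrices over a 2-D grid, per protocol.

    ``ttp[protocol][i, j]`` corresponds to ``axis_values[0][i]`` ×
    ``axis_values[1][j]``.  ``fraction_resistant`` is NaN where the
    tumor did not progress (sentinel TTP) or the cell is infeasible.
    ``optimal_protocols[i, j]`` is the frozenset of protocols attaining
    the cell's maximal TTP (ties kept, which is common at the
    sentinel); it is None for sweeps of a single protocol.
    """

    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    protocols: list[Protocol]
    ttp: dict[Protocol, np.ndarray]
    fraction_resistant: dict[Protocol, np.ndarray]
    feasible: np.ndarray
    optimal_protocols: np.ndarray | None = None
    base_params: ModelParams = field(default_factory=ModelParams)
    base_spec: ProtocolSpec | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per cell per protocol."""
        a1, a2 = self.axis_values
        rows = []
        for proto in self.protocols:
            for i, v1 in enumerate(a1):
                for j, v2 in enumerate(a2):
                    rows.append(
                        {
                            self.axis_names[0]: v1,
                            self.axis_names[1]: v2,
                            "protocol": proto.value,
                            "ttp": self.ttp[proto][i, j],
                            "fraction_resistant": self.fraction_resistant[proto][i, j],
                            "feasible": bool(self.feasible[i, j]),
                        }
                    )
        return pd.DataFrame(rows)


def _check_grid(name: str, grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError(f"axis {name!r}: grid must be a non-empty 1-D array")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise ValueError(f"axis {name!r}: grid values must be strictly increasing")
    return g


def _cell_ttps(
    params_list: list[ModelParams],
    spec: ProtocolSpec,
    init: InitialCondition | None,
    engine: str,
    thresholds: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(ttp, fraction_resistant) arrays for a flat list of courses."""
    if engine == "grid":
        out = ttp_batch(params_list, spec, init, thresholds=thresholds)
        return out["ttp"], out["fraction_resistant"]
    if engine != "event":
        raise ValueError(f"unknown engine {engine!r}; expected 'event' or 'grid'")
    n = len(params_list)
    thresholds = thresholds or {}
    ttp = np.empty(n)
    frac = np.full(n, np.nan)
    for i, p in enumerate(params_list):
        s = spec
        if thresholds:
            s = spec.replace(**{k: float(np.atleast_1d(v)[i % np.atleast_1d(v).size]) for k, v in thresholds.items()})
        res = simulate(p, s, init, dense=False)
        ttp[i] = res.ttp
        if res.progressed and res.fraction_resistant_at_ttp is not None:
            frac[i] = res.fraction_resistant_at_ttp
    return ttp, frac


def sweep_params(
    base: ModelParams,
    protocols,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    *,
    spec: ProtocolSpec | None = None,
    init: InitialCondition | None = None,
    engine: str = "event",
) -> SweepResult:
    """TTP and composition-at-failure over a 2-D model-parameter grid.

    ``protocols`` is an iterable of protocol identities to compare;
    ``spec`` supplies the (shared) thresholds and horizon.  Axis names
    are ``ModelParams`` fields, with ``alpha_R`` accepted and swept by
    varying ``epsilon``.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in _MODEL_AXES:
            raise ValueError(f"unknown model-parameter axis {name!r}")
    if name1 == name2:
        raise ValueError("the two axes must name different parameters")
    grid1 = _check_grid(name1, grid1)
    grid2 = _check_grid(name2, grid2)
    protocols = [Protocol.parse(p) for p in protocols]
    if spec is None:
        spec = ProtocolSpec()

    cells = [
        base.replace(**{name1: v1, name2: v2})
        for v1, v2 in itertools.product(grid1, grid2)
    ]
    shape = (grid1.size, grid2.size)
    ttp: dict[Protocol, np.ndarray] = {}
    frac: dict[Protocol, np.ndarray] = {}
    for proto in protocols:
        t, f = _cell_ttps(cells, spec.replace(protocol=proto), init, engine)
        ttp[proto] = t.reshape(shape)
        frac[proto] = f.reshape(shape)

    stacked = np.stack([ttp[p] for p in protocols])
    best = stacked.max(axis=0)
    optimal = np.empty(shape, dtype=object)
    for i in range(shape[0]):
        for j in range(shape[1]):
            optimal[i, j] = frozenset(
                p for k, p in enumerate(protocols) if stacked[k, i, j] == best[i, j]
            )

    return SweepResult(
        axis_names=(name1, name2),
        axis_values=(grid1, grid2),
        protocols=protocols,
        ttp=ttp,
        fraction_resistant=frac,
        feasible=np.ones(shape, dtype=bool),
        optimal_protocols=optimal,
        base_params=base,
        base_spec=spec,
    )


def threshold_feasible(
    rx_on: float, rx_off: float, tox_on: float, tox_off: float
) -> bool:
    """Whether a threshold combination is admissible (strict hysteresis bands)."""
    return (rx_on > rx_off) and (tox_off > tox_on)


def sweep_thresholds(
    base: ModelParams,
    protocol,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    *,
    base_spec: ProtocolSpec | None = None,
    init: InitialCondition | None = None,
    engine: str = "event",
) -> SweepResult:
    """TTP over a 2-D protocol-threshold grid for a single protocol.

    Cells where the resolved threshold set violates ``rx_on > rx_off``
    or ``tox_off > tox_on`` are infeasible: masked (NaN TTP,
    ``feasible=False``), mirroring the blacked-out regions of a
    threshold heatmap.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in _THRESHOLD_AXES:
            raise ValueError(f"unknown threshold axis {name!r}")
    if name1 == name2:
        raise ValueError("the two axes must name different thresholds")
    grid1 = _check_grid(name1, grid1)
    grid2 = _check_grid(name2, grid2)
    proto = Protocol.parse(protocol)
    if base_spec is None:
        base_spec = ProtocolSpec()

    shape = (grid1.size, grid2.size)
    ttp = np.full(shape, np.nan)
    frac = np.full(shape, np.nan)
    feas = np.zeros(shape, dtype=bool)

    flat_idx = []
    flat_thr: dict[str, list[float]] = {"rx_on": [], "rx_off": [], "tox_on": [], "tox_off": []}
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            thr = {
                "rx_on": base_spec.rx_on,
                "rx_off": base_spec.rx_off,
                "tox_on": base_spec.tox_on,
                "tox_off": base_spec.tox_off,
            }
            thr[name1] = float(v1)
            thr[name2] = float(v2)
            if threshold_feasible(**thr):
                feas[i, j] = True
                flat_idx.append((i, j))
                for k, v in thr.items():
                    flat_thr[k].append(v)

    if flat_idx:
        spec = base_spec.replace(protocol=proto)
        t, f = _cell_ttps(
            [base] * len(flat_idx),
            spec,
            init,
            engine,
            thresholds={k: np.asarray(v) for k, v in flat_thr.items()},
        )
        for m, (i, j) in enumerate(flat_idx):
            ttp[i, j] = t[m]
            frac[i, j] = f[m]

    return SweepResult(
        axis_names=(name1, name2),
        axis_values=(grid1, grid2),
        protocols=[proto],
        ttp={proto: ttp},
        fraction_resistant={proto: frac},
        feasible=feas,
        base_params=base,
        base_spec=base_spec.replace(protocol=proto),
    )


def gamma_bifurcation_scan(
    base: ModelParams,
    protocol,
    gamma_grid,
    *,
    spec: ProtocolSpec | None = None,
    init: InitialCondition | None = None,
    engine: str = "event",
    majority_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Classify the cause of treatment failure along a gamma scan.

    For a toxicity-feedback protocol, slow toxicity recovery (small
    gamma) forces long treatment breaks during which *sensitive* cells
    regrow and drive failure, while fast recovery (large gamma) permits
    near-continuous dosing that eliminates sensitive cells and lets
    *resistant* cells drive failure.  Returns a frame with columns
    ``gamma``, ``ttp``, ``fraction_resistant``, ``cause`` where cause
    is ``"resistant"`` if the resistant fraction at progression exceeds
    the majority cutoff, ``"sensitive"`` otherwise, and ``"none"`` when
    the tumor does not progress within the horizon.
    """
    proto = Protocol.parse(protocol)
    if not proto.uses_toxicity:
        raise ValueError("gamma bifurcation scan requires a toxicity-feedback protocol")
    grid = _check_grid("gamma", gamma_grid)
    if spec is None:
        spec = ProtocolSpec()
    spec = spec.replace(protocol=proto)

    cells = [base.replace(gamma=float(g)) for g in grid]
    ttp, frac = _cell_ttps(cells, spec, init, engine)
    cause = np.where(
        ttp >= spec.ttp_sentinel,
        "none",
        np.where(frac > majority_cutoff, "resistant", "sensitive"),
    )
    return pd.DataFrame(
        {"gamma": grid, "ttp": ttp, "fraction_resistant": frac, "cause": cause}
    )
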