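"""Treatment decision rules.

Four protocols, each evaluated once per decision interval (daily by
default), just before a potential dose administration:

``DAILY``
    A fixed dose every day, unconditionally.
``ADAPTIVE``
    Dose-skipping adaptive therapy: pause when the total tumor burden
    falls below ``rx_off``, resume once it regrows above ``rx_on``.
``DAILY_TOX``
    Daily dosing gated by accumulated toxicity: pause when toxicity
    surpasses ``tox_off``, resume once it falls below ``tox_on``.
``ADAPTIVE_TOX``
    Both feedbacks combined, with toxicity acting as an override:
    pause when *either* toxicity is above ``tox_off`` or burden is
    below ``rx_off``; resume only when *both* toxicity is below
    ``tox_on`` and burden is above ``rx_on``.

All rules are hysteresis state machines: between the two thresholds of
an observable the treating/paused status is retained, so the rule's
output depends on the current :class:`TreatmentStatus`.  Threshold
comparisons are strict ("falls below", "surpasses"); exact equality
leaves the status unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum

__all__ = ["Protocol", "ProtocolSpec", "TreatmentStatus", "decide"]


class Protocol(str, Enum):
    """Identity of a treatment decision rule."""

    DAILY = "daily"
    ADAPTIVE = "adaptive"
    DAILY_TOX = "daily_tox"
    ADAPTIVE_TOX = "adaptive_tox"

    @property
    def uses_tumor(self) -> bool:
        """Whether tumor-size thresholds participate in decisions."""
        return self in (Protocol.ADAPTIVE, Protocol.ADAPTIVE_TOX)

    @property
    def uses_toxicity(self) -> bool:
        """Whether toxicity thresholds participate in decisions."""
        return self in (Protocol.DAILY_TOX, Protocol.ADAPTIVE_TOX)

    @classmethod
    def parse(cls, value) -> "Protocol":
        """Accept a Protocol, its value, or a dashed/uppercase alias."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            key = value.strip().lower().replace("-", "_")
            try:
                return cls(key)
            except ValueError:
                pass
        raise ValueError(
            f"unknown protocol {value!r}; expected one of "
            f"{[p.value for p in cls]}"
        )


@dataclass(frozen=True)
class ProtocolSpec:
    """A protocol identity plus every knob governing one simulated course.

    Default thresholds are the baseline clinical logic: pause adaptive
    dosing once the tumor has shrunk to 40% of its initial size of 50,
    resume when it regrows past its initial size; pause on toxicity
    above 2, resume below 1.  Progression (treatment failure) is a
    burden of 75 — 150% of the initial burden — and the course is
    simulated for at most 100 days, with a sentinel TTP of 150 recorded
    for tumors that never progress.
    """

    protocol: Protocol = Protocol.DAILY
    rx_on: float = 50.0
    rx_off: float = 20.0
    tox_on: float = 1.0
    tox_off: float = 2.0
    dose: float = 1.0
    decision_interval: float = 1.0
    failure_size: float = 75.0
    horizon: float = 100.0
    ttp_sentinel: float = 150.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "protocol", Protocol.parse(self.protocol))
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose}")
        for name in ("decision_interval", "failure_size", "horizon"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.protocol.uses_tumor and not self.rx_on > self.rx_off:
            raise ValueError(
                f"rx_on must exceed rx_off (got rx_on={self.rx_on}, rx_off={self.rx_off})"
            )
        if self.protocol.uses_toxicity and not self.tox_off > self.tox_on:
            raise ValueError(
                f"tox_off must exceed tox_on (got tox_off={self.tox_off}, tox_on={self.tox_on})"
            )
        if self.ttp_sentinel <= self.horizon:
            raise ValueError("ttp_sentinel must exceed the horizon")

    def replace(self, **changes) -> "ProtocolSpec":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = self.protocol.value
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "ProtocolSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown protocol spec fields: {sorted(unknown)}")
        return cls(**mapping)


@dataclass(frozen=True)
class TreatmentStatus:
    """Hysteresis memory carried between decision times.

    Initialized to ``treating=True``: therapy begins at the first
    decision time (t = 0) unless the rule immediately pauses it.
    """

    treating: bool = True


def decide(
    spec: ProtocolSpec,
    status: TreatmentStatus,
    tumor_size: float,
    toxicity: float,
) -> TreatmentStatus:
    """Evaluate one treatment decision.

    Pure function of its arguments: the only state is the incoming
    ``status``.  Pause conditions are OR-ed and resume conditions
    AND-ed, so in the combined protocol toxicity overrides the
    tumor-size rule.  With both feedbacks inactive (``DAILY``) the
    pause condition is vacuously false and the resume condition
    vacuously true, so the rule always treats.
    """
    if not isinstance(spec.protocol, Protocol):  # pragma: no cover - guarded in spec
        raise ValueError(f"unknown protocol {spec.protocol!r}")
    if not (math.isfinite(tumor_size) and tumor_size >= 0):
        raise ValueError(f"tumor_size must be finite and non-negative, got {tumor_size}")
    if not (toxicity >= 0):
        raise ValueError(f"toxicity must be non-negative, got {toxicity}")

    p = spec.protocol
    pause = (p.uses_toxicity and toxicity > spec.tox_off) or (
        p.uses_tumor and tumor_size < spec.rx_off
    )
    resume = ((not p.uses_toxicity) or toxicity < spec.tox_on) and (
        (not p.uses_tumor) or tumor_size > spec.rx_on
    )
    if status.treating:
        return TreatmentStatus(treating=not pause)
    return TreatmentStatus(treating=resume)
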