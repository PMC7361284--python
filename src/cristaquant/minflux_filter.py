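"""Post-hoc quality filter for MINFLUX localization events.

Each MINFLUX localization carries five quality scalars.  An event is
retained only if all five criteria hold, with the published boundary
semantics kept verbatim:

* ``p0 < 0.11`` and ``r_relative < 32 nm`` — rejects false-positive
  localizations from background reactions or emission far outside the
  MINFLUX region;
* ``count_rate <= 100 kHz`` — rates strictly above 100 kHz indicate
  groups of simultaneously active molecules and are discarded;
* ``photons > 1000`` and ``sbr > 0.6`` — selects events with enough
  signal for high localization precision.

All failing criteria of a removed event are recorded (no
short-circuiting), which enables per-criterion QC summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "REASONS",
    "MinfluxEvent",
    "FilterParams",
    "FilterReport",
    "failing_reasons",
    "filter_events",
]

#: Reason codes, one per criterion, plus MALFORMED for non-finite fields.
REASONS = ("P0", "R_RELATIVE", "RATE", "PHOTONS", "SBR")


@dataclass(frozen=True)
class MinfluxEvent:
    """One localization event with its quality scalars."""

    x_nm: float
    y_nm: float
    z_nm: float
    photons: float
    count_rate_khz: float
    p0: float
    r_relative_nm: float
    sbr: float


@dataclass(frozen=True)
class FilterParams:
    """Filter thresholds; defaults are the published values."""

    p0_max: float = 0.11
    r_relative_max_nm: float = 32.0
    count_rate_max_khz: float = 100.0
    photons_min: float = 1000.0
    sbr_min: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "p0_max",
            "r_relative_max_nm",
            "count_rate_max_khz",
            "photons_min",
            "sbr_min",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass
class FilterReport:
    """Partition of the input events into kept and removed.

    ``removed`` pairs each rejected event with all of its reason
    codes; ``counts`` tallies reasons over the removed set (one event
    may contribute to several reasons).
    """

    kept: list[MinfluxEvent] = field(default_factory=list)
    removed: list[tuple[MinfluxEvent, tuple[str, ...]]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)


def failing_reasons(event: MinfluxEvent, params: FilterParams) -> tuple[str, ...]:
    """All reason codes the event fails; empty tuple means kept.

    Non-finite quality fields fail their criterion and add a MALFORMED
    flag; non-finite positions alone also flag MALFORMED, so malformed
    rows are never silently dropped nor silently kept.
    """
    reasons: list[str] = []
    malformed = False

    checks = (
        ("P0", event.p0, lambda v: v < params.p0_max),
        ("R_RELATIVE", event.r_relative_nm, lambda v: v < params.r_relative_max_nm),
        ("RATE", event.count_rate_khz, lambda v: v <= params.count_rate_max_khz),
        ("PHOTONS", event.photons, lambda v: v > params.photons_min),
        ("SBR", event.sbr, lambda v: v > params.sbr_min),
    )
    for code, value, passes in checks:
        if not math.isfinite(value):
            reasons.append(code)
            malformed = True
        elif not passes(value):
            reasons.append(code)
    if not all(math.isfinite(v) for v in (event.x_nm, event.y_nm, event.z_nm)):
        malformed = True
    if malformed:
        reasons.append("MALFORMED")
    return tuple(reasons)


def filter_events(
    events: list[MinfluxEvent], params: FilterParams | None = None
) -> FilterReport:
    """Partition events into kept and removed per the five criteria."""
    params = params or FilterParams()
    report = FilterReport(counts={code: 0 for code in (*REASONS, "MALFORMED")})
    for event in events:
        reasons = failing_reasons(event, params)
        if reasons:
            report.removed.append((event, reasons))
            for code in reasons:
                report.counts[code] += 1
        else:
            report.kept.append(event)
    return report
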