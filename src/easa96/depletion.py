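"""Group summaries and probe-depletion quantities from a plate reading.

The assay quantifies how much of a probe molecule a test chemical (TC)
consumed, relative to the signal window between the negative controls (NC,
probe in solvent) and the solvent-system blanks:

* control wells:  pct = (1 - (value - blank_mean) / (NC_mean - blank_mean)) * 100
* TC:             pct = (1 - (TC_mean - TCblank_mean) / (NC_mean - blank_mean)) * 100
* absolute:       D   = (NC_mean - blank_mean) - (TC_mean - TCblank_mean)

so that pct = 100 * D / (NC_mean - blank_mean) identically.  The TC blank
wells (chemical without probe) subtract whatever absorbance or fluorescence
the chemical itself contributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import GroupEmptyError, SignalWindowError
from .layout import PlateLayout, RoleKind, WellCoord
from .plate_io import PlateReading


@dataclass
class GroupSummary:
    """Mean / sample SD (n-1 denominator) / count of included wells."""

    mean: float
    sd: Optional[float]  # undefined (None) when n < 2
    n: int
    values: tuple[float, ...] = ()  # retained raw values for Bayesian analysis

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "GroupSummary":
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise GroupEmptyError("cannot summarize an empty group")
        sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
        return cls(mean=float(arr.mean()), sd=sd, n=int(arr.size), values=tuple(arr))


@dataclass
class DepletionEstimate:
    """Depletion of a TC with, optionally, the attached inference results."""

    depletion_abs: float  # signal units
    pct_depletion: float  # percent of the NC - blank window
    T: Optional[float] = None
    df: Optional[float] = None
    p_value: Optional[float] = None
    ci_low: Optional[float] = None  # percent scale
    ci_high: Optional[float] = None
    method: Optional[str] = None  # frequentist / bayesian / ksd


def summarize_groups(
    reading: PlateReading,
    layout: PlateLayout,
    excluded: frozenset | set = frozenset(),
) -> dict:
    """Per-group well summaries, honouring QC exclusions.

    Returns a map with keys ``"blank"``, ``"nc"``, ``("pc", level)`` for the
    seven dilution levels, and ``("tc", slot)`` / ``("tc_blank", slot)`` for
    each occupied chemical slot.  Raises :class:`GroupEmptyError` when an
    exclusion empties a group and :class:`SignalWindowError` when the plate
    has no dynamic range (NC mean <= blank mean).
    """
    excluded = {WellCoord.parse(w) if isinstance(w, str) else w for w in excluded}

    def collect(kind: RoleKind, **sel) -> list[float]:
        return [
            reading.value(c)
            for c in layout.wells_for_role(kind, **sel)
            if c not in excluded
        ]

    groups: dict = {}

    def summarize(key, values, label):
        if not values:
            raise GroupEmptyError(f"all wells of group {label} were excluded")
        groups[key] = GroupSummary.from_values(values)

    summarize("blank", collect(RoleKind.BLANK_SS), "blank")
    summarize("nc", collect(RoleKind.NEG_CONTROL), "NC")
    for level in range(1, 8):
        summarize(("pc", level), collect(RoleKind.PC, pc_level=level), f"PC level {level}")
    for slot in layout.occupied_slots():
        name = layout.slot_name(slot)
        summarize(("tc", slot), collect(RoleKind.TC_PROBE, slot=slot), f"TC {name!r}")
        summarize(
            ("tc_blank", slot), collect(RoleKind.TC_BLANK, slot=slot), f"TC blank {name!r}"
        )

    if groups["nc"].mean <= groups["blank"].mean:
        raise SignalWindowError(
            f"no signal window: NC mean {groups['nc'].mean:.4g} <= "
            f"blank mean {groups['blank'].mean:.4g}"
        )
    return groups


def signal_window(groups: Mapping) -> float:
    """NC mean minus blank mean; the denominator of every percentage."""
    window = groups["nc"].mean - groups["blank"].mean
    if window <= 0:
        raise SignalWindowError("NC mean <= blank mean")
    return window


def control_pct_depletion(value: float, nc_mean: float, blank_mean: float) -> float:
    """Percent depletion of a single control (NC or PC) well."""
    if nc_mean <= blank_mean:
        raise SignalWindowError("NC mean <= blank mean")
    return (1.0 - (value - blank_mean) / (nc_mean - blank_mean)) * 100.0


def nc_pct_depletion_sd(groups: Mapping) -> float:
    """Sample SD of the per-well percent depletion over the NC wells.

    This is the noise scale the k x SD classification rule compares against.
    """
    nc = groups["nc"]
    window = signal_window(groups)
    pcts = [
        control_pct_depletion(v, groups["nc"].mean, groups["blank"].mean)
        for v in nc.values
    ]
    return float(np.std(pcts, ddof=1))


def tc_depletion(groups: Mapping, slot: int) -> DepletionEstimate:
    """Absolute and percent depletion for one chemical slot."""
    window = signal_window(groups)
    tc = groups[("tc", slot)]
    tcb = groups[("tc_blank", slot)]
    depletion_abs = window - (tc.mean - tcb.mean)
    pct = 100.0 * depletion_abs / window
    return DepletionEstimate(depletion_abs=depletion_abs, pct_depletion=pct)
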