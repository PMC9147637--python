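"""In-process quality controls: bubble test, interference, pipetting, charts.

Each plate carries its own controls.  A 680 nm read (outside the absorbance
spectrum of both probes) detects air bubbles; wells over the threshold are
excluded before any statistic is computed.  The TC-blank wells quantify
chemical self-absorbance/fluorescence (interference) — an advisory flag,
or a not-available verdict when the signal saturates the instrument.  The
negative-control wells of column 2 (one multichannel stroke) and row A
(one well per stroke) measure within- and between-stroke pipetting
variability and any systematic column trend.  Across runs, four parameters
(blank mean, NC mean, NC CV, positive-control IC50) are control-charted at
mean +/- 3 SD over previously accepted runs; a violation rejects the plate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats as sps

from .errors import QCIncompleteError
from .layout import PlateLayout, RoleKind, WellCoord
from .plate_io import BUBBLE_680, AssayModality, PlateReading


@dataclass
class QCSpec:
    """Acceptance thresholds for the in-process controls."""

    bubble_abs_threshold: float = 0.081  # AU at 680 nm
    bubble_fluor_threshold: float = 5300.0  # instrument-scale units
    interference_k: float = 3.0  # multiplier on blank SD
    trend_alpha: float = 0.05  # NC column-trend significance
    chart_k: float = 3.0  # control-chart multiplier
    chart_min_history: int = 5  # runs before charting activates
    neg_depletion_anomaly_pct: float = -20.0
    dynamic_range_max: dict = field(
        default_factory=lambda: {
            AssayModality.NBT_ABS: 4.0,
            AssayModality.PDA_ABS: 4.0,
            AssayModality.PDA_FLUOR: 1e5,
        }
    )


@dataclass
class InterferenceFlag:
    flagged: bool
    magnitude: float  # TCblank mean minus blank mean, signal units
    assay_na: bool  # signal outside the instrument's dynamic range


@dataclass
class QCReport:
    excluded_wells: dict = field(default_factory=dict)  # WellCoord -> reason
    interference: dict = field(default_factory=dict)  # slot -> InterferenceFlag
    within_step_cv: Optional[float] = None  # percent
    between_step_cv: Optional[float] = None  # percent
    trend_slope: Optional[float] = None
    trend_slope_p: Optional[float] = None
    trend_warning: bool = False
    plate_outlier: bool = False
    outlier_parameters: list = field(default_factory=list)
    notes: list = field(default_factory=list)


def bubble_test(
    reading680: PlateReading,
    layout: PlateLayout,
    spec: QCSpec,
    modality: AssayModality,
) -> set[WellCoord]:
    """Wells whose 680 nm signal exceeds the modality's bubble threshold."""
    if reading680 is None:
        raise QCIncompleteError("680 nm bubble read is missing; plate cannot be accepted")
    if reading680.channel != BUBBLE_680:
        raise QCIncompleteError(f"expected a {BUBBLE_680} read, got {reading680.channel}")
    threshold = (
        spec.bubble_fluor_threshold
        if modality.is_fluorescence
        else spec.bubble_abs_threshold
    )
    return {
        coord
        for coord, _role in layout.wells()
        if reading680.value(coord) > threshold
    }


def interference_check(
    groups: Mapping, layout: PlateLayout, spec: QCSpec, modality: AssayModality
) -> dict[int, InterferenceFlag]:
    """Per-slot chemical interference relative to the blank wells.

    Flagged (advisory) when |TCblank mean - blank mean| exceeds k x blank SD;
    a TC-blank mean beyond the instrument ceiling makes the whole read-out
    not available for that chemical.
    """
    blank = groups["blank"]
    s_blank = blank.sd if blank.sd is not None else 0.0
    ceiling = spec.dynamic_range_max[modality]
    out = {}
    for slot in layout.occupied_slots():
        tcb = groups[("tc_blank", slot)]
        magnitude = tcb.mean - blank.mean
        out[slot] = InterferenceFlag(
            flagged=abs(magnitude) > spec.interference_k * s_blank,
            magnitude=magnitude,
            assay_na=tcb.mean > ceiling,
        )
    return out


def pipetting_qc(
    reading: PlateReading, layout: PlateLayout, spec: QCSpec
) -> tuple[float, float, float, float]:
    """Within-stroke CV, between-stroke CV, and the column-trend slope test.

    Returns (within_cv_pct, between_cv_pct, slope, slope_p).  Within uses
    the column-2 NC wells (filled in one multichannel stroke); between uses
    the row-A NC wells of columns 2-9 (one well per stroke); the trend is an
    ordinary least-squares regression of row-A NC value on column index.
    """
    col2 = [
        reading.value(c)
        for c in layout.wells_for_role(RoleKind.NEG_CONTROL)
        if c.col == 2
    ]
    row_a = [
        (c.col, reading.value(c))
        for c in layout.wells_for_role(RoleKind.NEG_CONTROL)
        if c.row == "A"
    ]
    if len(row_a) < 3:
        raise QCIncompleteError("fewer than 3 row-A NC wells; trend regression impossible")
    within_cv = 100.0 * float(np.std(col2, ddof=1) / np.mean(col2))
    vals = np.array([v for _, v in row_a])
    cols = np.array([c for c, _ in row_a], dtype=float)
    between_cv = 100.0 * float(np.std(vals, ddof=1) / vals.mean())
    if np.ptp(vals) == 0.0:  # constant values: slope 0, no evidence of trend
        return within_cv, between_cv, 0.0, 1.0
    fit = sps.linregress(cols, vals)
    return within_cv, between_cv, float(fit.slope), float(fit.pvalue)


# ---------------------------------------------------------------------------
# cross-run control charting

CHART_PARAMETERS = ("ss_mean", "nc_mean", "nc_cv", "pc_ic50")


@dataclass
class ControlChartState:
    """Expanding-window history of the four charted run parameters.

    Limits are mean +/- chart_k x SD of previously *accepted* runs and are
    only enforced once the history holds ``chart_min_history`` runs.
    A missing parameter (e.g. IC50 not estimable) is skipped, not charted.
    """

    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in CHART_PARAMETERS:
            self.history.setdefault(p, [])

    def limits(self, spec: QCSpec) -> dict:
        out = {}
        for p, vals in self.history.items():
            if len(vals) >= spec.chart_min_history:
                mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
                out[p] = (mean - spec.chart_k * sd, mean + spec.chart_k * sd)
        return out

    def to_json(self) -> str:
        return json.dumps({"history": self.history}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ControlChartState":
        doc = json.loads(text)
        state = cls()
        state.history.update(doc.get("history", {}))
        return state


def update_control_chart(
    state: ControlChartState, run_params: Mapping[str, Optional[float]], spec: QCSpec
) -> tuple[ControlChartState, bool, list[str]]:
    """Chart one run; returns (new state, is_outlier, tripped parameters).

    An outlier run is rejected and *not* appended to the baseline history.
    With insufficient history the run is accepted without limits.
    """
    limits = state.limits(spec)
    tripped = [
        p
        for p, (lo, hi) in limits.items()
        if run_params.get(p) is not None and not (lo <= run_params[p] <= hi)
    ]
    new = ControlChartState({p: list(v) for p, v in state.history.items()})
    if tripped:
        return new, True, tripped
    for p in CHART_PARAMETERS:
        if run_params.get(p) is not None:
            new.history[p].append(float(run_params[p]))
    return new, False, []
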