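"""Synthetic plate-reader output with the statistical structure the
analysis assumes.

Each simulated run produces, per assay read-out, four timepoint matrices
plus one 680 nm bubble-test read, built from Gaussian group models:

    well value = expected signal + N(0, cv x expected signal)

where the expected signal composes the blank level, the probe-derived
window (negative-control mean minus blank mean), the chemical's true
fractional depletion of that window, any chemical interference offset
(added to both TC and TC-blank wells), an optional pipetting column trend
on the probe-containing columns, a probe decay over the read schedule,
and bubble artifacts that spike the 680 nm read and carry over into the
measurement read.  Positive-control wells follow a four-parameter
log-logistic dose-response over the plate's 1:2 serial dilution.

Default signal scales are chosen so the per-well negative-control percent
depletion SD lands near 1.3 % (NBT absorbance), 2.3 % (PDA absorbance)
and 2.5 % (PDA fluorescence) — the noise regime the classification rules
and QC thresholds are designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .layout import ROWS, PlateLayout, RoleKind, build_layout
from .plate_io import BUBBLE_680, TIMEPOINTS_MIN, AssayModality, PlateReading


@dataclass
class PCCurve:
    """True positive-control dose-response (percent depletion vs mmol/L)."""

    top_concentration_mmol: float
    ic50_mmol: float
    hill: float = 1.5
    top_pct: float = 99.0
    bottom_pct: float = 0.0

    def pct_at(self, conc_mmol: float) -> float:
        return self.bottom_pct + (self.top_pct - self.bottom_pct) / (
            1.0 + (self.ic50_mmol / conc_mmol) ** self.hill
        )

    def level_concentration(self, level: int) -> float:
        """Concentration at dilution level 1..7 (1:2 series from the top)."""
        return self.top_concentration_mmol * 2.0 ** (1 - level)


@dataclass
class ModalityParams:
    blank_mean: float
    nc_mean: float
    noise_cv_pct: float  # SD as percent of the expected well signal
    dynamic_range_max: float
    pc_curve: PCCurve
    bubble_baseline: float  # 680 nm background level
    bubble_baseline_sd: float
    bubble_magnitude: float  # 680 nm excess added by a bubble
    bubble_carryover: float  # fraction of the excess leaking into the read


def default_modality_params() -> dict[AssayModality, ModalityParams]:
    return {
        AssayModality.NBT_ABS: ModalityParams(
            blank_mean=0.10, nc_mean=1.10, noise_cv_pct=1.2, dynamic_range_max=4.0,
            pc_curve=PCCurve(top_concentration_mmol=0.6, ic50_mmol=0.075),
            bubble_baseline=0.066, bubble_baseline_sd=0.003,
            bubble_magnitude=0.05, bubble_carryover=1.0,
        ),
        AssayModality.PDA_ABS: ModalityParams(
            blank_mean=0.08, nc_mean=0.60, noise_cv_pct=2.0, dynamic_range_max=4.0,
            pc_curve=PCCurve(top_concentration_mmol=0.2, ic50_mmol=0.025),
            bubble_baseline=0.066, bubble_baseline_sd=0.003,
            bubble_magnitude=0.05, bubble_carryover=1.0,
        ),
        AssayModality.PDA_FLUOR: ModalityParams(
            blank_mean=2000.0, nc_mean=50_000.0, noise_cv_pct=2.4, dynamic_range_max=1e5,
            pc_curve=PCCurve(top_concentration_mmol=0.02, ic50_mmol=0.0025),
            bubble_baseline=4000.0, bubble_baseline_sd=150.0,
            bubble_magnitude=3000.0, bubble_carryover=0.1,
        ),
    }


@dataclass
class ChemicalSpec:
    """Ground truth for one simulated test chemical."""

    name: str
    true_pct_depletion: float = 0.0  # negative values emulate signal gain
    interference_offset: float = 0.0  # signal units added by the chemical itself
    viscous_extra_cv_pct: float = 0.0  # extra pipetting noise on TC wells


@dataclass
class SimulationConfig:
    seed: int = 0
    modalities: dict = field(default_factory=default_modality_params)
    bubble_rate: float = 0.0  # probability per well
    column_trend_pct: float = 0.0  # total NC decline across probe columns 2-9
    time_drift_pct: float = 5.0  # probe decline from the 5 min to the 50 min read
    constant_sd: bool = False  # noise SD from the NC level instead of the well level

    def __post_init__(self) -> None:
        if any(m.noise_cv_pct < 0 for m in self.modalities.values()):
            raise ValueError("noise_cv_pct must be >= 0")


@dataclass
class SimulatedRun:
    layout: PlateLayout
    plates: dict  # (AssayModality, timepoint_min) -> PlateReading
    bubble_reads: dict  # AssayModality -> PlateReading at 680 nm
    truth: dict  # chemical name -> ChemicalSpec


def _expected_matrix(
    cfg: SimulationConfig,
    params: ModalityParams,
    layout: PlateLayout,
    chemicals: Sequence[ChemicalSpec],
    timepoint_min: int,
) -> np.ndarray:
    """Noise-free expected plate at one timepoint (no artifacts)."""
    window = params.nc_mean - params.blank_mean
    # probe decay: reads before 50 min see proportionally more probe
    t_mult = 1.0 + cfg.time_drift_pct / 100.0 * (50 - timepoint_min) / 45.0
    by_slot = {i + 1: chem for i, chem in enumerate(chemicals)}
    out = np.empty((8, 12))
    for coord, role in layout.wells():
        i, j = ROWS.index(coord.row), coord.col - 1
        col_mult = 1.0
        if 2 <= coord.col <= 9:  # probe added column-wise, left to right
            col_mult = 1.0 - cfg.column_trend_pct / 100.0 * (coord.col - 2) / 7.0
        probe = window * t_mult * col_mult
        if role.kind in (RoleKind.BLANK_SS, RoleKind.AUX_SS):
            out[i, j] = params.blank_mean
        elif role.kind is RoleKind.NEG_CONTROL:
            out[i, j] = params.blank_mean + probe
        elif role.kind is RoleKind.PC:
            conc = params.pc_curve.level_concentration(role.pc_level)
            pct = params.pc_curve.pct_at(conc)
            out[i, j] = params.blank_mean + (1.0 - pct / 100.0) * probe
        elif role.kind is RoleKind.TC_PROBE:
            chem = by_slot.get(role.tc_slot)
            if chem is None:
                out[i, j] = params.blank_mean  # unused row: solvent only
            else:
                out[i, j] = (
                    params.blank_mean
                    + chem.interference_offset
                    + (1.0 - chem.true_pct_depletion / 100.0) * probe
                )
        else:  # TC_BLANK: chemical without probe
            chem = by_slot.get(role.tc_slot)
            offset = chem.interference_offset if chem is not None else 0.0
            out[i, j] = params.blank_mean + offset
    return out


def simulate_run(
    cfg: SimulationConfig,
    chemicals: Sequence[ChemicalSpec],
    seed: Optional[int] = None,
    plate_id: str = "sim",
) -> SimulatedRun:
    """One run: 3 read-outs x 4 timepoints plus a 680 nm read per read-out."""
    layout = build_layout([c.name for c in chemicals])
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    by_slot = {i + 1: chem for i, chem in enumerate(chemicals)}
    plates: dict = {}
    bubbles: dict = {}
    for modality, params in cfg.modalities.items():
        # bubbles are a property of how the plate was loaded: one draw per well
        bubble_excess = (
            rng.random((8, 12)) < cfg.bubble_rate
        ) * params.bubble_magnitude
        read680 = (
            params.bubble_baseline
            + rng.normal(0.0, params.bubble_baseline_sd, (8, 12))
            + bubble_excess
        )
        bubbles[modality] = PlateReading(
            f"{plate_id}-{modality.value}", BUBBLE_680, TIMEPOINTS_MIN[0],
            np.clip(read680, 0.0, None), fluorescence_scale=modality.is_fluorescence,
        )
        extra_cv = np.zeros((8, 12))
        for coord, role in layout.wells():
            chem = by_slot.get(role.tc_slot) if role.tc_slot else None
            if chem is not None and role.kind in (RoleKind.TC_PROBE, RoleKind.TC_BLANK):
                extra_cv[ROWS.index(coord.row), coord.col - 1] = chem.viscous_extra_cv_pct
        for t in TIMEPOINTS_MIN:
            expected = _expected_matrix(cfg, params, layout, chemicals, t)
            base = params.nc_mean if cfg.constant_sd else np.abs(expected)
            cv = np.sqrt(params.noise_cv_pct**2 + extra_cv**2) / 100.0
            values = (
                expected
                + rng.normal(0.0, 1.0, (8, 12)) * cv * base
                + bubble_excess * params.bubble_carryover
            )
            floor = 0.0 if modality.is_fluorescence else -0.09
            plates[(modality, t)] = PlateReading(
                f"{plate_id}-{modality.value}", modality, t, np.clip(values, floor, None)
            )
    return SimulatedRun(
        layout=layout,
        plates=plates,
        bubble_reads=bubbles,
        truth={c.name: c for c in chemicals},
    )


def simulate_study(
    cfg: SimulationConfig,
    n_runs: int,
    chemicals: Sequence[ChemicalSpec],
    seed: Optional[int] = None,
) -> list[SimulatedRun]:
    """Independent repeated runs sharing the same ground truth."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    return [
        simulate_run(cfg, chemicals, seed=child, plate_id=f"sim-run{i + 1}")
        for i, child in enumerate(root.spawn(n_runs))
    ]
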