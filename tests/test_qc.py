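import numpy as np
import pytest

from easa96.depletion import summarize_groups
from easa96.errors import QCIncompleteError
from easa96.layout import WellCoord
from easa96.plate_io import BUBBLE_680, AssayModality, PlateReading
from easa96.qc import (
    ControlChartState,
    QCSpec,
    bubble_test,
    interference_check,
    pipetting_qc,
    update_control_chart,
)

from conftest import grid_reading, reading_from

SPEC = QCSpec()


def bubble_reading(values_by_well, baseline=0.066, fluor=False):
    matrix = np.full((8, 12), baseline)
    from easa96.layout import ROWS

    for well, v in values_by_well.items():
        c = WellCoord.parse(well)
        matrix[ROWS.index(c.row), c.col - 1] = v
    return PlateReading("p", BUBBLE_680, 5, matrix, fluorescence_scale=fluor)


def test_bubble_threshold_examples(layout7):
    read = bubble_reading({"B6": 0.085, "C3": 0.079})
    excluded = bubble_test(read, layout7, SPEC, AssayModality.NBT_ABS)
    assert excluded == {WellCoord.parse("B6")}


def test_bubble_clean_plate_excludes_nothing(layout7):
    read = bubble_reading({})
    assert bubble_test(read, layout7, SPEC, AssayModality.NBT_ABS) == set()


def test_bubble_fluorescence_scale(layout7):
    read = bubble_reading({"D4": 6000.0, "D5": 5200.0}, baseline=4000.0, fluor=True)
    excluded = bubble_test(read, layout7, SPEC, AssayModality.PDA_FLUOR)
    assert excluded == {WellCoord.parse("D4")}


def test_bubble_exclusion_monotone_in_threshold(layout7):
    rng = np.random.default_rng(4)
    matrix = np.abs(rng.normal(0.07, 0.01, (8, 12)))
    read = PlateReading("p", BUBBLE_680, 5, matrix)
    previous = None
    for threshold in (0.06, 0.07, 0.081, 0.1):
        spec = QCSpec(bubble_abs_threshold=threshold)
        excluded = bubble_test(read, layout7, spec, AssayModality.NBT_ABS)
        if previous is not None:
            assert excluded <= previous
        previous = excluded


def test_missing_bubble_read_is_qc_incomplete(layout7):
    with pytest.raises(QCIncompleteError):
        bubble_test(None, layout7, SPEC, AssayModality.NBT_ABS)
    wrong = grid_reading(layout7)  # a measurement read, not the 680 nm read
    with pytest.raises(QCIncompleteError):
        bubble_test(wrong, layout7, SPEC, AssayModality.NBT_ABS)


# ---------------------------------------------------------------------------
# interference


def groups_for(layout, tcb_offsets, jitter=0.001):
    reading = grid_reading(
        layout,
        tcb={slot: 0.10 + off for slot, off in tcb_offsets.items()},
        jitter=jitter,
        seed=8,
    )
    return summarize_groups(reading, layout)


def test_interference_flags(layout3):
    groups = groups_for(layout3, {1: 0.0, 2: 0.5})
    flags = interference_check(groups, layout3, SPEC, AssayModality.NBT_ABS)
    assert not flags[1].flagged  # TC blank at the blank level
    assert flags[2].flagged and flags[2].magnitude == pytest.approx(0.5, abs=0.01)
    assert not flags[2].assay_na


def test_interference_dynamic_range_violation(layout3):
    groups = groups_for(layout3, {1: 4.5})  # beyond the absorbance ceiling
    flags = interference_check(groups, layout3, SPEC, AssayModality.NBT_ABS)
    assert flags[1].assay_na


# ---------------------------------------------------------------------------
# pipetting variability


def test_constant_nc_passes_pipetting_qc(layout7):
    reading = grid_reading(layout7)
    within, between, slope, p = pipetting_qc(reading, layout7, SPEC)
    assert within == 0.0 and between == 0.0
    assert slope == 0.0 and p == pytest.approx(1.0)


def test_declining_columns_raise_trend_warning(layout7):
    rng = np.random.default_rng(9)

    def value(coord, role):
        from easa96.layout import RoleKind

        if role.kind is RoleKind.NEG_CONTROL and coord.row == "A":
            return 1.10 - 0.01 * (coord.col - 2) + rng.normal(0, 1e-4)
        return {RoleKind.BLANK_SS: 0.1, RoleKind.AUX_SS: 0.1}.get(role.kind, 1.10)

    reading = reading_from(layout7, value)
    within, between, slope, p = pipetting_qc(reading, layout7, SPEC)
    assert slope < 0
    assert p < 0.05
    assert between > within


# ---------------------------------------------------------------------------
# control charting


def params(nc_cv=1.0, nc_mean=1.1, ss_mean=0.1, ic50=0.07):
    return {"ss_mean": ss_mean, "nc_mean": nc_mean, "nc_cv": nc_cv, "pc_ic50": ic50}


def seeded_state(n_runs=10, spread=0.02):
    state = ControlChartState()
    rng = np.random.default_rng(14)
    for _ in range(n_runs):
        p = params(
            nc_cv=1.0 + rng.normal(0, spread),
            nc_mean=1.1 + rng.normal(0, spread / 10),
            ss_mean=0.1 + rng.normal(0, spread / 10),
            ic50=0.07 + rng.normal(0, spread / 30),
        )
        state, outlier, _ = update_control_chart(state, p, SPEC)
        assert not outlier
    return state


def test_identical_run_accepted():
    state = ControlChartState({p: [1.0] * 10 for p in ("ss_mean", "nc_mean", "nc_cv", "pc_ic50")})
    run = {"ss_mean": 1.0, "nc_mean": 1.0, "nc_cv": 1.0, "pc_ic50": 1.0}
    _, outlier, tripped = update_control_chart(state, run, SPEC)
    assert not outlier and tripped == []


def test_four_sd_nc_cv_rejects_plate():
    state = seeded_state()
    history = np.array(state.history["nc_cv"])
    bad = params(nc_cv=history.mean() + 4 * history.std(ddof=1))
    new_state, outlier, tripped = update_control_chart(state, bad, SPEC)
    assert outlier and tripped == ["nc_cv"]
    # rejected runs do not contaminate the baseline
    assert new_state.history["nc_cv"] == state.history["nc_cv"]


def test_short_history_is_not_charted():
    state = ControlChartState()
    for _ in range(2):
        state, outlier, _ = update_control_chart(state, params(), SPEC)
        assert not outlier
    assert state.limits(SPEC) == {}  # charting inactive below the minimum history
    wild = params(nc_cv=50.0)
    _, outlier, _ = update_control_chart(state, wild, SPEC)
    assert not outlier


def test_missing_ic50_is_skipped_not_tripped():
    state = seeded_state()
    run = params()
    run["pc_ic50"] = None
    _, outlier, _ = update_control_chart(state, run, SPEC)
    assert not outlier


def test_chart_state_json_round_trip():
    state = seeded_state(6)
    restored = ControlChartState.from_json(state.to_json())
    assert restored.history == state.history


def test_false_rejection_rate_under_clean_conditions():
    """With Gaussian run parameters, 3-SD charting rejects < 5 % per check."""
    rng = np.random.default_rng(15)
    rejections = trials = 0
    for rep in range(25):
        state = seeded_state(n_runs=8)
        for _ in range(8):
            p = params(nc_cv=1.0 + rng.normal(0, 0.02))
            state, outlier, _ = update_control_chart(state, p, SPEC)
            trials += 1
            rejections += outlier
    assert rejections / trials < 0.05
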