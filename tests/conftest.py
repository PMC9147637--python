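import numpy as np
import pytest

from easa96.layout import ROWS, PlateLayout, RoleKind, build_layout
from easa96.plate_io import AssayModality, PlateReading


@pytest.fixture
def layout7() -> PlateLayout:
    return build_layout([f"chem{i}" for i in range(1, 8)])


@pytest.fixture
def layout3() -> PlateLayout:
    return build_layout(["aldehyde", "thiuram", "glycol"])


def reading_from(layout, value_fn, channel=AssayModality.NBT_ABS, timepoint=50, **kw):
    """Build a PlateReading by evaluating value_fn(coord, role) per well."""
    matrix = np.empty((8, 12))
    for coord, role in layout.wells():
        matrix[ROWS.index(coord.row), coord.col - 1] = value_fn(coord, role)
    return PlateReading("test", channel, timepoint, matrix, **kw)


def grid_reading(
    layout,
    blank=0.10,
    nc=1.10,
    tc=None,
    tcb=None,
    pc=None,
    jitter=0.0,
    seed=0,
    channel=AssayModality.NBT_ABS,
):
    """Deterministic plate: group-level values with optional Gaussian jitter.

    ``tc`` / ``tcb`` map slot -> value (defaults: no depletion, no
    interference); ``pc`` maps dilution level -> value (default: NC level).
    """
    tc, tcb, pc = tc or {}, tcb or {}, pc or {}
    rng = np.random.default_rng(seed)

    def value(coord, role):
        base = {
            RoleKind.BLANK_SS: blank,
            RoleKind.AUX_SS: blank,
            RoleKind.NEG_CONTROL: nc,
        }.get(role.kind)
        if base is None:
            if role.kind is RoleKind.PC:
                base = pc.get(role.pc_level, nc)
            elif role.kind is RoleKind.TC_PROBE:
                base = tc.get(role.tc_slot, nc)
            else:
                base = tcb.get(role.tc_slot, blank)
        return base + (rng.normal(0.0, jitter) if jitter else 0.0)

    return reading_from(layout, value, channel=channel)
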