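"""Fixed 96-well plate design for the EASA assay and well-role lookup.

The plate is organised so that every run carries its own in-process
controls alongside up to seven test chemicals (TCs):

* column 1, rows A-H           : solvent-system blanks (plate blank), 8 wells
* column 2, rows A-H and
  row A, columns 3-9           : negative controls (probe in solvent), 15 wells
* columns 3-5, rows B-H        : positive-control 1:2 serial dilution,
                                 7 levels (row B = level 1, top concentration)
                                 x 3 replicates, 21 wells
* columns 6-9, rows B-H        : TC + probe wells, one chemical per row,
                                 4 replicates, 28 wells
* columns 10-12, rows B-H      : TC blanks (chemical, no probe), 3 replicates,
                                 21 wells
* row A, columns 10-12         : auxiliary solvent-system wells, excluded from
                                 all statistics, 3 wells

Unused chemical rows (fewer than 7 TCs loaded) keep their TC_PROBE/TC_BLANK
roles with no slot name bound and are skipped by the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple, Optional, Sequence

from .errors import CapacityError, ValidationError

ROWS = "ABCDEFGH"
N_COLS = 12

#: expected replicate counts at full occupancy
GROUP_SIZES = {"blank": 8, "nc": 15, "pc": 21, "tc_probe": 28, "tc_blank": 21, "aux_ss": 3}


class WellCoord(NamedTuple):
    """A plate coordinate, e.g. ``WellCoord('B', 6)`` printed as ``B6``."""

    row: str
    col: int

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.row}{self.col}"

    @classmethod
    def parse(cls, text: str) -> "WellCoord":
        row, col = text[0].upper(), int(text[1:])
        if row not in ROWS or not (1 <= col <= N_COLS):
            raise ValidationError(f"not a 96-well coordinate: {text!r}")
        return cls(row, col)


class RoleKind(str, Enum):
    BLANK_SS = "blank_ss"
    NEG_CONTROL = "neg_control"
    PC = "pc"
    TC_PROBE = "tc_probe"
    TC_BLANK = "tc_blank"
    AUX_SS = "aux_ss"


@dataclass(frozen=True)
class WellRole:
    kind: RoleKind
    pc_level: Optional[int] = None  # 1 (top concentration, row B) .. 7 (row H)
    pc_rep: Optional[int] = None  # 1..3 (columns 3..5)
    tc_slot: Optional[int] = None  # 1..7 (rows B..H)
    tc_rep: Optional[int] = None  # 1..4 probe wells, 1..3 blank wells


def _role_for(coord: WellCoord) -> WellRole:
    row_i = ROWS.index(coord.row)
    col = coord.col
    if col == 1:
        return WellRole(RoleKind.BLANK_SS)
    if col == 2 or (coord.row == "A" and 3 <= col <= 9):
        return WellRole(RoleKind.NEG_CONTROL)
    if coord.row == "A":  # columns 10-12
        return WellRole(RoleKind.AUX_SS)
    if 3 <= col <= 5:
        return WellRole(RoleKind.PC, pc_level=row_i, pc_rep=col - 2)
    if 6 <= col <= 9:
        return WellRole(RoleKind.TC_PROBE, tc_slot=row_i, tc_rep=col - 5)
    return WellRole(RoleKind.TC_BLANK, tc_slot=row_i, tc_rep=col - 9)


class PlateLayout:
    """Immutable well -> role map plus the chemical names bound to rows B-H."""

    MAX_SLOTS = 7

    def __init__(self, tc_slot_names: Sequence[str] = ()):
        if len(tc_slot_names) > self.MAX_SLOTS:
            raise CapacityError(
                f"plate holds at most {self.MAX_SLOTS} test chemicals, got {len(tc_slot_names)}"
            )
        self.tc_slot_names: tuple[str, ...] = tuple(tc_slot_names)
        self._roles = {
            WellCoord(r, c): _role_for(WellCoord(r, c)) for r in ROWS for c in range(1, N_COLS + 1)
        }

    # -- lookup ------------------------------------------------------------

    def role(self, coord: WellCoord | str) -> WellRole:
        if isinstance(coord, str):
            coord = WellCoord.parse(coord)
        return self._roles[coord]

    def wells(self) -> Iterable[tuple[WellCoord, WellRole]]:
        return self._roles.items()

    def wells_for_role(
        self, kind: RoleKind, slot: Optional[int] = None, pc_level: Optional[int] = None
    ) -> list[WellCoord]:
        """Row-major list of wells of a kind, optionally restricted to one
        TC slot or one PC dilution level."""
        if not isinstance(kind, RoleKind):
            raise ValidationError(f"unknown well role kind: {kind!r}")
        if slot is not None and kind not in (RoleKind.TC_PROBE, RoleKind.TC_BLANK):
            raise ValidationError("slot filter applies only to TC roles")
        out = []
        for coord, role in self._roles.items():
            if role.kind is not kind:
                continue
            if slot is not None and role.tc_slot != slot:
                continue
            if pc_level is not None and role.pc_level != pc_level:
                continue
            out.append(coord)
        out.sort(key=lambda c: (ROWS.index(c.row), c.col))
        return out

    def slot_name(self, slot: int) -> Optional[str]:
        """Chemical bound to a TC slot, or None for an unused row."""
        if not 1 <= slot <= self.MAX_SLOTS:
            raise ValidationError(f"TC slot out of range: {slot}")
        return self.tc_slot_names[slot - 1] if slot <= len(self.tc_slot_names) else None

    def occupied_slots(self) -> list[int]:
        return list(range(1, len(self.tc_slot_names) + 1))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "tc_slot_names": list(self.tc_slot_names),
            "wells": {
                str(c): {k: v for k, v in vars(r).items() if v is not None} | {"kind": r.kind.value}
                for c, r in self._roles.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlateLayout":
        doc = json.loads(text)
        layout = cls(doc["tc_slot_names"])
        # the geometry is fixed; verify the document agrees with it
        for coord_s, role_d in doc["wells"].items():
            if layout.role(coord_s).kind.value != role_d["kind"]:
                raise ValidationError(f"layout document disagrees with plate design at {coord_s}")
        return layout


def build_layout(tc_slot_names: Sequence[str] = ()) -> PlateLayout:
    """Build the fixed plate layout with up to 7 chemicals bound to rows B-H."""
    return PlateLayout(tc_slot_names)
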