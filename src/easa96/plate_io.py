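"""Reading and writing plate matrices, reference tables and result sets.

Plate matrices are plain 8x12 CSV grids as exported by common plate readers:
comma separated, period decimal, with an optional ``1..12`` header row and
optional ``A..H`` row labels (both auto-detected).  The reader is tolerant
about labels and strict about the numeric block.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .layout import N_COLS, ROWS

TIMEPOINTS_MIN = (5, 20, 35, 50)  # nominal read schedule
ANALYSIS_TIMEPOINT_MIN = 50  # read used for depletion statistics

BUBBLE_680 = "bubble_680"  # 680 nm bubble-test channel marker


class AssayModality(str, Enum):
    """The three assay read-outs that together form one EASA run."""

    NBT_ABS = "nbt_abs"  # 4-nitrobenzenethiol probe, absorbance 412 nm
    PDA_ABS = "pda_abs"  # pyridoxylamine probe, absorbance 324 nm
    PDA_FLUOR = "pda_fluor"  # pyridoxylamine probe, ex 324 nm / em 398 nm

    @property
    def is_fluorescence(self) -> bool:
        return self is AssayModality.PDA_FLUOR

    @property
    def wavelengths_nm(self) -> dict:
        return {
            AssayModality.NBT_ABS: {"measure": 412},
            AssayModality.PDA_ABS: {"measure": 324},
            AssayModality.PDA_FLUOR: {"excitation": 324, "emission": 398},
        }[self]

    @property
    def signal_unit(self) -> str:
        return "RFU" if self.is_fluorescence else "AU"


@dataclass
class PlateReading:
    """One 8x12 instrument matrix for a plate / channel / timepoint."""

    plate_id: str
    channel: AssayModality | str  # an AssayModality or BUBBLE_680
    timepoint_min: int
    values: np.ndarray
    fluorescence_scale: bool = False  # for BUBBLE_680 reads on the fluor assay

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (8, 12):
            raise ValidationError(f"plate matrix must be 8x12, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("plate matrix contains NaN or infinite values")
        fluor = (
            self.channel is AssayModality.PDA_FLUOR
            if isinstance(self.channel, AssayModality)
            else self.fluorescence_scale
        )
        floor = 0.0 if fluor else -0.1  # small negatives tolerated for baseline
        if np.any(self.values < floor):
            raise ValidationError(f"signal below instrument floor {floor}")

    def value(self, coord) -> float:
        from .layout import WellCoord

        if isinstance(coord, str):
            coord = WellCoord.parse(coord)
        return float(self.values[ROWS.index(coord.row), coord.col - 1])


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_plate_csv(
    path,
    plate_id: str,
    channel: AssayModality | str,
    timepoint_min: int,
    fluorescence_scale: bool = False,
) -> PlateReading:
    """Parse an 8x12 plate-reader CSV grid (header/labels auto-detected)."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(cell.strip() for cell in r)]
    # drop a "1..12" header row if present
    if rows and not _looks_numeric(rows[0][0]) or (rows and rows[0][:3] == ["1", "2", "3"]):
        first = [c.strip() for c in rows[0]]
        if first and (first[0] in ("", "<>") or first[-N_COLS:] == [str(i) for i in range(1, 13)]):
            rows = rows[1:]
    if len(rows) != 8:
        raise FormatError(f"{path}: expected 8 data rows, found {len(rows)}")
    matrix = np.empty((8, 12))
    for i, row in enumerate(rows):
        cells = [c.strip() for c in row]
        if cells and cells[0].upper() in tuple(ROWS):  # row label column
            cells = cells[1:]
        if len(cells) != N_COLS:
            raise FormatError(
                f"{path}: row {ROWS[i]} has {len(cells)} columns, expected {N_COLS}"
            )
        for j, cell in enumerate(cells):
            try:
                matrix[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: cannot parse value {cell!r} at well {ROWS[i]}{j + 1}"
                ) from None
    return PlateReading(plate_id, channel, timepoint_min, matrix, fluorescence_scale)


def write_plate_csv(reading: PlateReading, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + [str(i) for i in range(1, N_COLS + 1)])
        for i, row_label in enumerate(ROWS):
            writer.writerow([row_label] + [repr(float(v)) for v in reading.values[i]])


# ---------------------------------------------------------------------------
# chemical reference table


_CALL_TOKENS = {
    "binder": "binder",
    "nonbinder": "nonbinder",
    "non-binder": "nonbinder",
    "inconclusive": "inconclusive",
    "sensitizer": "sensitizer",
    "sensitiser": "sensitizer",
    "nonsensitizer": "nonsensitizer",
    "non-sensitizer": "nonsensitizer",
    "nonsensitiser": "nonsensitizer",
    "positive": "positive",
    "negative": "negative",
    "llna": "llna",
    "gpmt": "gpmt",
}


def _norm_call(raw, column: str, allowed: set[str]) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    token = _CALL_TOKENS.get(str(raw).strip().lower())
    if token is None or token not in allowed:
        raise ValidationError(
            f"unknown {column} token {raw!r}; accepted: {sorted(allowed)} or blank"
        )
    return token


@dataclass
class ReferenceRecord:
    """One row of the transcribed test-chemical reference table."""

    chemical: str
    cas: str
    dpra_call: Optional[str] = None  # binder / nonbinder / inconclusive
    invivo_call: Optional[str] = None  # sensitizer / nonsensitizer
    invivo_assay: Optional[str] = None  # llna / gpmt
    ec3: Optional[str] = None  # LLNA EC3, free text (values and ranges); metadata only
    ke2_call: Optional[str] = None  # KeratinoSens positive / negative
    ke3_call: Optional[str] = None  # h-CLAT positive / negative
    easa_call: Optional[str] = None  # overall printed EASA determination


def read_reference_table(path) -> list[ReferenceRecord]:
    """Read the chemical reference CSV (blank cells become missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("chemical", "cas"):
        if required not in df.columns:
            raise FormatError(f"reference table lacks required column {required!r}")
    records = []
    for _, row in df.iterrows():
        get = lambda col: row[col] if col in df.columns else None
        rec = ReferenceRecord(
            chemical=row["chemical"].strip(),
            cas=row["cas"].strip(),
            dpra_call=_norm_call(get("dpra_call"), "dpra_call", {"binder", "nonbinder", "inconclusive"}),
            invivo_call=_norm_call(get("invivo_call"), "invivo_call", {"sensitizer", "nonsensitizer"}),
            invivo_assay=_norm_call(get("invivo_assay"), "invivo_assay", {"llna", "gpmt"}),
            ec3=(get("ec3") or "").strip() or None,
            ke2_call=_norm_call(get("ke2_call"), "ke2_call", {"positive", "negative"}),
            ke3_call=_norm_call(get("ke3_call"), "ke3_call", {"positive", "negative"}),
            easa_call=_norm_call(get("easa_call"), "easa_call", {"binder", "nonbinder", "inconclusive"}),
        )
        if (rec.invivo_call is None) != (rec.invivo_assay is None):
            raise ValidationError(
                f"{rec.chemical}: in vivo call and assay must be present together"
            )
        records.append(rec)
    return records


def load_bundled_reference() -> list[ReferenceRecord]:
    """The packaged transcription of the published 92-chemical reference table."""
    with resources.as_file(
        resources.files("easa96.data").joinpath("reference_chemicals.csv")
    ) as path:
        return read_reference_table(path)


# ---------------------------------------------------------------------------
# result sets

RESULTS_SCHEMA_VERSION = 1


def _nan_to_none(obj):
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(results: dict, path) -> None:
    """Serialize a run result set to JSON (NaN -> null, lossless round trip)."""
    doc = {"schema_version": RESULTS_SCHEMA_VERSION}
    doc.update(_nan_to_none(results))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, allow_nan=False)


def read_results(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.pop("schema_version", None)
    if version != RESULTS_SCHEMA_VERSION:
        raise ValidationError(f"unsupported results schema version: {version}")
    return doc
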