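"""Defined approaches (2-of-3, KE 3/1) and Cooper concordance statistics.

A defined approach combines key-event assays of the skin-sensitization
adverse outcome pathway — KE1 protein binding (EASA or DPRA), KE2
keratinocyte activation (KeratinoSens), KE3 dendritic-cell activation
(h-CLAT) — into one hazard call via a fixed data-interpretation procedure.
Predictions are scored against reference calls with Cooper statistics:
accuracy, false-positive rate over reference negatives, false-negative
rate over reference positives, each reported as a fraction so every cell
of a concordance table is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import NotEvaluableError, ValidationError
from .plate_io import ReferenceRecord

POSITIVE, NEGATIVE, INCONCLUSIVE = "positive", "negative", "inconclusive"

#: KE1 binder/nonbinder and in vivo sensitizer/nonsensitizer calls mapped
#: onto the positive/negative vocabulary used by the defined approaches.
TO_PN = {
    "binder": POSITIVE,
    "nonbinder": NEGATIVE,
    "sensitizer": POSITIVE,
    "nonsensitizer": NEGATIVE,
    "positive": POSITIVE,
    "negative": NEGATIVE,
    "inconclusive": INCONCLUSIVE,
    None: None,
}


@dataclass
class KEInputs:
    ke1: Optional[str] = None  # positive / negative / None (missing)
    ke2: Optional[str] = None
    ke3: Optional[str] = None


@dataclass
class DAClassification:
    da: str  # "two_of_three" or "ke31"
    result: str  # positive / negative / inconclusive


def _as_pn(value: Optional[str], name: str) -> Optional[str]:
    if value not in (POSITIVE, NEGATIVE, INCONCLUSIVE, None):
        raise ValidationError(f"{name} must be positive/negative/inconclusive or missing")
    return None if value == INCONCLUSIVE else value


def two_of_three(ke: KEInputs) -> DAClassification:
    """Hazard call from two concordant findings among the three key events.

    Inconclusive assay results count as missing.  With no two concordant
    conclusive calls (e.g. one positive, one negative, one missing) the
    defined approach is inconclusive.
    """
    calls = [_as_pn(ke.ke1, "ke1"), _as_pn(ke.ke2, "ke2"), _as_pn(ke.ke3, "ke3")]
    conclusive = [c for c in calls if c is not None]
    if not conclusive:
        raise NotEvaluableError("all three key-event inputs are missing")
    if conclusive.count(POSITIVE) >= 2:
        return DAClassification("two_of_three", POSITIVE)
    if conclusive.count(NEGATIVE) >= 2:
        return DAClassification("two_of_three", NEGATIVE)
    return DAClassification("two_of_three", INCONCLUSIVE)


def ke31(ke1: Optional[str], ke3: Optional[str]) -> DAClassification:
    """Decision tree on KE3 then KE1.

    Positive KE3 -> positive.  Negative KE3 -> KE1's call, or inconclusive
    if KE1 is missing/inconclusive.  Missing KE3 -> inconclusive.
    """
    ke1, ke3 = _as_pn(ke1, "ke1"), _as_pn(ke3, "ke3")
    if ke3 == POSITIVE:
        return DAClassification("ke31", POSITIVE)
    if ke3 == NEGATIVE and ke1 in (POSITIVE, NEGATIVE):
        return DAClassification("ke31", ke1)
    return DAClassification("ke31", INCONCLUSIVE)


# ---------------------------------------------------------------------------


@dataclass
class CooperStats:
    accuracy_pct: float
    accuracy_frac: tuple[int, int]  # (TP + TN, n evaluated)
    fp_rate_pct: Optional[float]
    fp_frac: tuple[int, int]  # (FP, reference negatives)
    fn_rate_pct: Optional[float]
    fn_frac: tuple[int, int]  # (FN, reference positives)
    n_evaluated: int = 0
    n_excluded: int = 0
    excluded: list = field(default_factory=list)


SCOPES = ("llna", "llna+gpmt", "dpra")


def _comparator(rec: ReferenceRecord, scope: str) -> Optional[str]:
    if scope == "dpra":
        return TO_PN[rec.dpra_call] if rec.dpra_call != "inconclusive" else None
    if rec.invivo_call is None:
        return None
    if scope == "llna" and rec.invivo_assay != "llna":
        return None
    return TO_PN[rec.invivo_call]


def cooper_stats(
    predictions: Mapping[str, str],
    references: Sequence[ReferenceRecord],
    scope: str = "llna",
) -> CooperStats:
    """Score positive/negative predictions against a reference comparator.

    ``scope`` selects the comparator: in vivo calls restricted to the
    murine local lymph node assay (``llna``), in vivo calls from either
    LLNA or the guinea pig maximization test (``llna+gpmt``), or the
    reference peptide-reactivity assay head-to-head (``dpra``, with
    DPRA-inconclusive chemicals excluded).  Chemicals with inconclusive or
    missing predictions, or without a comparator call, are excluded and
    counted.
    """
    if scope not in SCOPES:
        raise ValidationError(f"scope must be one of {SCOPES}")
    tp = tn = fp = fn = 0
    excluded = []
    for rec in references:
        ref = _comparator(rec, scope)
        pred_raw = predictions.get(rec.chemical)
        pred = TO_PN.get(pred_raw, pred_raw) if pred_raw is not None else None
        if pred == INCONCLUSIVE:
            pred = None
        if ref is None or pred is None:
            if ref is not None or pred is not None:
                excluded.append(rec.chemical)
            continue
        if ref == POSITIVE:
            tp += pred == POSITIVE
            fn += pred == NEGATIVE
        else:
            tn += pred == NEGATIVE
            fp += pred == POSITIVE
    n = tp + tn + fp + fn
    if n == 0:
        raise NotEvaluableError("no chemical has both a prediction and a comparator call")
    npos, nneg = tp + fn, tn + fp
    return CooperStats(
        accuracy_pct=100.0 * (tp + tn) / n,
        accuracy_frac=(tp + tn, n),
        fp_rate_pct=100.0 * fp / nneg if nneg else None,
        fp_frac=(fp, nneg),
        fn_rate_pct=100.0 * fn / npos if npos else None,
        fn_frac=(fn, npos),
        n_evaluated=n,
        n_excluded=len(excluded),
        excluded=excluded,
    )


def predictions_from_records(
    records: Sequence[ReferenceRecord], column: str = "easa_call"
) -> dict[str, str]:
    """Lift a call column of the reference table into a predictions map."""
    out = {}
    for rec in records:
        call = getattr(rec, column)
        if call is not None:
            out[rec.chemical] = TO_PN[call] if call != "inconclusive" else INCONCLUSIVE
    return out
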