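"""Structural-progression classification and matched case-control design.

A knee is a *structural progressor* over 12 months when its medial
femorotibial cartilage thickness loss (MRI) and its medial minimum joint
space width loss (radiography) both exceed their smallest-detectable-change
(SDC) thresholds — two independent modalities confirming the same medial
progression.  Non-progressors show no loss beyond SDC medially (cartilage
and minJSW) nor laterally.  Everything in between is indeterminate.

Default SDC thresholds (test–retest derived): 102 µm for medial and 92 µm
for lateral femorotibial cartilage thickness loss, 328 µm for medial
minJSW loss.

Progressors are matched 1:1 to non-progressors on exact sex and
Kellgren-Lawrence grade (restricted to KLG 2–3: definite but not end-stage
radiographic OA), with calipers of ±3 cm body height, ±5 kg/m² BMI and ±5
WOMAC pain points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ProgressionError",
    "UnclassifiableRecordError",
    "KneeRecord",
    "SDCThresholds",
    "MatchSpec",
    "MatchResult",
    "compute_sdc",
    "classify_knee",
    "classify_cohort",
    "apply_eligibility",
    "match_pairs",
    "records_from_frame",
]

MM_TO_UM = 1000.0

Classification = Literal["progressor", "non_progressor", "indeterminate"]


class ProgressionError(ValueError):
    pass


class UnclassifiableRecordError(ProgressionError):
    """Follow-up or baseline values needed for classification are missing."""


@dataclass
class KneeRecord:
    """One knee's covariates and longitudinal cartilage/minJSW values.

    Thickness and joint-space values are stored in mm; losses are computed
    in µm when compared against the SDC thresholds.  Follow-up fields may
    be None, in which case the record is unclassifiable.
    """

    knee_id: str
    sex: str  # "M" | "F"
    age_years: float
    height_cm: float
    bmi_kg_m2: float
    womac_pain: float  # 0–20 scale
    klg: int  # Kellgren-Lawrence grade 0–4
    med_jsn: int | None = None
    lat_jsn: int | None = None
    mftc_mm_baseline: float | None = None
    mftc_mm_y1: float | None = None
    lftc_mm_baseline: float | None = None
    lftc_mm_y1: float | None = None
    minjsw_mm_baseline: float | None = None
    minjsw_mm_y1: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ProgressionError(f"sex must be M|F, got {self.sex!r}")
        if not 0 <= self.womac_pain <= 20:
            raise ProgressionError(f"womac_pain must be in [0, 20], got {self.womac_pain}")
        if not 0 <= int(self.klg) <= 4:
            raise ProgressionError(f"klg must be in 0..4, got {self.klg}")
        for name in (
            "mftc_mm_baseline", "mftc_mm_y1", "lftc_mm_baseline",
            "lftc_mm_y1", "minjsw_mm_baseline", "minjsw_mm_y1",
        ):
            v = getattr(self, name)
            if v is not None and not (v > 0 or np.isnan(v)):
                raise ProgressionError(f"{name} must be > 0 when present, got {v}")

    def loss_um(self, structure: str) -> float:
        """Baseline − follow-up change in µm (positive = loss)."""
        base = getattr(self, f"{structure}_mm_baseline")
        y1 = getattr(self, f"{structure}_mm_y1")
        if base is None or y1 is None or np.isnan(base) or np.isnan(y1):
            raise UnclassifiableRecordError(
                f"knee {self.knee_id}: missing {structure} baseline/follow-up"
            )
        return (base - y1) * MM_TO_UM


@dataclass(frozen=True)
class SDCThresholds:
    """Smallest-detectable-change thresholds in µm (all > 0)."""

    mftc_um: float = 102.0
    lftc_um: float = 92.0
    minjsw_um: float = 328.0

    def __post_init__(self) -> None:
        if min(self.mftc_um, self.lftc_um, self.minjsw_um) <= 0:
            raise ProgressionError("SDC thresholds must be > 0")


@dataclass(frozen=True)
class MatchSpec:
    """1:1 matching rules: exact sex and KLG, plus covariate calipers."""

    height_caliper_cm: float = 3.0
    bmi_caliper: float = 5.0
    womac_caliper: float = 5.0

    def __post_init__(self) -> None:
        if min(self.height_caliper_cm, self.bmi_caliper, self.womac_caliper) <= 0:
            raise ProgressionError("calipers must be > 0")

    def eligible(self, case: KneeRecord, control: KneeRecord) -> bool:
        return (
            case.sex == control.sex
            and int(case.klg) == int(control.klg)
            and abs(case.height_cm - control.height_cm) <= self.height_caliper_cm
            and abs(case.bmi_kg_m2 - control.bmi_kg_m2) <= self.bmi_caliper
            and abs(case.womac_pain - control.womac_pain) <= self.womac_caliper
        )

    def distance(self, case: KneeRecord, control: KneeRecord) -> float:
        """Caliper-normalized L1 distance (each term in [0, 1] when eligible)."""
        return (
            abs(case.height_cm - control.height_cm) / self.height_caliper_cm
            + abs(case.bmi_kg_m2 - control.bmi_kg_m2) / self.bmi_caliper
            + abs(case.womac_pain - control.womac_pain) / self.womac_caliper
        )


# ---------------------------------------------------------------------------
# SDC and classification
# ---------------------------------------------------------------------------

def compute_sdc(test_retest_differences: Sequence[float]) -> float:
    """SDC = 1.96 × SD of test–retest change differences (n−1 denominator).

    The input is the list of differences between repeated change
    measurements of the same object; the result is in the input's units.
    """
    d = np.asarray(test_retest_differences, dtype=float)
    if d.size < 2:
        raise ProgressionError("compute_sdc needs at least 2 differences")
    return 1.96 * float(np.std(d, ddof=1))


def classify_knee(
    rec: KneeRecord,
    thr: SDCThresholds = SDCThresholds(),
    strict: bool = True,
) -> Classification:
    """Classify one knee as progressor / non_progressor / indeterminate.

    Progressor: medial cartilage loss AND medial minJSW loss both exceed
    their thresholds.  Non-progressor: medial cartilage, medial minJSW and
    lateral cartilage losses all within thresholds.  ``strict`` controls
    whether "exceeding" is a strict inequality (default); a boundary value
    is then non-progressor-compatible.
    """
    loss_mftc = rec.loss_um("mftc")
    loss_lftc = rec.loss_um("lftc")
    loss_minjsw = rec.loss_um("minjsw")

    def exceeds(loss: float, threshold: float) -> bool:
        return loss > threshold if strict else loss >= threshold

    if exceeds(loss_mftc, thr.mftc_um) and exceeds(loss_minjsw, thr.minjsw_um):
        return "progressor"
    if (
        not exceeds(loss_mftc, thr.mftc_um)
        and not exceeds(loss_minjsw, thr.minjsw_um)
        and not exceeds(loss_lftc, thr.lftc_um)
    ):
        return "non_progressor"
    return "indeterminate"


def classify_cohort(
    records: Iterable[KneeRecord],
    thr: SDCThresholds = SDCThresholds(),
    strict: bool = True,
) -> pd.DataFrame:
    """Classify every record; unclassifiable records get a reason code.

    Returns a frame with columns ``knee_id``, ``class`` and ``reason``
    (empty for classified records).
    """
    rows = []
    for rec in records:
        try:
            cls = classify_knee(rec, thr, strict=strict)
            rows.append({"knee_id": rec.knee_id, "class": cls, "reason": ""})
        except UnclassifiableRecordError as exc:
            rows.append({"knee_id": rec.knee_id, "class": "unclassifiable",
                         "reason": str(exc)})
    return pd.DataFrame(rows, columns=["knee_id", "class", "reason"])


def apply_eligibility(
    records: Sequence[KneeRecord], klg_min: int = 2, klg_max: int = 3
) -> tuple[list[KneeRecord], dict[int, int]]:
    """Keep knees with definite but not end-stage radiographic OA.

    Returns the retained records and the per-KLG counts of the input
    (funnel bookkeeping).
    """
    counts: dict[int, int] = {}
    kept = []
    for rec in records:
        k = int(rec.klg)
        counts[k] = counts.get(k, 0) + 1
        if klg_min <= k <= klg_max:
            kept.append(rec)
    return kept, counts


# ---------------------------------------------------------------------------
# 1:1 matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (case_id, control_id)
    unmatched_cases: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


_BIG = 1.0e9  # larger than any achievable total caliper distance


def match_pairs(
    cases: Sequence[KneeRecord],
    controls: Sequence[KneeRecord],
    spec: MatchSpec = MatchSpec(),
    method: Literal["optimal", "greedy"] = "optimal",
) -> MatchResult:
    """1:1 case-control matching on the caliper eligibility graph.

    ``optimal`` (default) finds a maximum-cardinality matching and, among
    maximum matchings, one of minimal total caliper-normalized distance
    (assignment-problem formulation).  ``greedy`` pairs each case, in input
    order, with its nearest eligible unused control — provided for
    sensitivity analysis.  Each control is used at most once; unmatched
    cases are reported, never an error.
    """
    n, m = len(cases), len(controls)
    if n == 0 or m == 0:
        return MatchResult(pairs=[], unmatched_cases=[c.knee_id for c in cases])

    dist = np.full((n, m), _BIG)
    for i, case in enumerate(cases):
        for j, control in enumerate(controls):
            if spec.eligible(case, control):
                dist[i, j] = spec.distance(case, control)

    pairs: list[tuple[str, str]] = []
    matched_cases: set[int] = set()
    if method == "optimal":
        # An ineligible edge costs _BIG, which dwarfs any sum of eligible
        # distances (each <= 3), so minimising total cost first maximises
        # the number of eligible pairs, then minimises distance.
        row, col = linear_sum_assignment(dist)
        for i, j in zip(row, col):
            if dist[i, j] < _BIG:
                pairs.append((cases[i].knee_id, controls[j].knee_id))
                matched_cases.add(i)
    elif method == "greedy":
        used: set[int] = set()
        for i, case in enumerate(cases):
            candidates = [(dist[i, j], j) for j in range(m)
                          if j not in used and dist[i, j] < _BIG]
            if candidates:
                _, j = min(candidates)
                pairs.append((case.knee_id, controls[j].knee_id))
                used.add(j)
                matched_cases.add(i)
    else:
        raise ProgressionError(f"unknown matching method {method!r}")

    unmatched = [c.knee_id for i, c in enumerate(cases) if i not in matched_cases]
    return MatchResult(pairs=pairs, unmatched_cases=unmatched)


# ---------------------------------------------------------------------------
# Tabular plumbing
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "knee_id", "sex", "age_years", "height_cm", "bmi_kg_m2", "womac_pain",
    "klg", "med_jsn", "lat_jsn", "mftc_mm_baseline", "mftc_mm_y1",
    "lftc_mm_baseline", "lftc_mm_y1", "minjsw_mm_baseline", "minjsw_mm_y1",
]


def records_from_frame(df: pd.DataFrame) -> list[KneeRecord]:
    """Build KneeRecords from a cohort table (one row per knee)."""
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _RECORD_COLUMNS:
            if col not in df.columns:
                continue
            v = row[col]
            if pd.isna(v):
                v = None
            kwargs[col] = v
        kwargs["knee_id"] = str(kwargs["knee_id"])
        kwargs["klg"] = int(kwargs["klg"])
        for jsn in ("med_jsn", "lat_jsn"):
            if kwargs.get(jsn) is not None:
                kwargs[jsn] = int(kwargs[jsn])
        records.append(KneeRecord(**kwargs))
    return records
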