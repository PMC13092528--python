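"""Progression outcomes: clinician SPMS labels and the objective detector.

The objective outcome is relapse-independent confirmed disability
progression: a candidate visit with overall EDSS >= 4.0 and pyramidal FS >= 2,
an EDSS increase of >= 1.0 over the reference when the reference EDSS is
<= 5.5 (>= 0.5 when >= 6.0), confirmation sustained in EDSS and in the
leading functional subsystem at least three months later, and no relapse
between the preceding evaluation and the candidate.

The reference comparator is configurable: the default is the roving nadir
(minimum EDSS from baseline up to, but excluding, the candidate); the
alternative is the fixed baseline-visit EDSS. The half-point grid makes a
reference strictly between 5.5 and 6.0 impossible, so the two delta bands
partition all references (asserted at import).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

from .registry import FS_NAMES, PatientRecord, Visit

__all__ = [
    "ProgressionCriteria",
    "ProgressionEvent",
    "DetectionScan",
    "detect_objective_progression",
    "label_clinical_progression",
    "objective_rrms_at_baseline",
]

HORIZON_DAYS = 1826  # five years in the fixed day convention


@dataclass(frozen=True)
class ProgressionCriteria:
    edss_floor: float = 4.0
    pyramidal_min: int = 2
    delta_low_baseline: float = 1.0  # applies when reference EDSS <= 5.5
    delta_high_baseline: float = 0.5  # applies when reference EDSS >= 6.0
    confirmation_days: int = 90
    require_leading_fs_confirmation: bool = True
    reference: str = "nadir"  # or "baseline"

    def __post_init__(self) -> None:
        if self.delta_high_baseline > self.delta_low_baseline:
            raise ValueError("delta_high_baseline must be <= delta_low_baseline")
        if min(
            self.edss_floor,
            self.delta_low_baseline,
            self.delta_high_baseline,
            self.confirmation_days,
        ) <= 0:
            raise ValueError("criteria thresholds must be positive")
        if self.reference not in {"nadir", "baseline"}:
            raise ValueError(f"unknown reference semantics {self.reference!r}")


# The EDSS half-point grid leaves no value strictly between the two delta
# bands; guard the assumption the band logic relies on.
assert not any(5.5 < v / 2 < 6.0 for v in range(0, 21))


@dataclass(frozen=True)
class ProgressionEvent:
    patient_id: str
    event_date: dt.date
    confirm_date: dt.date
    reference_edss: float
    event_edss: float
    leading_fs: str
    reason_trace: tuple[str, ...] = ()


@dataclass
class DetectionScan:
    """Full detector output: the earliest event (if any) plus abstentions
    recorded where missing FS data blocked a determination."""

    event: ProgressionEvent | None
    abstentions: list[tuple[dt.date, str]] = field(default_factory=list)


def _required_delta(reference_edss: float, criteria: ProgressionCriteria) -> float:
    if reference_edss <= 5.5:
        return criteria.delta_low_baseline
    return criteria.delta_high_baseline


def _leading_fs(reference: Visit, candidate: Visit) -> str | None:
    """Subsystem with the largest increase reference -> candidate.

    Ties break by the fixed subsystem order. Returns None when any score
    needed for the comparison is missing.
    """
    best_name: str | None = None
    best_delta: float | None = None
    for name in FS_NAMES:
        ref = reference.fs(name)
        cand = candidate.fs(name)
        if ref is None or cand is None:
            return None
        delta = cand - ref
        if best_delta is None or delta > best_delta:
            best_name, best_delta = name, delta
    return best_name


def _scan_progression(
    record: PatientRecord,
    criteria: ProgressionCriteria,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> DetectionScan:
    """Scan visits in [start, end] for the earliest confirmed progression."""
    start = start if start is not None else record.baseline_date
    visits = record.visits_between(start=start, end=end)
    abstentions: list[tuple[dt.date, str]] = []
    if len(visits) < 2:
        return DetectionScan(event=None, abstentions=abstentions)

    for i, candidate in enumerate(visits):
        if i == 0:
            continue  # need a reference strictly before the candidate

        if criteria.reference == "nadir":
            ref_visit = min(visits[:i], key=lambda v: v.edss)
        else:
            ref_visit = visits[0]
        reference_edss = ref_visit.edss

        # (i) absolute floor and pyramidal involvement
        if candidate.edss < criteria.edss_floor:
            continue
        pyramidal = candidate.fs("pyramidal")
        if pyramidal is None:
            abstentions.append((candidate.date, "pyramidal FS missing at candidate"))
            continue
        if pyramidal < criteria.pyramidal_min:
            continue

        # (ii) threshold increase over the reference
        if candidate.edss - reference_edss < _required_delta(reference_edss, criteria):
            continue

        # (iv) no relapse in (previous visit, candidate]
        previous = visits[i - 1]
        if any(
            previous.date < r.date <= candidate.date for r in record.relapses
        ):
            continue

        # (iii) sustained confirmation >= confirmation_days later
        leading = _leading_fs(ref_visit, candidate)
        if leading is None and criteria.require_leading_fs_confirmation:
            abstentions.append(
                (candidate.date, "FS missing for leading-subsystem determination")
            )
            continue
        cand_fs = candidate.fs(leading) if leading is not None else None

        confirm_date: dt.date | None = None
        stable = True
        for later in visits[i + 1 :]:
            if later.edss < candidate.edss:
                stable = False
                break
            if criteria.require_leading_fs_confirmation and leading is not None:
                later_fs = later.fs(leading)
                if later_fs is None:
                    abstentions.append(
                        (later.date, f"{leading} FS missing at confirmation visit")
                    )
                    stable = False
                    break
                if cand_fs is not None and later_fs < cand_fs:
                    stable = False
                    break
            if (later.date - candidate.date).days >= criteria.confirmation_days:
                confirm_date = later.date
                break
        if not stable or confirm_date is None:
            continue

        trace = (
            f"EDSS {candidate.edss} >= floor {criteria.edss_floor}",
            f"pyramidal {pyramidal} >= {criteria.pyramidal_min}",
            f"increase {candidate.edss - reference_edss:.1f} over reference "
            f"{reference_edss} meets threshold",
            f"confirmed at {confirm_date} "
            f"(+{(confirm_date - candidate.date).days} d)",
            "no relapse since the preceding evaluation",
        )
        return DetectionScan(
            event=ProgressionEvent(
                patient_id=record.patient_id,
                event_date=candidate.date,
                confirm_date=confirm_date,
                reference_edss=reference_edss,
                event_edss=candidate.edss,
                leading_fs=leading if leading is not None else "pyramidal",
                reason_trace=trace,
            ),
            abstentions=abstentions,
        )

    return DetectionScan(event=None, abstentions=abstentions)


def detect_objective_progression(
    record: PatientRecord,
    criteria: ProgressionCriteria | None = None,
) -> ProgressionEvent | None:
    """Earliest confirmed relapse-independent progression event, or None.

    Missing FS data at a visit the detector needs makes it abstain at that
    candidate (recorded on the scan, retrievable via
    :func:`scan_objective_progression`) rather than silently pass.
    """
    return _scan_progression(record, criteria or ProgressionCriteria()).event


def scan_objective_progression(
    record: PatientRecord,
    criteria: ProgressionCriteria | None = None,
) -> DetectionScan:
    """Like :func:`detect_objective_progression` but exposing abstentions."""
    return _scan_progression(record, criteria or ProgressionCriteria())


def label_clinical_progression(
    record: PatientRecord, horizon_years: float = 5.0
) -> int:
    """1 iff a clinician SPMS transition falls within (baseline, baseline+horizon]."""
    if record.spms_transition_date is None:
        return 0
    if record.spms_transition_date < record.baseline_date:
        raise ValueError(
            f"patient {record.patient_id}: SPMS transition predates baseline"
        )
    horizon_days = round(horizon_years * 365.25)
    delta = (record.spms_transition_date - record.baseline_date).days
    return int(0 < delta <= horizon_days)


def objective_rrms_at_baseline(
    record: PatientRecord, criteria: ProgressionCriteria | None = None
) -> bool:
    """Criterion K: no objective progression event dated on or before baseline.

    The detector is run on the pre-baseline history only (visits and relapses
    up to and including the baseline date), anchored at the first recorded
    visit.
    """
    crit = criteria or ProgressionCriteria()
    pre_visits = [v for v in record.visits if v.date <= record.baseline_date]
    if len(pre_visits) < 2:
        return True
    truncated = PatientRecord(
        patient_id=record.patient_id,
        sex=record.sex,
        birth_date=record.birth_date,
        onset_date=record.onset_date,
        baseline_date=record.baseline_date,
        course_at_baseline=record.course_at_baseline,
        visits=list(pre_visits),
        relapses=[r for r in record.relapses if r.date <= record.baseline_date],
        treatments=list(record.treatments),
        spms_transition_date=None,
    )
    scan = _scan_progression(truncated, crit, start=pre_visits[0].date)
    return not (
        scan.event is not None and scan.event.event_date <= record.baseline_date
    )
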