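"""Longitudinal registry data model, CSV I/O, and cohort inclusion criteria.

The registry is four delimited tables (patients, visits, relapses,
treatments) keyed by an opaque ``patient_id``. Dates are ISO-8601; EDSS lives
on the 0-10 half-point grid; the seven functional-subsystem (FS) scores are
integers 0-6 and may be missing.

Inclusion screening mirrors a multicentre observational design: adults with
RRMS at baseline, two or more evaluations, strictly more than three years of
follow-up (five-year target window), and baseline EDSS available. The
objective-outcome sub-cohort additionally requires relapse reporting, full FS
availability at the visits the progression detector consumes, consecutive
evaluations more than 90 days apart, and no objective progression event on or
before baseline.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FS_NAMES",
    "Visit",
    "Relapse",
    "TreatmentEpisode",
    "PatientRecord",
    "InclusionReport",
    "RegistryFormatError",
    "load_registry",
    "write_registry",
    "apply_inclusion_criteria",
    "normalize_episodes",
    "years_between",
]

#: Fixed order of the seven functional subsystems underlying the EDSS.
FS_NAMES = (
    "pyramidal",
    "cerebellar",
    "brainstem",
    "sensory",
    "bowel_bladder",
    "visual",
    "cerebral",
)

DAYS_PER_YEAR = 365.25


class RegistryFormatError(ValueError):
    """A registry file violates the documented schema (bad date, off-grid EDSS,
    orphan row...). Carries the file and row number when known."""


def years_between(start: dt.date, end: dt.date) -> float:
    """Elapsed years computed in days / 365.25 (fixed convention)."""
    return (end - start).days / DAYS_PER_YEAR


def _parse_date(text: str, *, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise RegistryFormatError(f"{where}: malformed ISO-8601 date {text!r}") from exc


def _parse_edss(text: str, *, where: str) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise RegistryFormatError(f"{where}: EDSS {text!r} is not numeric") from exc
    if not (0.0 <= value <= 10.0) or (value * 2) != int(value * 2):
        raise RegistryFormatError(
            f"{where}: EDSS {value} violates the 0-10 half-point grid"
        )
    return value


@dataclass(frozen=True)
class Visit:
    date: dt.date
    edss: float
    fs_scores: Mapping[str, int | None] = field(
        default_factory=lambda: {name: None for name in FS_NAMES}
    )

    def fs(self, name: str) -> int | None:
        return self.fs_scores.get(name)

    @property
    def fs_complete(self) -> bool:
        return all(self.fs_scores.get(name) is not None for name in FS_NAMES)


@dataclass(frozen=True)
class Relapse:
    date: dt.date


@dataclass(frozen=True)
class TreatmentEpisode:
    dmt_name: str
    start_date: dt.date
    stop_date: dt.date | None  # None = ongoing

    def clipped(self, stop: dt.date) -> "TreatmentEpisode":
        """Episode truncated so it ends no later than ``stop``."""
        if self.stop_date is None or self.stop_date > stop:
            return replace(self, stop_date=stop)
        return self


@dataclass
class PatientRecord:
    patient_id: str
    sex: str  # female / male / unknown
    birth_date: dt.date
    onset_date: dt.date
    baseline_date: dt.date
    course_at_baseline: str  # RRMS / SPMS / PPMS / other
    visits: list[Visit] = field(default_factory=list)
    relapses: list[Relapse] = field(default_factory=list)
    treatments: list[TreatmentEpisode] = field(default_factory=list)
    spms_transition_date: dt.date | None = None
    other_neuro_disorder: bool = False
    prior_use: bool = False

    def __post_init__(self) -> None:
        self.visits.sort(key=lambda v: v.date)
        self.relapses.sort(key=lambda r: r.date)
        self.treatments.sort(key=lambda t: t.start_date)
        dates = [v.date for v in self.visits]
        if len(set(dates)) != len(dates):
            raise RegistryFormatError(
                f"patient {self.patient_id}: duplicate visit dates"
            )
        if self.onset_date > self.baseline_date:
            raise RegistryFormatError(
                f"patient {self.patient_id}: onset after baseline"
            )

    # Derived clinical quantities -------------------------------------------------

    def age_at(self, date: dt.date) -> float:
        return years_between(self.birth_date, date)

    def disease_duration_at(self, date: dt.date) -> float:
        return years_between(self.onset_date, date)

    @property
    def age_at_onset(self) -> float:
        return years_between(self.birth_date, self.onset_date)

    @property
    def last_visit_date(self) -> dt.date | None:
        return self.visits[-1].date if self.visits else None

    @property
    def followup_years(self) -> float:
        if not self.visits:
            return 0.0
        return years_between(self.baseline_date, self.visits[-1].date)

    def baseline_visit(self) -> Visit | None:
        """The visit at (or first on/after) the baseline date."""
        for visit in self.visits:
            if visit.date >= self.baseline_date:
                return visit
        return None

    def baseline_edss(self) -> float | None:
        visit = self.baseline_visit()
        if visit is not None and visit.date == self.baseline_date:
            return visit.edss
        return None

    def visits_between(
        self, start: dt.date | None = None, end: dt.date | None = None
    ) -> list[Visit]:
        out = self.visits
        if start is not None:
            out = [v for v in out if v.date >= start]
        if end is not None:
            out = [v for v in out if v.date <= end]
        return out


@dataclass
class InclusionReport:
    included_ids: set[str]
    exclusions: list[tuple[str, str, str]]  # (patient_id, criterion code, message)
    criteria_matrix: dict[str, dict[str, bool]] = field(default_factory=dict)

    @property
    def excluded_ids(self) -> set[str]:
        return {pid for pid, _, _ in self.exclusions}

    def write_csv(self, path: str | Path) -> None:
        codes = sorted({c for row in self.criteria_matrix.values() for c in row})
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["patient_id", "included"] + codes)
            for pid in sorted(self.criteria_matrix):
                row = self.criteria_matrix[pid]
                writer.writerow(
                    [pid, int(pid in self.included_ids)]
                    + [int(row.get(c, True)) for c in codes]
                )


# ---------------------------------------------------------------------------
# Loading and writing
# ---------------------------------------------------------------------------


def _read_rows(path: Path) -> Iterable[tuple[int, dict[str, str]]]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        for i, row in enumerate(reader, start=2):  # header is line 1
            yield i, row


def load_registry(
    patients_path: str | Path,
    visits_path: str | Path,
    relapses_path: str | Path,
    treatments_path: str | Path,
) -> list[PatientRecord]:
    """Read the four registry CSVs into :class:`PatientRecord` objects.

    Visits, relapses and treatment episodes are attached to their patient and
    sorted by date. Unknown DMT names are preserved verbatim; efficacy
    classification happens downstream. Malformed rows (bad dates, off-grid
    EDSS, rows referencing an unknown patient) raise
    :class:`RegistryFormatError` naming the file and row.
    """
    patients: dict[str, dict] = {}
    for lineno, row in _read_rows(Path(patients_path)):
        where = f"{patients_path}:{lineno}"
        pid = row["patient_id"].strip()
        if pid in patients:
            raise RegistryFormatError(f"{where}: duplicate patient_id {pid!r}")
        spms = row.get("spms_transition_date", "").strip()
        patients[pid] = dict(
            patient_id=pid,
            sex=row.get("sex", "unknown").strip() or "unknown",
            birth_date=_parse_date(row["birth_date"], where=where),
            onset_date=_parse_date(row["onset_date"], where=where),
            baseline_date=_parse_date(row["baseline_date"], where=where),
            course_at_baseline=row.get("course_at_baseline", "RRMS").strip(),
            spms_transition_date=_parse_date(spms, where=where) if spms else None,
            other_neuro_disorder=row.get("other_neuro_disorder_flag", "0").strip()
            in {"1", "true", "True", "yes"},
            prior_use=row.get("prior_use_flag", "0").strip()
            in {"1", "true", "True", "yes"},
            visits=[],
            relapses=[],
            treatments=[],
        )

    for lineno, row in _read_rows(Path(visits_path)):
        where = f"{visits_path}:{lineno}"
        pid = row["patient_id"].strip()
        if pid not in patients:
            raise RegistryFormatError(f"{where}: visit for unknown patient {pid!r}")
        fs: dict[str, int | None] = {}
        for name in FS_NAMES:
            raw = row.get(f"fs_{name}", "").strip()
            if raw == "":
                fs[name] = None
            else:
                value = int(raw)
                if not 0 <= value <= 6:
                    raise RegistryFormatError(
                        f"{where}: fs_{name}={value} outside the 0-6 integer grid"
                    )
                fs[name] = value
        patients[pid]["visits"].append(
            Visit(
                date=_parse_date(row["date"], where=where),
                edss=_parse_edss(row["edss"], where=where),
                fs_scores=fs,
            )
        )

    for lineno, row in _read_rows(Path(relapses_path)):
        where = f"{relapses_path}:{lineno}"
        pid = row["patient_id"].strip()
        if pid not in patients:
            raise RegistryFormatError(f"{where}: relapse for unknown patient {pid!r}")
        patients[pid]["relapses"].append(
            Relapse(date=_parse_date(row["date"], where=where))
        )

    for lineno, row in _read_rows(Path(treatments_path)):
        where = f"{treatments_path}:{lineno}"
        pid = row["patient_id"].strip()
        if pid not in patients:
            raise RegistryFormatError(
                f"{where}: treatment for unknown patient {pid!r}"
            )
        stop = row.get("stop_date", "").strip()
        start = _parse_date(row["start_date"], where=where)
        stop_date = _parse_date(stop, where=where) if stop else None
        if stop_date is not None and start >= stop_date:
            raise RegistryFormatError(f"{where}: start_date not before stop_date")
        patients[pid]["treatments"].append(
            TreatmentEpisode(
                dmt_name=row["dmt_name"].strip().lower(),
                start_date=start,
                stop_date=stop_date,
            )
        )

    return [PatientRecord(**kw) for _, kw in sorted(patients.items())]


def write_registry(records: Sequence[PatientRecord], out_dir: str | Path) -> None:
    """Write records back to the four-file CSV schema (inverse of loading)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "patients.csv", "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "patient_id",
                "sex",
                "birth_date",
                "onset_date",
                "baseline_date",
                "course_at_baseline",
                "spms_transition_date",
                "other_neuro_disorder_flag",
                "prior_use_flag",
            ]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.sex,
                    rec.birth_date.isoformat(),
                    rec.onset_date.isoformat(),
                    rec.baseline_date.isoformat(),
                    rec.course_at_baseline,
                    rec.spms_transition_date.isoformat()
                    if rec.spms_transition_date
                    else "",
                    int(rec.other_neuro_disorder),
                    int(rec.prior_use),
                ]
            )

    with open(out / "visits.csv", "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["patient_id", "date", "edss"] + [f"fs_{name}" for name in FS_NAMES]
        )
        for rec in records:
            for visit in rec.visits:
                edss = visit.edss
                edss_text = str(int(edss)) if edss == int(edss) else str(edss)
                writer.writerow(
                    [rec.patient_id, visit.date.isoformat(), edss_text]
                    + [
                        "" if visit.fs(name) is None else visit.fs(name)
                        for name in FS_NAMES
                    ]
                )

    with open(out / "relapses.csv", "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "date"])
        for rec in records:
            for relapse in rec.relapses:
                writer.writerow([rec.patient_id, relapse.date.isoformat()])

    with open(out / "treatments.csv", "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "dmt_name", "start_date", "stop_date"])
        for rec in records:
            for ep in rec.treatments:
                writer.writerow(
                    [
                        rec.patient_id,
                        ep.dmt_name,
                        ep.start_date.isoformat(),
                        ep.stop_date.isoformat() if ep.stop_date else "",
                    ]
                )


def load_registry_dir(registry_dir: str | Path) -> list[PatientRecord]:
    """Load a registry from a directory holding the four standard CSVs."""
    d = Path(registry_dir)
    return load_registry(
        d / "patients.csv", d / "visits.csv", d / "relapses.csv", d / "treatments.csv"
    )


# ---------------------------------------------------------------------------
# Treatment-episode normalization
# ---------------------------------------------------------------------------


def normalize_episodes(
    episodes: Sequence[TreatmentEpisode],
) -> list[TreatmentEpisode]:
    """Resolve overlapping episodes by truncating the earlier at the later's start.

    Episodes are half-open ``[start, stop)``; a zero-length episode produced by
    truncation is dropped. The result is sorted and pairwise non-overlapping.
    """
    ordered = sorted(episodes, key=lambda e: (e.start_date, e.stop_date or dt.date.max))
    out: list[TreatmentEpisode] = []
    for ep in ordered:
        while out:
            prev = out[-1]
            prev_stop = prev.stop_date
            if prev_stop is None or prev_stop > ep.start_date:
                trimmed = replace(prev, stop_date=ep.start_date)
                out.pop()
                if trimmed.start_date < ep.start_date:
                    out.append(trimmed)
                continue
            break
        out.append(ep)
    return out


# ---------------------------------------------------------------------------
# Inclusion criteria
# ---------------------------------------------------------------------------


def apply_inclusion_criteria(
    records: Sequence[PatientRecord],
    mode: str = "base",
    min_followup_years: float = 3.0,
    target_years: float = 5.0,
    tolerance_years: float = 2.0,
    min_gap_days: int = 90,
    criteria=None,
) -> InclusionReport:
    """Screen records against the cohort inclusion criteria.

    Base mode enforces:

    A. RRMS course at baseline;
    B. no other neurological disorder (upstream flag);
    C. age >= 18 years at baseline;
    D. two or more clinical evaluations;
    E. follow-up strictly greater than ``min_followup_years`` (target
       ``target_years`` +/- ``tolerance_years``; the cap is applied downstream
       when exposure windows are formed);
    F. EDSS recorded at the baseline visit;
    G. data not previously used (upstream flag).

    ``mode="objective"`` additionally enforces:

    H. relapse reporting available (schema-level, recorded as pass);
    I. all seven FS scores present at the visits the progression detector
       consumes (fails only when a missing FS leaves detection indeterminate);
    J. consecutive evaluations more than ``min_gap_days`` days apart;
    K. no objective progression event on or before baseline.

    Every input patient lands in exactly one of included/excluded; failures
    are reported per criterion code, never raised.
    """
    if mode not in {"base", "objective"}:
        raise ValueError(f"unknown mode {mode!r}")

    # Imported here to avoid a cycle: outcomes needs PatientRecord.
    from .outcomes import (
        ProgressionCriteria,
        objective_rrms_at_baseline,
        _scan_progression,
    )

    crit = criteria or ProgressionCriteria()

    included: set[str] = set()
    exclusions: list[tuple[str, str, str]] = []
    matrix: dict[str, dict[str, bool]] = {}

    for rec in records:
        checks: dict[str, bool] = {}
        messages: list[tuple[str, str]] = []

        def fail(code: str, message: str) -> None:
            checks[code] = False
            messages.append((code, message))

        # --- base criteria ---
        if rec.course_at_baseline == "RRMS":
            checks["A"] = True
        else:
            fail("A", f"course at baseline is {rec.course_at_baseline}, not RRMS")

        if not rec.other_neuro_disorder:
            checks["B"] = True
        else:
            fail("B", "other neurological disorder flagged")

        age = rec.age_at(rec.baseline_date)
        if age >= 18.0:
            checks["C"] = True
        else:
            fail("C", f"age {age:.1f} < 18 at baseline")

        if len(rec.visits) >= 2:
            checks["D"] = True
        else:
            fail("D", f"{len(rec.visits)} clinical evaluation(s), need >= 2")

        followup = rec.followup_years
        if followup > min_followup_years:
            checks["E"] = True
        else:
            fail("E", f"follow-up {followup:.2f} y not > {min_followup_years} y")

        if rec.baseline_edss() is not None:
            checks["F"] = True
        else:
            fail("F", "no EDSS recorded at the baseline visit")

        if not rec.prior_use:
            checks["G"] = True
        else:
            fail("G", "data previously used (upstream flag)")

        # SPMS label before baseline contradicts RRMS at baseline.
        if (
            rec.spms_transition_date is not None
            and rec.spms_transition_date < rec.baseline_date
        ):
            fail("A", "SPMS transition dated before baseline")

        # --- objective-mode criteria ---
        if mode == "objective":
            checks["H"] = True  # relapse reporting is schema-level in this format

            visits = rec.visits_between(start=rec.baseline_date)
            gaps_ok = all(
                (b.date - a.date).days > min_gap_days
                for a, b in zip(visits, visits[1:])
            )
            if gaps_ok:
                checks["J"] = True
            else:
                fail("J", f"consecutive evaluations <= {min_gap_days} days apart")

            # I: detector must not be left indeterminate by missing FS.
            scan = _scan_progression(rec, crit, start=rec.baseline_date)
            if scan.event is not None or not scan.abstentions:
                checks["I"] = True
            else:
                fail(
                    "I",
                    "missing FS scores left progression detection indeterminate",
                )

            if objective_rrms_at_baseline(rec, crit):
                checks["K"] = True
            else:
                fail("K", "objective progression event on or before baseline")

        matrix[rec.patient_id] = checks
        if messages:
            for code, message in messages:
                exclusions.append((rec.patient_id, code, message))
        else:
            included.add(rec.patient_id)

    return InclusionReport(
        included_ids=included, exclusions=exclusions, criteria_matrix=matrix
    )
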