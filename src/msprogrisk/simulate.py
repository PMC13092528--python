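"""Synthetic MS registry with known ground truth.

Emulates the structure of a large observational MS cohort: ~6-monthly visits
over 3-7 years, EDSS on the half-point grid (baseline median 2, IQR 1-3),
mean baseline age ~37 (SD ~11), mean disease duration ~6 years, Poisson
relapses with age decay, dated DMT episodes drawn from the named drug list
with indication bias (sicker patients preferentially receive high-efficacy
therapy), and a latent progression process.

Progression is a discrete-time hazard per inter-visit interval whose
log-hazard is linear in age, disease duration and current EDSS, multiplied by
the efficacy of the DMT class in force (high < intermediate < low < none).
After the latent progression date the EDSS walk acquires an upward drift and
pyramidal involvement; the clinician SPMS label is the latent date plus an
exponential recognition delay and is only recorded with a configurable
probability — under-recognition makes objective (EDSS-defined) events more
frequent than clinical labels, matching the ordering seen in registries.

The module also ships a hand-built fixture catalogue: minimal trajectories
instantiating each branch of the objective progression definition and each of
the ten treatment-history categories, with their expected outputs.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registry import (
    FS_NAMES,
    PatientRecord,
    Relapse,
    TreatmentEpisode,
    Visit,
    write_registry,
)

__all__ = ["SimConfig", "GroundTruth", "generate_registry", "make_fixture", "FIXTURE_CASES"]

_DRUGS_BY_CLASS = {
    "low": ["interferon-beta", "glatiramer acetate", "teriflunomide", "dimethyl fumarate"],
    "intermediate": ["fingolimod", "cladribine"],
    "high": ["natalizumab", "ocrelizumab", "rituximab"],
}

_CLASS_ORDER = ("none", "low", "intermediate", "high")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the emulated cohort conditions."""

    n_patients: int = 1000
    seed: int = 0
    # visit schedule
    visit_interval_days: int = 182
    visit_jitter_days: int = 30  # keeps gaps > 90 days
    followup_years: tuple[float, float] = (3.0, 7.0)
    # baseline covariates
    baseline_age_mean: float = 37.1
    baseline_age_sd: float = 10.8
    duration_mean: float = 5.8
    duration_sd: float = 7.3
    baseline_edss_shape: float = 2.0
    baseline_edss_scale: float = 1.1
    # relapses
    relapse_rate: float = 0.35  # per year at age 37
    relapse_age_decay: float = 0.02
    # progression hazard (annual, log scale)
    log_hazard_intercept: float = math.log(0.050)
    beta_age: float = 0.025
    beta_duration: float = 0.02
    beta_edss: float = 0.30
    efficacy_multipliers: tuple[float, float, float, float] = (1.0, 0.80, 0.65, 0.45)
    # DMT assignment and switching
    indication_bias: float = 0.6  # log-odds of high-efficacy per EDSS point
    base_class_probs: tuple[float, float, float, float] = (0.36, 0.48, 0.06, 0.10)
    escalation_rate: float = 0.05  # per year; x3 after latent progression
    deescalation_rate: float = 0.02
    initiation_rate: float = 0.10
    discontinuation_rate: float = 0.04
    # clinical labelling of the latent progression
    spms_delay_mean_days: float = 182.5
    spms_label_prob: float = 0.65
    # missingness
    fs_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "relapse_rate",
            "escalation_rate",
            "deescalation_rate",
            "initiation_rate",
            "discontinuation_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mult = self.efficacy_multipliers
        if not all(0 < m <= 1 for m in mult):
            raise ValueError("efficacy multipliers must lie in (0, 1]")
        # ordered none >= low >= intermediate >= high
        if not (mult[0] >= mult[1] >= mult[2] >= mult[3]):
            raise ValueError(
                "efficacy multipliers must be ordered none >= low >= "
                "intermediate >= high"
            )
        if not 0 <= self.fs_missing_rate < 1:
            raise ValueError("fs_missing_rate must lie in [0, 1)")
        if not 0 <= self.spms_label_prob <= 1:
            raise ValueError("spms_label_prob must lie in [0, 1]")

    def multiplier(self, dmt_class: str) -> float:
        return self.efficacy_multipliers[_CLASS_ORDER.index(dmt_class)]


@dataclass
class GroundTruth:
    """Latent quantities the generator knows and downstream stages estimate."""

    latent_progression: dict[str, dt.date | None] = field(default_factory=dict)
    linear_predictors: dict[str, list[tuple[dt.date, float]]] = field(
        default_factory=dict
    )
    assigned_class: dict[str, str] = field(default_factory=dict)

    def write_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["patient_id", "latent_progression_date", "initial_class"])
            for pid in sorted(self.latent_progression):
                date = self.latent_progression[pid]
                writer.writerow(
                    [
                        pid,
                        date.isoformat() if date else "",
                        self.assigned_class.get(pid, "none"),
                    ]
                )


def _half_grid(value: float, lo: float = 0.0, hi: float = 10.0) -> float:
    return min(hi, max(lo, round(value * 2) / 2))


def _draw_class(
    rng: np.random.Generator,
    cfg: SimConfig,
    edss: float,
    age: float,
    duration: float,
    sex: str,
) -> str:
    """Initial DMT class with indication bias: higher EDSS, younger age,
    shorter duration and male sex all tilt assignment toward high efficacy
    (strength scaled by ``indication_bias``; 0 removes all confounding)."""
    logits = np.log(np.array(cfg.base_class_probs))
    shift = cfg.indication_bias * (
        (edss - 2.0)
        + 0.03 * (37.1 - age)
        + 0.04 * (5.8 - duration)
        + (0.5 if sex == "male" else 0.0)
    )
    logits += np.array([-0.5 * shift, 0.0, 0.4 * shift, shift])
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    return _CLASS_ORDER[rng.choice(4, p=probs)]


def _step_class(
    rng: np.random.Generator,
    cfg: SimConfig,
    current: str,
    dt_years: float,
    progressed: bool,
) -> str:
    """One interval of the treatment-switching process."""
    boost = 3.0 if progressed else 1.0
    if current == "none":
        if rng.random() < cfg.initiation_rate * dt_years * boost:
            return str(rng.choice(["low", "intermediate", "high"], p=[0.6, 0.15, 0.25]))
        return current
    if rng.random() < cfg.discontinuation_rate * dt_years:
        return "none"
    rank = _CLASS_ORDER.index(current)
    if rank < 3 and rng.random() < cfg.escalation_rate * dt_years * boost:
        return _CLASS_ORDER[rank + 1]
    if rank > 1 and rng.random() < cfg.deescalation_rate * dt_years:
        return _CLASS_ORDER[rank - 1]
    return current


def _simulate_patient(
    pid: str, rng: np.random.Generator, cfg: SimConfig
) -> tuple[PatientRecord, dt.date | None, list[tuple[dt.date, float]], str]:
    baseline = dt.date(2005, 1, 1) + dt.timedelta(days=int(rng.integers(0, 3653)))
    age0 = float(np.clip(rng.normal(cfg.baseline_age_mean, cfg.baseline_age_sd), 18.5, 70))
    shape = (cfg.duration_mean / cfg.duration_sd) ** 2
    scale = cfg.duration_mean / shape
    duration0 = float(max(0.2, rng.gamma(shape, scale)))
    duration0 = min(duration0, age0 - 18.0)  # onset at 18+
    birth = baseline - dt.timedelta(days=round(age0 * 365.25))
    onset = baseline - dt.timedelta(days=round(duration0 * 365.25))
    sex = "female" if rng.random() < 0.726 else "male"

    edss = _half_grid(rng.gamma(cfg.baseline_edss_shape, cfg.baseline_edss_scale), 0, 6.5)
    followup_days = round(
        rng.uniform(cfg.followup_years[0], cfg.followup_years[1]) * 365.25
    )

    # visit schedule: baseline plus ~6-monthly visits
    dates = [baseline]
    day = 0
    while True:
        day += int(
            cfg.visit_interval_days
            + rng.integers(-cfg.visit_jitter_days, cfg.visit_jitter_days + 1)
        )
        if day > followup_days:
            break
        dates.append(baseline + dt.timedelta(days=day))

    dmt_class = _draw_class(rng, cfg, edss, age0, duration0, sex)
    initial_class = dmt_class
    episodes: list[TreatmentEpisode] = []
    episode_start: dt.date | None = baseline if dmt_class != "none" else None
    episode_drug = (
        str(rng.choice(_DRUGS_BY_CLASS[dmt_class])) if dmt_class != "none" else ""
    )

    latent: dt.date | None = None
    visits: list[Visit] = []
    relapses: list[Relapse] = []
    lps: list[tuple[dt.date, float]] = []

    for i, date in enumerate(dates):
        progressed = latent is not None and date >= latent
        # EDSS walk
        if i > 0:
            if progressed:
                step = rng.choice([0.0, 0.5, 1.0], p=[0.30, 0.50, 0.20])
            else:
                step = rng.choice([-0.5, 0.0, 0.5], p=[0.20, 0.60, 0.20])
            edss = _half_grid(edss + step, 0, 9.5)
            if progressed and visits:
                edss = max(edss, visits[-1].edss)  # progression does not remit

        # functional subsystems co-generated with the EDSS
        pyramidal = int(np.clip(round(edss / 2 + rng.normal(0, 0.5)), 0, 6))
        if progressed and edss >= 4.0:
            pyramidal = max(pyramidal, 2)
        fs = {"pyramidal": pyramidal}
        for name in FS_NAMES[1:]:
            fs[name] = int(np.clip(rng.poisson(max(edss, 0.2) / 4), 0, 6))
        if cfg.fs_missing_rate > 0:
            for name in FS_NAMES:
                if rng.random() < cfg.fs_missing_rate:
                    fs[name] = None
        visits.append(Visit(date=date, edss=edss, fs_scores=fs))

        if i + 1 >= len(dates):
            break
        nxt = dates[i + 1]
        dt_years = (nxt - date).days / 365.25

        # relapses over the interval (pre-progression disease activity)
        age = (date - birth).days / 365.25
        rate = cfg.relapse_rate * math.exp(-cfg.relapse_age_decay * (age - 37.0))
        if latent is None:
            for _ in range(rng.poisson(rate * dt_years)):
                offset = int(rng.integers(1, max(2, (nxt - date).days)))
                relapses.append(Relapse(date=date + dt.timedelta(days=offset)))

        # latent progression hazard over the interval
        lp = (
            cfg.log_hazard_intercept
            + cfg.beta_age * (age - cfg.baseline_age_mean)
            + cfg.beta_duration * ((date - onset).days / 365.25 - cfg.duration_mean)
            + cfg.beta_edss * (edss - 2.0)
            + math.log(cfg.multiplier(dmt_class))
        )
        lps.append((date, lp))
        if latent is None:
            p_event = 1.0 - math.exp(-math.exp(lp) * dt_years)
            if rng.random() < p_event:
                offset = int(rng.integers(0, max(1, (nxt - date).days)))
                latent = date + dt.timedelta(days=offset)

        # treatment switching process
        new_class = _step_class(rng, cfg, dmt_class, dt_years, progressed)
        if new_class != dmt_class:
            if dmt_class != "none" and episode_start is not None:
                episodes.append(
                    TreatmentEpisode(
                        dmt_name=episode_drug, start_date=episode_start, stop_date=nxt
                    )
                )
            episode_start = nxt if new_class != "none" else None
            episode_drug = (
                str(rng.choice(_DRUGS_BY_CLASS[new_class]))
                if new_class != "none"
                else ""
            )
            dmt_class = new_class

    if dmt_class != "none" and episode_start is not None:
        episodes.append(
            TreatmentEpisode(
                dmt_name=episode_drug, start_date=episode_start, stop_date=None
            )
        )

    # clinician SPMS label: delayed, imperfect recognition
    spms: dt.date | None = None
    if latent is not None and rng.random() < cfg.spms_label_prob:
        delay = rng.exponential(cfg.spms_delay_mean_days)
        candidate = latent + dt.timedelta(days=round(delay))
        if candidate <= visits[-1].date:
            spms = candidate

    record = PatientRecord(
        patient_id=pid,
        sex=sex,
        birth_date=birth,
        onset_date=onset,
        baseline_date=baseline,
        course_at_baseline="RRMS",
        visits=visits,
        relapses=[r for r in relapses if r.date >= onset],
        treatments=episodes,
        spms_transition_date=spms,
    )
    return record, latent, lps, initial_class


def generate_registry(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a registry; deterministic for a fixed config (incl. seed).

    When ``out_dir`` is given, the four registry CSVs and groundtruth.csv are
    written there.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    records = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        record, latent, lps, initial = _simulate_patient(pid, rng, config)
        records.append(record)
        truth.latent_progression[pid] = latent
        truth.linear_predictors[pid] = lps
        truth.assigned_class[pid] = initial
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_registry(records, out)
        truth.write_csv(out / "groundtruth.csv")
    return records, truth


# ---------------------------------------------------------------------------
# Fixture catalogue
# ---------------------------------------------------------------------------

_B = dt.date(2020, 1, 1)


def _m(months: int, extra_days: int = 0) -> dt.date:
    """Date ``months`` 30.44-day months after the fixture baseline."""
    return _B + dt.timedelta(days=round(months * 30.44) + extra_days)


def _fs(pyramidal: int) -> dict:
    fs = {name: 0 for name in FS_NAMES}
    fs["pyramidal"] = pyramidal
    return fs


def _fixture_record(
    visits: list[Visit],
    relapses: list[Relapse] = (),
    treatments: list[TreatmentEpisode] = (),
) -> PatientRecord:
    return PatientRecord(
        patient_id="FIX",
        sex="female",
        birth_date=dt.date(1985, 1, 1),
        onset_date=dt.date(2015, 1, 1),
        baseline_date=_B,
        course_at_baseline="RRMS",
        visits=list(visits),
        relapses=list(relapses),
        treatments=list(treatments),
    )


def _stable_visits() -> list[Visit]:
    """Eleven six-monthly visits at EDSS 2.0 (no progression)."""
    return [
        Visit(date=_m(6 * i), edss=2.0, fs_scores=_fs(1)) for i in range(11)
    ]


def _detector_case(visits, relapses=()) -> PatientRecord:
    return _fixture_record(visits, relapses=relapses)


def _ep(drug: str, start_m: float, stop_m: float | None) -> TreatmentEpisode:
    stop = None if stop_m is None else _B + dt.timedelta(days=round(stop_m * 30.44))
    return TreatmentEpisode(
        dmt_name=drug,
        start_date=_B + dt.timedelta(days=round(start_m * 30.44)),
        stop_date=stop,
    )


def _build_fixtures() -> dict[str, tuple[PatientRecord, dict]]:
    cases: dict[str, tuple[PatientRecord, dict]] = {}

    # --- objective-detector branches -------------------------------------
    cases["clean_delta10"] = (
        _detector_case(
            [
                Visit(_m(0), 3.5, _fs(1)),
                Visit(_m(6), 3.5, _fs(1)),
                Visit(_m(12), 4.5, _fs(3)),
                Visit(_m(18), 4.5, _fs(3)),
            ]
        ),
        {"event_date": _m(12), "confirm_date": _m(18)},
    )
    cases["clean_high_base"] = (
        _detector_case(
            [
                Visit(_m(0), 6.0, _fs(3)),
                Visit(_m(8), 6.5, _fs(3)),
                Visit(_m(12), 6.5, _fs(3)),
            ]
        ),
        {"event_date": _m(8), "confirm_date": _m(12)},
    )
    cases["unconfirmed_spike"] = (
        _detector_case(
            [
                Visit(_m(0), 3.5, _fs(1)),
                Visit(_m(12), 4.5, _fs(3)),
                Visit(_m(14), 3.5, _fs(1)),
            ]
        ),
        {"event_date": None},
    )
    cases["relapse_block"] = (
        _detector_case(
            [
                Visit(_m(0), 3.5, _fs(1)),
                Visit(_m(6), 3.5, _fs(1)),
                Visit(_m(12), 4.5, _fs(3)),
                Visit(_m(18), 4.5, _fs(3)),
            ],
            relapses=[Relapse(date=_m(11))],
        ),
        {"event_date": None},
    )
    cases["pyramidal_block"] = (
        _detector_case(
            [
                Visit(_m(0), 3.5, _fs(1)),
                Visit(_m(6), 3.5, _fs(1)),
                Visit(_m(12), 4.5, _fs(1)),
                Visit(_m(18), 4.5, _fs(1)),
            ]
        ),
        {"event_date": None},
    )
    cases["floor_block"] = (
        _detector_case(
            [
                Visit(_m(0), 2.0, _fs(1)),
                Visit(_m(6), 2.0, _fs(1)),
                Visit(_m(12), 3.0, _fs(2)),
                Visit(_m(18), 3.0, _fs(2)),
            ]
        ),
        {"event_date": None},
    )

    # --- treatment-history categories (landmark at month 60) -------------
    landmark = {"landmark_date": _m(60)}

    def elie(case: str, episodes: list[TreatmentEpisode], expected: str) -> None:
        cases[case] = (
            _fixture_record(_stable_visits(), treatments=episodes),
            {**landmark, "elie_category": expected},
        )

    elie("elie_never_treated", [], "never_treated")
    elie("elie_stable_low", [_ep("dimethyl fumarate", 0, None)], "stable_low")
    elie("elie_stable_intermediate", [_ep("fingolimod", 0, None)], "stable_intermediate")
    elie("elie_stable_high", [_ep("natalizumab", 0, None)], "stable_high")
    elie(
        "elie_escalation",
        [_ep("interferon-beta", 0, 30), _ep("natalizumab", 30, None)],
        "switcher_escalation",
    )
    elie(
        "elie_deescalation",
        [_ep("natalizumab", 0, 30), _ep("interferon-beta", 30, None)],
        "switcher_deescalation",
    )
    elie(
        "elie_bidirectional",
        [
            _ep("natalizumab", 0, 18),
            _ep("interferon-beta", 18, 36),
            _ep("natalizumab", 36, None),
        ],
        "switcher_bidirectional",
    )
    elie(
        "elie_initiation",
        [_ep("teriflunomide", 36, None)],
        "switcher_initiation",
    )
    elie(
        "elie_discontinuation",
        [_ep("glatiramer acetate", 0, 24)],
        "switcher_discontinuation",
    )
    elie(
        "elie_complex",
        [_ep("teriflunomide", 12, 24), _ep("teriflunomide", 48, None)],
        "switcher_complex",
    )
    return cases


FIXTURE_CASES: tuple[str, ...] = tuple(_build_fixtures().keys())


def make_fixture(case_id: str) -> tuple[PatientRecord, dict]:
    """Hand-built trajectory plus its expected detector/classifier output."""
    cases = _build_fixtures()
    if case_id not in cases:
        raise KeyError(
            f"unknown fixture case {case_id!r}; known: {sorted(cases)}"
        )
    return cases[case_id]
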