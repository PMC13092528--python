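"""DMT efficacy classification and longitudinal treatment-exposure summaries.

Two exposure schemes coexist and use deliberately different denominators:

* the score-table scheme: majority class = efficacy class covering strictly
  more than 50% of the whole observation window; switch flag = some *other*
  class covering strictly more than 25% of the whole window;
* the landmark scheme: a ten-level mutually exclusive treatment-history
  category per (patient, landmark) window, plus a switcher flag defined on
  treated time (>= 50% of the window treated and >= 25% of treated time on a
  non-dominant class).

Treatment intervals are half-open ``[start, stop)``: a drug stopped on day d
does not count on day d, so adjacent episodes never double-count a day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .registry import PatientRecord, TreatmentEpisode, normalize_episodes

__all__ = [
    "EFFICACY_CLASSES",
    "DEFAULT_EFFICACY_MAP",
    "UnknownDrugError",
    "classify_efficacy",
    "exposure_fractions",
    "daae_exposure",
    "baseline_dmt",
    "elie_history_category",
    "summarize_exposure",
    "ExposureSummary",
    "ELIE_CATEGORIES",
]

EFFICACY_CLASSES = ("low", "intermediate", "high")

#: Drug name -> efficacy class. Fifteen disease-modifying therapies grouped by
#: established efficacy tiers; lookups are case-insensitive.
DEFAULT_EFFICACY_MAP: Mapping[str, str] = {
    # high efficacy
    "rituximab": "high",
    "ocrelizumab": "high",
    "mitoxantrone": "high",
    "alemtuzumab": "high",
    "natalizumab": "high",
    "ofatumumab": "high",
    # intermediate efficacy
    "fingolimod": "intermediate",
    "siponimod": "intermediate",
    "daclizumab": "intermediate",
    "laquinimod": "intermediate",
    "cladribine": "intermediate",
    # low efficacy
    "interferon-beta": "low",
    "glatiramer acetate": "low",
    "teriflunomide": "low",
    "dimethyl fumarate": "low",
}

ELIE_CATEGORIES = (
    "never_treated",
    "stable_low",
    "stable_intermediate",
    "stable_high",
    "switcher_escalation",
    "switcher_deescalation",
    "switcher_bidirectional",
    "switcher_initiation",
    "switcher_discontinuation",
    "switcher_complex",
)

_CLASS_RANK = {"low": 0, "intermediate": 1, "high": 2}


class UnknownDrugError(KeyError):
    """A DMT name absent from the efficacy map; never silently classed low."""


def classify_efficacy(
    dmt_name: str, efficacy_map: Mapping[str, str] | None = None
) -> str:
    """Efficacy class (low/intermediate/high) of a canonicalized drug name."""
    table = efficacy_map or DEFAULT_EFFICACY_MAP
    key = dmt_name.strip().lower()
    try:
        return table[key]
    except KeyError:
        raise UnknownDrugError(
            f"DMT {dmt_name!r} is not in the efficacy map; add it explicitly"
        ) from None


@dataclass(frozen=True)
class ExposureSummary:
    window: tuple[dt.date, dt.date]
    fractions: Mapping[str, float]  # low / intermediate / high / none
    treated_fraction: float
    majority_class: str | None  # class, "none", or None for no-majority
    daae_switch_flag: bool
    elie_switch_flag: bool
    transitions: tuple[tuple[str, str, dt.date], ...]
    elie_category: str


def _class_segments(
    episodes: Sequence[TreatmentEpisode],
    window: tuple[dt.date, dt.date],
    efficacy_map: Mapping[str, str] | None,
) -> list[tuple[dt.date, dt.date, str]]:
    """Normalized episodes clipped to the window, as (start, stop, class)."""
    start, end = window
    segments = []
    for ep in normalize_episodes(episodes):
        stop = ep.stop_date if ep.stop_date is not None else end
        s, e = max(ep.start_date, start), min(stop, end)
        if s < e:
            segments.append((s, e, classify_efficacy(ep.dmt_name, efficacy_map)))
    return segments


def exposure_fractions(
    episodes: Sequence[TreatmentEpisode],
    window: tuple[dt.date, dt.date],
    efficacy_map: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Fraction of the window spent in each efficacy class (plus untreated).

    Each class fraction is (days of that class's episodes intersected with the
    window) / (window days); ``none`` is the remainder. Fractions sum to 1.
    """
    start, end = window
    total = (end - start).days
    if total <= 0:
        raise ValueError(f"empty or inverted window {start}..{end}")
    days = {cls: 0 for cls in EFFICACY_CLASSES}
    for s, e, cls in _class_segments(episodes, window, efficacy_map):
        days[cls] += (e - s).days
    fractions = {cls: d / total for cls, d in days.items()}
    fractions["none"] = 1.0 - sum(fractions.values())
    return fractions


def daae_exposure(
    record: PatientRecord,
    window: tuple[dt.date, dt.date] | None = None,
    efficacy_map: Mapping[str, str] | None = None,
) -> tuple[str | None, bool]:
    """Majority-exposure class and switch flag over the observation window.

    Majority = the efficacy class with fraction strictly > 0.5 of the whole
    window ("none" when the untreated fraction exceeds 0.5); None when no
    state reaches a strict majority. The switch flag is set when some other
    efficacy class covers strictly more than 25% of the whole window.
    """
    if window is None:
        end = min(
            record.baseline_date + dt.timedelta(days=1826),
            record.last_visit_date or record.baseline_date,
        )
        window = (record.baseline_date, end)
    fractions = exposure_fractions(record.treatments, window, efficacy_map)
    majority: str | None = None
    for state in (*EFFICACY_CLASSES, "none"):
        if fractions[state] > 0.5:
            majority = state
            break
    switch = any(
        fractions[cls] > 0.25 for cls in EFFICACY_CLASSES if cls != majority
    )
    return majority, switch


def baseline_dmt(
    record: PatientRecord,
    baseline_date: dt.date | None = None,
    efficacy_map: Mapping[str, str] | None = None,
) -> str:
    """Efficacy class of the therapy in force on the baseline date, else "none".

    Half-open episode semantics: an episode stopping on the baseline date does
    not count. Normalization guarantees at most one covering episode.
    """
    date = baseline_date or record.baseline_date
    for ep in normalize_episodes(record.treatments):
        stop = ep.stop_date or dt.date.max
        if ep.start_date <= date < stop:
            return classify_efficacy(ep.dmt_name, efficacy_map)
    return "none"


def _state_sequence(
    segments: list[tuple[dt.date, dt.date, str]],
    window: tuple[dt.date, dt.date],
    gap_tolerance_days: int,
) -> list[tuple[str, dt.date]]:
    """Chronological exposure states over the window, as (state, start date).

    Untreated stretches longer than the gap tolerance become explicit "none"
    states; shorter gaps between same-class episodes are bridged. Adjacent
    same-state segments merge.
    """
    start, end = window
    states: list[tuple[str, dt.date]] = []
    cursor = start
    for s, e, cls in segments:
        gap = (s - cursor).days
        if gap > gap_tolerance_days:
            states.append(("none", cursor))
        states.append((cls, s))
        cursor = e
    if (end - cursor).days > gap_tolerance_days:
        states.append(("none", cursor))
    merged: list[tuple[str, dt.date]] = []
    for state, date in states:
        if merged and merged[-1][0] == state:
            continue
        merged.append((state, date))
    return merged


def _transitions(
    states: list[tuple[str, dt.date]],
) -> list[tuple[str, str, dt.date]]:
    return [
        (a_state, b_state, b_date)
        for (a_state, _), (b_state, b_date) in zip(states, states[1:])
    ]


def _categorize(
    fractions: Mapping[str, float],
    transitions: list[tuple[str, str, dt.date]],
    any_exposure: bool,
) -> str:
    """Assign the single treatment-history category, in fixed precedence.

    Precedence: never treated; stability (>= 50% of the window on one class
    with no class-to-class transition); bidirectional before unidirectional
    switching; class-to-class patterns before initiation/discontinuation;
    complex as the strict fallback.
    """
    if not any_exposure:
        return "never_treated"

    cc = [
        (a, b) for a, b, _ in transitions if a != "none" and b != "none"
    ]  # class-to-class transitions
    escalations = sum(1 for a, b in cc if _CLASS_RANK[b] > _CLASS_RANK[a])
    deescalations = sum(1 for a, b in cc if _CLASS_RANK[b] < _CLASS_RANK[a])

    if not cc:
        for cls in EFFICACY_CLASSES:
            if fractions[cls] >= 0.5:
                return f"stable_{cls}"

    if escalations and deescalations:
        return "switcher_bidirectional"
    if escalations:
        return "switcher_escalation"
    if deescalations:
        return "switcher_deescalation"

    initiations = [i for i, (a, b, _) in enumerate(transitions) if a == "none"]
    discontinuations = [i for i, (a, b, _) in enumerate(transitions) if b == "none"]
    if initiations and not discontinuations:
        return "switcher_initiation"
    if discontinuations and not any(i > discontinuations[-1] for i in initiations):
        return "switcher_discontinuation"
    return "switcher_complex"


def summarize_exposure(
    record: PatientRecord,
    window: tuple[dt.date, dt.date],
    efficacy_map: Mapping[str, str] | None = None,
    gap_tolerance_days: int = 0,
) -> ExposureSummary:
    """Full exposure summary (fractions, flags, transitions, category) for a window."""
    start, end = window
    if start > end:
        raise ValueError("window start after end")

    if start == end:
        # Degenerate point window (landmark at baseline): classify by the
        # therapy in force at that instant.
        cls = baseline_dmt(record, start, efficacy_map)
        fractions = {c: 0.0 for c in (*EFFICACY_CLASSES, "none")}
        fractions[cls] = 1.0
        category = "never_treated" if cls == "none" else f"stable_{cls}"
        return ExposureSummary(
            window=window,
            fractions=fractions,
            treated_fraction=1.0 - fractions["none"],
            majority_class=cls,
            daae_switch_flag=False,
            elie_switch_flag=False,
            transitions=(),
            elie_category=category,
        )

    segments = _class_segments(record.treatments, window, efficacy_map)
    fractions = exposure_fractions(record.treatments, window, efficacy_map)
    treated = 1.0 - fractions["none"]
    states = _state_sequence(segments, window, gap_tolerance_days)
    transitions = _transitions(states)

    majority: str | None = None
    for state in (*EFFICACY_CLASSES, "none"):
        if fractions[state] > 0.5:
            majority = state
            break
    daae_switch = any(
        fractions[cls] > 0.25 for cls in EFFICACY_CLASSES if cls != majority
    )

    elie_switch = False
    if treated >= 0.5 and treated > 0:
        dominant = max(EFFICACY_CLASSES, key=lambda c: fractions[c])
        non_dominant = sum(
            fractions[c] for c in EFFICACY_CLASSES if c != dominant
        )
        elie_switch = non_dominant / treated >= 0.25

    category = _categorize(fractions, transitions, any_exposure=bool(segments))

    return ExposureSummary(
        window=window,
        fractions=fractions,
        treated_fraction=treated,
        majority_class=majority,
        daae_switch_flag=daae_switch,
        elie_switch_flag=elie_switch,
        transitions=tuple(transitions),
        elie_category=category,
    )


def elie_history_category(
    record: PatientRecord,
    landmark_date: dt.date,
    efficacy_map: Mapping[str, str] | None = None,
    gap_tolerance_days: int = 0,
) -> str:
    """Treatment-history category over baseline -> landmark (one of ten levels)."""
    return summarize_exposure(
        record,
        (record.baseline_date, landmark_date),
        efficacy_map,
        gap_tolerance_days,
    ).elie_category
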