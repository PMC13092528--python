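"""Dynamic landmark prediction of 5-year progression risk.

Every eligible clinical visit is a landmark: covariates are frozen at the
visit (age, disease duration, EDSS, age at onset, time since baseline, plus
the ten-level treatment-history category over baseline -> landmark) and the
outcome is progression within the following five years. Visits on or after
the patient's outcome date contribute no row, and event-free landmarks with
less than five years of remaining follow-up are censored (dropped) — this is
what shields the model from immortal-time bias.

The model is a class-weighted L1-penalized logistic regression, statsmodels
style: construct :class:`ElieModel` from the landmark rows, call
:meth:`~ElieModel.fit` (penalty chosen by patient-grouped cross-validation
under class-weighted log-loss), and get an :class:`ElieResults` carrying the
coefficients, the frozen preprocessing recipe, predictions and a summary
table. The preprocessing recipe — median imputation, one-hot category
encoding, standardization — is learned on training data only and applied
with the stored constants thereafter.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exposure import ELIE_CATEGORIES, elie_history_category
from .outcomes import ProgressionCriteria, detect_objective_progression
from .registry import PatientRecord

__all__ = [
    "CONTINUOUS_PREDICTORS",
    "build_landmark_dataset",
    "split_by_patient",
    "ElieModel",
    "ElieResults",
    "stratify_deciles",
]

CONTINUOUS_PREDICTORS = (
    "age",
    "disease_duration",
    "edss",
    "age_at_onset",
    "time_since_baseline",
)
REFERENCE_CATEGORY = "never_treated"


def _outcome_date(
    record: PatientRecord,
    outcome_source: str,
    criteria: ProgressionCriteria | None,
) -> dt.date | None:
    if outcome_source == "clinical":
        return record.spms_transition_date
    if outcome_source == "objective":
        event = detect_objective_progression(record, criteria)
        return event.event_date if event else None
    raise ValueError(f"unknown outcome source {outcome_source!r}")


def build_landmark_dataset(
    records: Sequence[PatientRecord],
    outcome_source: str = "clinical",
    horizon_years: float = 5.0,
    criteria: ProgressionCriteria | None = None,
) -> pd.DataFrame:
    """One row per eligible (patient, visit) landmark.

    Label = 1 iff the outcome falls in the half-open interval
    (landmark, landmark + horizon]. Rows are dropped when the visit is on or
    after the outcome date, or when an event-free patient has less than the
    full horizon of follow-up after the landmark (outcome indeterminate).
    Drop reasons are tallied in ``df.attrs["drops"]``.
    """
    horizon_days = round(horizon_years * 365.25)
    rows = []
    drops = {"on_or_after_outcome": 0, "insufficient_followup": 0, "missing_edss": 0}
    for rec in records:
        outcome = _outcome_date(rec, outcome_source, criteria)
        last = rec.last_visit_date
        if last is None:
            continue
        for visit in rec.visits_between(start=rec.baseline_date):
            if visit.edss is None:
                drops["missing_edss"] += 1
                continue
            if outcome is not None and visit.date >= outcome:
                drops["on_or_after_outcome"] += 1
                continue
            if outcome is not None:
                label = int(
                    0 < (outcome - visit.date).days <= horizon_days
                )
            else:
                if (last - visit.date).days < horizon_days:
                    drops["insufficient_followup"] += 1
                    continue
                label = 0
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "landmark_date": visit.date,
                    "age": rec.age_at(visit.date),
                    "disease_duration": rec.disease_duration_at(visit.date),
                    "edss": visit.edss,
                    "age_at_onset": rec.age_at_onset,
                    "time_since_baseline": (visit.date - rec.baseline_date).days
                    / 365.25,
                    "dmt_history_category": elie_history_category(rec, visit.date),
                    "outcome_label": label,
                    "outcome_source": outcome_source,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["drops"] = drops
    return df


def split_by_patient(
    rows: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition landmark rows by PATIENT (all of a patient's rows on one side)."""
    if rows.empty:
        raise ValueError("no landmark rows to split")
    patients = np.array(sorted(rows["patient_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n_train = int(round(train_fraction * len(patients)))
    train_ids = set(patients[:n_train])
    mask = rows["patient_id"].isin(train_ids)
    return rows[mask].reset_index(drop=True), rows[~mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Preprocessing recipe
# ---------------------------------------------------------------------------


@dataclass
class Recipe:
    """Preprocessing constants learned on training data only."""

    medians: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    categories: tuple[str, ...] = ELIE_CATEGORIES
    reference: str = REFERENCE_CATEGORY

    @classmethod
    def learn(cls, train: pd.DataFrame) -> "Recipe":
        medians, means, sds = {}, {}, {}
        for col in CONTINUOUS_PREDICTORS:
            x = train[col].astype(float)
            medians[col] = float(x.median())
            filled = x.fillna(medians[col])
            means[col] = float(filled.mean())
            sd = float(filled.std(ddof=0))
            sds[col] = sd if sd > 0 else 1.0
        return cls(medians=medians, means=means, sds=sds)

    @property
    def feature_names(self) -> list[str]:
        dummies = [
            f"category_{c}" for c in self.categories if c != self.reference
        ]
        return list(CONTINUOUS_PREDICTORS) + dummies

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        unknown = set(rows["dmt_history_category"]) - set(self.categories)
        if unknown:
            raise ValueError(
                f"unknown treatment-history categories {sorted(unknown)}; "
                "no silent reference coding"
            )
        cols = []
        for col in CONTINUOUS_PREDICTORS:
            x = rows[col].astype(float).fillna(self.medians[col])
            cols.append(((x - self.means[col]) / self.sds[col]).to_numpy())
        for cat in self.categories:
            if cat == self.reference:
                continue
            cols.append(
                (rows["dmt_history_category"] == cat).to_numpy(dtype=float)
            )
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ElieModel:
    """Class-weighted L1 logistic landmark risk model (unfitted).

    Parameters
    ----------
    rows : DataFrame from :func:`build_landmark_dataset` (must carry
        ``patient_id``, the five continuous predictors,
        ``dmt_history_category`` and ``outcome_label``).
    """

    def __init__(self, rows: pd.DataFrame):
        required = {
            "patient_id",
            "dmt_history_category",
            "outcome_label",
            *CONTINUOUS_PREDICTORS,
        }
        missing = required - set(rows.columns)
        if missing:
            raise ValueError(f"landmark rows missing columns {sorted(missing)}")
        self.rows = rows.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Sequence[PatientRecord],
        outcome_source: str = "clinical",
        horizon_years: float = 5.0,
        criteria: ProgressionCriteria | None = None,
    ) -> "ElieModel":
        return cls(
            build_landmark_dataset(records, outcome_source, horizon_years, criteria)
        )

    def fit(
        self,
        seed: int = 0,
        n_folds: int = 5,
        n_penalties: int = 100,
        penalty_range: tuple[float, float] = (1e-4, 1e2),
    ) -> "ElieResults":
        """Learn the recipe, choose the L1 penalty by patient-grouped CV
        under class-weighted log-loss, and fit the final model.

        Folds never split a patient; class weights are n / (2 * n_class).
        Deterministic for a fixed seed.
        """
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import GroupKFold

        y = self.rows["outcome_label"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training outcome has a single class")
        groups = self.rows["patient_id"].to_numpy()
        if len(np.unique(groups)) < n_folds:
            raise ValueError("need at least n_folds distinct patients")

        recipe = Recipe.learn(self.rows)
        X = recipe.transform(self.rows)

        n = len(y)
        n_pos = int(y.sum())
        class_weights = {0: n / (2 * (n - n_pos)), 1: n / (2 * n_pos)}
        sample_w = np.where(y == 1, class_weights[1], class_weights[0])

        penalties = np.logspace(
            math.log10(penalty_range[0]), math.log10(penalty_range[1]), n_penalties
        )
        cv = GroupKFold(n_splits=n_folds)
        losses = np.zeros(n_penalties)
        for train_idx, val_idx in cv.split(X, y, groups):
            ytr = y[train_idx]
            if len(np.unique(ytr)) < 2:
                continue
            for i, lam in enumerate(penalties):
                model = LogisticRegression(
                    l1_ratio=1.0,
                    C=1.0 / (lam * len(train_idx)),
                    solver="liblinear",
                    class_weight=class_weights,
                    random_state=seed,
                )
                model.fit(X[train_idx], ytr)
                p = np.clip(model.predict_proba(X[val_idx])[:, 1], 1e-12, 1 - 1e-12)
                yv = y[val_idx]
                wv = sample_w[val_idx]
                losses[i] += -np.sum(
                    wv * (yv * np.log(p) + (1 - yv) * np.log(1 - p))
                )

        best = int(np.argmin(losses))
        lam = float(penalties[best])
        final = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (lam * n),
            solver="liblinear",
            class_weight=class_weights,
            random_state=seed,
        )
        final.fit(X, y)

        params = pd.Series(
            np.concatenate([final.intercept_, final.coef_.ravel()]),
            index=["intercept"] + recipe.feature_names,
        )
        return ElieResults(
            model=self,
            recipe=recipe,
            params=params,
            penalty=lam,
            class_weights=class_weights,
            cv_losses=pd.Series(losses, index=penalties),
            seed=seed,
            n_folds=n_folds,
        )


@dataclass
class ElieResults:
    """Fitted landmark risk model: coefficients, recipe, diagnostics."""

    model: ElieModel
    recipe: Recipe
    params: pd.Series
    penalty: float
    class_weights: dict[int, float]
    cv_losses: pd.Series
    seed: int
    n_folds: int
    _extra: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted 5-year progression probability per landmark row."""
        data = self.model.rows if rows is None else rows
        X = self.recipe.transform(data)
        eta = self.params["intercept"] + X @ self.params.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            "Landmark progression risk model (class-weighted L1 logistic)",
            f"  rows: {len(self.model.rows)}   "
            f"patients: {self.model.rows['patient_id'].nunique()}   "
            f"events: {int(self.model.rows['outcome_label'].sum())}",
            f"  penalty (lambda): {self.penalty:.6g}   "
            f"grouped CV folds: {self.n_folds}   seed: {self.seed}",
            f"  class weights: 0 -> {self.class_weights[0]:.3f}, "
            f"1 -> {self.class_weights[1]:.3f}",
            "",
            "  coefficient                      value",
            "  " + "-" * 42,
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:<30s} {value:>10.4f}")
        nonzero = int((self.params.iloc[1:] != 0).sum())
        lines.append("")
        lines.append(
            f"  {nonzero}/{len(self.params) - 1} slope coefficients retained"
        )
        return "\n".join(lines)

    def to_card(self) -> dict:
        """Portable model card (JSON-serializable)."""
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "penalty": self.penalty,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "recipe": {
                "medians": self.recipe.medians,
                "means": self.recipe.means,
                "sds": self.recipe.sds,
                "categories": list(self.recipe.categories),
                "reference": self.recipe.reference,
            },
            "seed": self.seed,
            "n_folds": self.n_folds,
        }

    @classmethod
    def from_card(cls, card: dict, rows: pd.DataFrame) -> "ElieResults":
        recipe = Recipe(
            medians=card["recipe"]["medians"],
            means=card["recipe"]["means"],
            sds=card["recipe"]["sds"],
            categories=tuple(card["recipe"]["categories"]),
            reference=card["recipe"]["reference"],
        )
        params = pd.Series(card["params"])
        return cls(
            model=ElieModel(rows),
            recipe=recipe,
            params=params,
            penalty=card["penalty"],
            class_weights={int(k): v for k, v in card["class_weights"].items()},
            cv_losses=pd.Series(dtype=float),
            seed=card["seed"],
            n_folds=card["n_folds"],
        )


def stratify_deciles(
    train_predictions: Sequence[float],
    test_predictions: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Decile assignment (1..10) by training-prediction quantile boundaries.

    Boundaries are the 10/20/.../90% training quantiles; test rows are binned
    by those same boundaries (values below the first boundary go to decile 1,
    above the last to decile 10). Returns (train deciles, test deciles or
    None, boundaries). Fewer than 10 distinct prediction values triggers a
    merged-bin warning.
    """
    import warnings

    train = np.asarray(train_predictions, dtype=float)
    boundaries = np.quantile(train, np.linspace(0.1, 0.9, 9))
    if len(np.unique(train)) < 10:
        warnings.warn("fewer than 10 distinct predictions; deciles merge bins")
    train_dec = np.searchsorted(boundaries, train, side="right") + 1
    test_dec = None
    if test_predictions is not None:
        test = np.asarray(test_predictions, dtype=float)
        test_dec = np.searchsorted(boundaries, test, side="right") + 1
    return train_dec, test_dec, boundaries
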