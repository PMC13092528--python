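"""Propensity-score matching to mitigate indication bias.

Sicker patients are preferentially escalated to high-efficacy therapy, so raw
between-class comparisons are confounded. The propensity of treatment is
modelled by logistic regression on four baseline covariates (age, sex,
disease duration, EDSS); treated patients are then greedily matched 1:1
without replacement to the nearest unmatched control on the logit of the
score, and covariate balance is reported as standardized mean differences
before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROPENSITY_COVARIATES",
    "MatchedCohort",
    "estimate_propensity",
    "match_nearest_neighbor",
    "standardized_mean_differences",
]

PROPENSITY_COVARIATES = ("age", "sex", "disease_duration", "edss")


@dataclass
class MatchedCohort:
    pairs: list[tuple[str, str, float]]  # (treated_id, control_id, |logit diff|)
    unmatched_ids: list[str]
    balance: pd.DataFrame  # SMD before/after per covariate

    @property
    def treated_ids(self) -> list[str]:
        return [t for t, _, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c, _ in self.pairs]


def _design(covariates: pd.DataFrame) -> np.ndarray:
    df = covariates.copy()
    if df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "female").astype(float)
    return df[list(PROPENSITY_COVARIATES)].to_numpy(dtype=float)


def estimate_propensity(
    covariates: pd.DataFrame, treatment_label: Sequence[int]
) -> np.ndarray:
    """Per-patient probability of treatment given the four baseline covariates.

    ``covariates`` must carry columns age, sex, disease_duration, edss (sex as
    female/male strings or 0/1). Perfect separation or non-convergence in the
    maximum-likelihood fit triggers a warning and a ridge-penalized fallback.
    """
    import statsmodels.api as sm

    y = np.asarray(treatment_label, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("treatment label must contain both classes")
    X = _design(covariates)

    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, sm.add_constant(X)).fit(disp=False, maxiter=100)
            probs = np.asarray(fit.predict(sm.add_constant(X)))
            if np.all(np.isfinite(probs)) and probs.min() > 0 and probs.max() < 1:
                return probs
            raise RuntimeError("degenerate fitted probabilities")
        except Exception:
            pass

    warnings.warn(
        "propensity model did not converge cleanly (possible perfect "
        "separation); falling back to a ridge-penalized logistic fit",
        stacklevel=2,
    )
    from sklearn.linear_model import LogisticRegression

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    model = LogisticRegression(C=1.0, max_iter=1000)
    model.fit((X - mu) / sd, y)
    return model.predict_proba((X - mu) / sd)[:, 1]


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def standardized_mean_differences(
    covariates: pd.DataFrame,
    treated_mask: np.ndarray,
) -> pd.Series:
    """Absolute SMD per covariate: |mean_t - mean_c| / pooled SD."""
    X = _design(covariates)
    t, c = X[treated_mask], X[~treated_mask]
    pooled = np.sqrt((t.var(ddof=1, axis=0) + c.var(ddof=1, axis=0)) / 2)
    pooled[pooled == 0] = 1.0
    smd = np.abs(t.mean(axis=0) - c.mean(axis=0)) / pooled
    return pd.Series(smd, index=list(PROPENSITY_COVARIATES))


def match_nearest_neighbor(
    treated_scores: dict[str, float],
    control_scores: dict[str, float],
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated patients are processed in a seed-randomized order; each is matched
    to the nearest unmatched control by absolute difference of logit
    propensity scores, ties broken by lowest control id. When ``covariates``
    (indexed by patient id, with a boolean ``treated`` column implied by group
    membership) are supplied, the balance table holds SMDs before and after.
    """
    if not treated_scores or not control_scores:
        raise ValueError("both groups must be non-empty")

    rng = np.random.default_rng(seed)
    treated_ids = list(treated_scores)
    rng.shuffle(treated_ids)

    control_ids = sorted(control_scores)
    control_logits = _logit(np.array([control_scores[c] for c in control_ids]))
    available = np.ones(len(control_ids), dtype=bool)

    pairs: list[tuple[str, str, float]] = []
    unmatched: list[str] = []
    for tid in treated_ids:
        if not available.any():
            unmatched.append(tid)
            continue
        t_logit = _logit(np.array([treated_scores[tid]]))[0]
        dist = np.abs(control_logits - t_logit)
        dist[~available] = np.inf
        # argmin returns the first (lowest-id) minimiser: ids are sorted.
        j = int(np.argmin(dist))
        available[j] = False
        pairs.append((tid, control_ids[j], float(dist[j])))

    balance = pd.DataFrame()
    if covariates is not None:
        all_ids = list(treated_scores) + list(control_scores)
        pre = covariates.loc[all_ids]
        pre_mask = np.array([pid in treated_scores for pid in all_ids])
        matched_ids = [t for t, _, _ in pairs] + [c for _, c, _ in pairs]
        post = covariates.loc[matched_ids]
        post_mask = np.array([True] * len(pairs) + [False] * len(pairs))
        balance = pd.DataFrame(
            {
                "smd_before": standardized_mean_differences(pre, pre_mask),
                "smd_after": standardized_mean_differences(post, post_mask),
            }
        )

    return MatchedCohort(pairs=pairs, unmatched_ids=unmatched, balance=balance)
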