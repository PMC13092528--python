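"""Calibration and discrimination validation protocol.

Observed event proportions get Wilson 95% intervals; predicted vs observed
risks are compared with pooled two-proportion z-tests, Bonferroni-adjusted
across strata. Discrimination is AUROC and accuracy with stratified
percentile-bootstrap CIs, after class rebalancing by synthetic minority
oversampling plus Tomek-link removal (k = 10). Missing covariates are
multiply imputed by chained equations with predictive mean matching, pooled
by Rubin's rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "observed_proportion_ci",
    "two_proportion_ztest",
    "brier_score",
    "smote_tomek_balance",
    "auroc_accuracy",
    "mice_impute",
    "pool_estimates",
    "CalibrationTable",
    "calibration_report",
]


def observed_proportion_ci(
    events: int, n: int, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Observed proportion with a Wilson score interval.

    Wilson is used for its coverage at small counts; it is oracle-checked
    against the exact (Clopper-Pearson) interval in the test suite.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(events, n, alpha=1 - level, method="wilson")
    lo = 0.0 if events == 0 else max(0.0, float(lo))
    hi = 1.0 if events == n else min(1.0, float(hi))
    return events / n, (lo, hi)


def two_proportion_ztest(
    x1: int, n1: int, x2: int, n2: int
) -> tuple[float, float]:
    """Two-sided pooled-variance z-test for two independent proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    from scipy.stats import norm

    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return z, 2 * float(norm.sf(abs(z)))


def brier_score(predictions: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# SMOTE + Tomek links
# ---------------------------------------------------------------------------


def smote_tomek_balance(
    features: np.ndarray,
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a binary problem: synthetic minority oversampling, then
    Tomek-link removal.

    Synthetic minority points are convex interpolations between a random
    minority point and one of its ``k`` minority nearest neighbours, generated
    until the classes are equal in count. A Tomek link is a cross-class
    mutual-nearest-neighbour pair; both members of each link are removed.
    Original minority points are never all removed, and synthetic points are
    created only in the minority class.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k:
        raise ValueError(
            f"minority class has {n_min} members, need more than k={k}; "
            "use a smaller k"
        )

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    n_new = n_maj - n_min
    if n_new > 0:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)  # first neighbour is the point itself
        base = rng.integers(0, len(X_min), size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)
        lam = rng.random(size=n_new)[:, None]
        neighbours = X_min[idx[base, pick]]
        synthetic = X_min[base] + lam * (neighbours - X_min[base])
        X = np.vstack([X, synthetic])
        y = np.concatenate([y, np.full(n_new, minority)])

    # Tomek links: cross-class mutual nearest neighbours.
    nn_all = NearestNeighbors(n_neighbors=2).fit(X)
    _, idx = nn_all.kneighbors(X)
    nearest = idx[:, 1]
    drop = np.zeros(len(X), dtype=bool)
    for i in range(len(X)):
        j = nearest[i]
        if nearest[j] == i and y[i] != y[j]:
            drop[i] = drop[j] = True
    # Never remove every original minority point.
    orig_minority = np.flatnonzero(np.asarray(labels, dtype=int) == minority)
    if drop[orig_minority].all():
        drop[orig_minority[0]] = False
    return X[~drop], y[~drop]


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


def auroc_accuracy(
    predictions: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """AUROC and accuracy-at-threshold with stratified percentile bootstrap CIs."""
    from sklearn.metrics import roc_auc_score

    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    auroc = float(roc_auc_score(y, p))
    accuracy = float(np.mean((p >= threshold).astype(int) == y))

    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    accs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc_score(y[idx], p[idx])
        accs[b] = np.mean((p[idx] >= threshold).astype(int) == y[idx])
    return {
        "auroc": auroc,
        "auroc_ci": (float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975))),
        "accuracy": accuracy,
        "accuracy_ci": (
            float(np.quantile(accs, 0.025)),
            float(np.quantile(accs, 0.975)),
        ),
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# Multiple imputation
# ---------------------------------------------------------------------------


def mice_impute(
    table: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    sweeps: int = 10,
    max_missing_fraction: float = 0.5,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Chained-equations multiple imputation (predictive mean matching).

    Returns ``m`` completed copies of the table plus a pooled per-column
    summary (Rubin's rules on the column means). Columns with no observed
    value, or tables exceeding the missingness ceiling, are rejected.
    Determinism: the global NumPy seed is set per copy from ``seed``.
    """
    from statsmodels.imputation.mice import MICEData

    df = table.copy()
    numeric = df.select_dtypes(include=[np.number]).columns
    if len(numeric) != df.shape[1]:
        raise ValueError("all columns must be numeric for imputation")
    if df.isna().all().any():
        raise ValueError("a column is entirely missing")
    frac = df.isna().to_numpy().mean()
    if frac > max_missing_fraction:
        raise ValueError(
            f"missingness {frac:.0%} exceeds ceiling {max_missing_fraction:.0%}"
        )

    if not df.isna().any().any():
        completed = [df.copy() for _ in range(m)]
    else:
        completed = []
        for i in range(m):
            np.random.seed((seed + 1000003 * i) % (2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imp = MICEData(df)
                imp.update_all(sweeps)
            completed.append(imp.data.copy())

    means = np.array([c.mean().to_numpy() for c in completed])
    variances = np.array(
        [c.var(ddof=1).to_numpy() / len(c) for c in completed]
    )
    pooled = pd.DataFrame(
        [
            pool_estimates(means[:, j], variances[:, j])
            for j in range(df.shape[1])
        ],
        index=df.columns,
    )
    return completed, pooled


def pool_estimates(estimates: Sequence[float], variances: Sequence[float]) -> dict:
    """Rubin's rules: pooled estimate, within/between variance, total SE."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    qbar = q.mean()
    within = u.mean()
    between = q.var(ddof=1) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    return {
        "estimate": float(qbar),
        "within_var": float(within),
        "between_var": float(between),
        "se": float(math.sqrt(total)),
    }


# ---------------------------------------------------------------------------
# Calibration report
# ---------------------------------------------------------------------------


@dataclass
class CalibrationTable:
    table: pd.DataFrame  # one row per stratum
    monotone: bool
    brier: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def calibration_report(
    strata: Sequence[str],
    predicted: Sequence[float],
    observed_events: Sequence[int],
    n: Sequence[int],
    bonferroni_m: int | None = None,
) -> CalibrationTable:
    """Observed vs predicted risk per ordered stratum.

    Per stratum: observed proportion with Wilson CI, a one-sample z-test of
    the observed count against the predicted proportion, raw and
    Bonferroni-adjusted p-values (m defaults to the number of strata), and a
    flag for monotone non-decreasing observed risk across the given order.
    Predicted and observed are on the proportion scale (0-1).
    """
    from scipy.stats import norm

    m = bonferroni_m if bonferroni_m is not None else len(strata)
    rows = []
    observed_props = []
    for stratum, pred, x, size in zip(strata, predicted, observed_events, n):
        obs, (lo, hi) = observed_proportion_ci(x, size)
        se = math.sqrt(pred * (1 - pred) / size) if 0 < pred < 1 else 0.0
        z = (obs - pred) / se if se > 0 else 0.0
        p_raw = 2 * float(norm.sf(abs(z))) if se > 0 else 1.0
        rows.append(
            {
                "stratum": stratum,
                "n": size,
                "events": x,
                "observed": obs,
                "ci_low": lo,
                "ci_high": hi,
                "predicted": pred,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m * p_raw),
            }
        )
        observed_props.append(obs)
    monotone = all(a <= b for a, b in zip(observed_props, observed_props[1:]))
    return CalibrationTable(table=pd.DataFrame(rows), monotone=monotone)
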