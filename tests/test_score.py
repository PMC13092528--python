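"""Point score, risk groups, embedded reference tables, risk ratios."""

import math

import numpy as np
import pytest

from msprogrisk import (
    CLINICAL_RISK_SCHEMA,
    DEMO_WEIGHT_TABLE,
    OBJECTIVE_RISK_SCHEMA,
    RISK_TABLE,
    assign_risk_group,
    compute_daae_score,
    derive_score_weights,
    lookup_risk,
    risk_ratio,
)
from msprogrisk.score import (
    DMT_CONTEXTS,
    RISK_GROUPS,
    SCORE_FEATURES,
    UnsupportedContextError,
    WeightTable,
)

# Printed risk-ratio comparisons: (outcome, numerator context, denominator
# context, risk group, printed RR). The printed RRs were computed upstream
# from unrounded proportions, so each is checked for consistency with the
# interval the rounded table cells induce; the bulk also reproduce exactly at
# printed precision.
PRINTED_RRS = [
    ("clinical", "majority_high", "majority_low", "very_low", 0.54),
    ("clinical", "majority_high", "majority_low", "low", 0.64),
    ("clinical", "majority_high", "majority_low", "medium", 0.73),
    ("clinical", "majority_high", "majority_low", "high", 0.37),
    ("clinical", "majority_none", "majority_low", "very_low", 1.58),
    ("clinical", "majority_none", "majority_low", "low", 1.62),
    ("clinical", "majority_none", "majority_low", "medium", 1.46),
    ("clinical", "majority_none", "majority_low", "high", 0.86),
    ("objective", "majority_high", "majority_low", "low", 0.34),
    ("objective", "majority_high", "majority_low", "high", 0.49),
    ("objective", "majority_none", "majority_low", "very_low", 3.4),
    ("objective", "majority_none", "majority_low", "medium", 1.4),
    ("objective", "baseline_high", "baseline_low", "low", 0.49),
]

EXACT_RRS = [
    row for row in PRINTED_RRS if row[4] not in (0.54, 3.4)
    and not (row[:4] == ("objective", "majority_high", "majority_low", "high"))
]


def _decimals(x: float) -> int:
    text = f"{x}"
    return len(text.split(".")[1]) if "." in text else 0


class TestScore:
    def test_zero_point_bins_give_zero(self):
        assert compute_daae_score(1.0, 25.0, 24.0, 1.0) == 0

    def test_maximal_bins_give_twelve(self):
        assert compute_daae_score(25.0, 60.0, 45.0, 7.0) == 12

    def test_random_vectors_match_bin_lookup_resummation(self):
        """Score equals an independent re-summation of per-feature lookups."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            duration = float(rng.uniform(0, 40))
            age = float(rng.uniform(18, 80))
            onset = float(rng.uniform(5, 60))
            edss = float(rng.integers(0, 17)) / 2

            def lookup(pairs, value):
                for edge, pts in pairs:
                    if value < edge:
                        return pts
                raise AssertionError

            expected = sum(
                lookup(DEMO_WEIGHT_TABLE.bins[f], v)
                for f, v in zip(
                    SCORE_FEATURES, (duration, age, onset, edss)
                )
            )
            assert compute_daae_score(duration, age, onset, edss) == min(
                12, expected
            )

    def test_monotone_in_edss(self):
        grid = [i / 2 for i in range(0, 17)]
        scores = [compute_daae_score(5.0, 40.0, 35.0, e) for e in grid]
        assert scores == sorted(scores)

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_daae_score(float("nan"), 40.0, 35.0, 2.0)

    from hypothesis import given, settings, strategies as st

    @given(
        st.floats(0, 60),
        st.floats(18, 90),
        st.floats(5, 70),
        st.integers(0, 20).map(lambda k: k / 2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_score_always_integer_in_range(self, duration, age, onset, edss):
        score = compute_daae_score(duration, age, onset, edss)
        assert isinstance(score, int) and 0 <= score <= 12


class TestRiskGroups:
    @pytest.mark.parametrize(
        "score,schema,expected",
        [
            (2, CLINICAL_RISK_SCHEMA, "very_low"),
            (3, CLINICAL_RISK_SCHEMA, "low"),
            (8, CLINICAL_RISK_SCHEMA, "medium"),
            (10, CLINICAL_RISK_SCHEMA, "high"),
            (1, OBJECTIVE_RISK_SCHEMA, "very_low"),
            (2, OBJECTIVE_RISK_SCHEMA, "low"),
            (5, OBJECTIVE_RISK_SCHEMA, "medium"),
            (7, OBJECTIVE_RISK_SCHEMA, "high"),
        ],
    )
    def test_cutoffs(self, score, schema, expected):
        assert assign_risk_group(score, schema) == expected


class TestRiskTable:
    @pytest.mark.parametrize(
        "group,outcome,context,expected",
        [
            ("medium", "clinical", "unspecified", (22.6, (21.1, 24.1))),
            ("low", "clinical", "majority_none", (16.7, (14.6, 19.0))),
            ("high", "objective", "majority_high", (13.8, (9.9, 18.5))),
            ("very_low", "clinical", "unspecified", (3.1, (2.9, 3.4))),
            ("high", "objective", "unspecified", (38.8, (37.5, 40.1))),
        ],
    )
    def test_lookup_values(self, group, outcome, context, expected):
        assert lookup_risk(group, outcome, context) == expected

    def test_switch_context_unsupported(self):
        with pytest.raises(UnsupportedContextError):
            lookup_risk("low", "clinical", "majority_switch")

    def test_table_complete(self):
        """Every (outcome, context, group) cell of the reference tables."""
        assert len(RISK_TABLE) == 2 * len(DMT_CONTEXTS) * len(RISK_GROUPS)
        for (outcome, context, group), (risk, lo, hi) in RISK_TABLE.items():
            assert lo <= risk <= hi

    def test_most_contexts_monotone_across_groups(self):
        from msprogrisk.score import NON_MONOTONE_CONTEXTS

        for outcome in ("clinical", "objective"):
            for context in DMT_CONTEXTS:
                risks = [
                    lookup_risk(g, outcome, context)[0] for g in RISK_GROUPS
                ]
                if (outcome, context) in NON_MONOTONE_CONTEXTS:
                    assert risks != sorted(risks)  # stored verbatim, flagged
                else:
                    assert risks == sorted(risks)


class TestRiskRatios:
    @pytest.mark.parametrize("outcome,num,den,group,printed", EXACT_RRS)
    def test_printed_rr_reproduced_at_printed_precision(
        self, outcome, num, den, group, printed
    ):
        p1 = lookup_risk(group, outcome, num)[0]
        p2 = lookup_risk(group, outcome, den)[0]
        assert round(risk_ratio(p1, p2), _decimals(printed)) == printed

    @pytest.mark.parametrize("outcome,num,den,group,printed", PRINTED_RRS)
    def test_printed_rr_consistent_with_cell_rounding(
        self, outcome, num, den, group, printed
    ):
        """The interval of RRs achievable from the rounded table cells must
        overlap the printed RR's rounding interval (the published RRs were
        computed from unrounded proportions)."""
        p1 = lookup_risk(group, outcome, num)[0]
        p2 = lookup_risk(group, outcome, den)[0]
        rr_lo = (p1 - 0.05) / (p2 + 0.05)
        rr_hi = (p1 + 0.05) / (p2 - 0.05)
        half_ulp = 0.5 * 10 ** (-_decimals(printed))
        assert rr_lo <= printed + half_ulp and rr_hi >= printed - half_ulp

    def test_equal_risks_give_unity(self):
        assert risk_ratio(12.5, 12.5) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            risk_ratio(1.0, 0.0)

    def test_log_normal_ci_close_to_bootstrap(self):
        """Log-RR normal CI vs a 100,000-resample percentile bootstrap."""
        x1, n1, x2, n2 = 66, 1000, 103, 1000
        rr, (lo, hi), p = risk_ratio(x1 / n1, x2 / n2, counts=(x1, n1, x2, n2))
        rng = np.random.default_rng(0)
        b1 = rng.binomial(n1, x1 / n1, size=100_000) / n1
        b2 = rng.binomial(n2, x2 / n2, size=100_000) / n2
        boot = b1 / np.maximum(b2, 1e-12)
        blo, bhi = np.quantile(boot, [0.025, 0.975])
        assert abs(lo - blo) < 0.02 and abs(hi - bhi) < 0.02
        assert rr == pytest.approx(0.64, abs=0.005)
        assert p < 0.01


class TestWeightDerivation:
    @staticmethod
    def _synthetic_rows(n=3000, seed=0, edss_beta=1.2, null=False):
        rng = np.random.default_rng(seed)
        duration = rng.gamma(1.5, 4, n)
        age = rng.normal(40, 10, n)
        onset = np.clip(age - duration, 10, None)
        edss = np.round(np.clip(rng.gamma(2, 1.1, n), 0, 8) * 2) / 2
        if null:
            eta = np.full(n, -1.5)
        else:
            eta = -3.0 + edss_beta * (edss - 2) + 0.02 * (age - 40)
        label = rng.random(n) < 1 / (1 + np.exp(-eta))
        return {
            "disease_duration": duration,
            "age": age,
            "age_at_onset": onset,
            "edss": edss,
            "label": label.astype(int),
        }

    def test_edss_dominant_signal_gets_largest_share(self):
        report = derive_score_weights(self._synthetic_rows())
        shares = {
            f: max(p for _, p in report.table.bins[f]) for f in SCORE_FEATURES
        }
        assert shares["edss"] == max(shares.values())
        assert not report.degenerate

    def test_outcome_independent_of_features_flags_degenerate(self):
        report = derive_score_weights(
            self._synthetic_rows(null=True), alpha=0.05
        )
        assert report.degenerate
        assert report.table.degenerate

    def test_all_identical_labels_rejected(self):
        rows = self._synthetic_rows(n=100)
        rows["label"] = np.zeros(100, dtype=int)
        with pytest.raises(ValueError, match="degenerate outcome"):
            derive_score_weights(rows)

    def test_derived_scores_stratify_heldout_risk(self):
        """Monotone observed risk across the four clinical risk groups on
        held-out data scored with a freshly derived table."""
        report = derive_score_weights(self._synthetic_rows(seed=1))
        held = self._synthetic_rows(n=4000, seed=2)
        scores = [
            compute_daae_score(d, a, o, e, weights=report.table)
            for d, a, o, e in zip(
                held["disease_duration"], held["age"], held["age_at_onset"], held["edss"]
            )
        ]
        groups = [assign_risk_group(s, CLINICAL_RISK_SCHEMA) for s in scores]
        rates = []
        for g in ("very_low", "low", "medium", "high"):
            mask = np.array(groups) == g
            if mask.sum() >= 30:
                rates.append(held["label"][mask].mean())
        assert len(rates) >= 3
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))


class TestWeightTableValidation:
    def test_overweight_table_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            WeightTable(
                bins={
                    "disease_duration": ((math.inf, 5),),
                    "age": ((math.inf, 5),),
                    "age_at_onset": ((math.inf, 2),),
                    "edss": ((math.inf, 4),),
                }
            )

    def test_value_outside_coverage_named(self):
        table = WeightTable(
            bins={
                "disease_duration": ((10.0, 0),),
                "age": ((math.inf, 0),),
                "age_at_onset": ((math.inf, 0),),
                "edss": ((math.inf, 0),),
            }
        )
        with pytest.raises(ValueError, match="disease_duration"):
            table.points("disease_duration", 11.0)
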