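"""Landmark dataset construction, leakage audits, and the risk model."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from msprogrisk import ElieModel, build_landmark_dataset, split_by_patient
from msprogrisk.landmark import Recipe, stratify_deciles
from msprogrisk.registry import FS_NAMES, PatientRecord, Visit

B = dt.date(2020, 1, 1)
Y = 365  # approximate year in days for visit spacing


def _rec(pid, visit_days, edss=2.0, spms=None):
    return PatientRecord(
        patient_id=pid,
        sex="female",
        birth_date=dt.date(1985, 1, 1),
        onset_date=dt.date(2014, 1, 1),
        baseline_date=B,
        course_at_baseline="RRMS",
        visits=[Visit(B + dt.timedelta(days=d), edss) for d in visit_days],
        spms_transition_date=spms,
    )


class TestDatasetConstruction:
    def test_event_within_horizon_labelled_one(self):
        spms = B + dt.timedelta(days=3 * Y)
        rec = _rec("a", [0, 180], spms=spms)
        rows = build_landmark_dataset([rec], "clinical")
        assert len(rows) == 2
        assert (rows["outcome_label"] == 1).all()

    def test_event_free_short_followup_dropped(self):
        rec = _rec("a", [0, 180, 2 * Y])  # last visit 2 y after baseline
        rows = build_landmark_dataset([rec], "clinical")
        assert rows.empty
        assert rows.attrs["drops"]["insufficient_followup"] == 3

    def test_visits_after_outcome_excluded(self):
        spms = B + dt.timedelta(days=400)
        rec = _rec("a", [0, 180, 500, 700], spms=spms)
        rows = build_landmark_dataset([rec], "clinical")
        assert set(rows["landmark_date"]) == {
            B,
            B + dt.timedelta(days=180),
        }

    def test_event_beyond_horizon_labels_zero(self):
        spms = B + dt.timedelta(days=2200)  # > 1826 d after baseline
        rec = _rec("a", [0, 2100], spms=spms)
        rows = build_landmark_dataset([rec], "clinical")
        row0 = rows[rows["landmark_date"] == B].iloc[0]
        assert row0["outcome_label"] == 0
        # a later landmark brings the event inside its horizon
        row1 = rows[rows["landmark_date"] == B + dt.timedelta(days=2100)].iloc[0]
        assert row1["outcome_label"] == 1

    def test_covariates_frozen_at_landmark(self):
        spms = B + dt.timedelta(days=3 * Y)
        rec = _rec("a", [0, 365], spms=spms)
        rows = build_landmark_dataset([rec], "clinical")
        first, second = rows.sort_values("landmark_date").itertuples(index=False)
        assert second.age == pytest.approx(first.age + 365 / 365.25, abs=1e-9)
        assert second.time_since_baseline == pytest.approx(365 / 365.25)

    def test_post_landmark_permutation_leaves_rows_unchanged(self, included_records):
        """No predictor or label uses information after landmark + horizon:
        rewriting each patient's trajectory after the last landmark's horizon
        leaves the landmark rows bit-identical."""
        records = included_records[:40]
        rows = build_landmark_dataset(records, "clinical")
        horizon = dt.timedelta(days=1826)
        mutated = []
        for rec in records:
            keep = rows[rows.patient_id == rec.patient_id]
            if keep.empty:
                mutated.append(rec)
                continue
            cutoff = max(keep["landmark_date"]) + horizon
            new_visits = [v for v in rec.visits if v.date <= cutoff]
            # append garbage far beyond every horizon
            new_visits.append(
                Visit(cutoff + dt.timedelta(days=400), 9.0,
                      {name: 6 for name in FS_NAMES})
            )
            mutated.append(
                PatientRecord(
                    patient_id=rec.patient_id,
                    sex=rec.sex,
                    birth_date=rec.birth_date,
                    onset_date=rec.onset_date,
                    baseline_date=rec.baseline_date,
                    course_at_baseline=rec.course_at_baseline,
                    visits=new_visits,
                    relapses=list(rec.relapses),
                    treatments=list(rec.treatments),
                    spms_transition_date=rec.spms_transition_date,
                )
            )
        rows2 = build_landmark_dataset(mutated, "clinical")
        a = rows.sort_values(["patient_id", "landmark_date"]).reset_index(drop=True)
        b = rows2.sort_values(["patient_id", "landmark_date"]).reset_index(drop=True)
        common = a.merge(
            b,
            on=["patient_id", "landmark_date"],
            suffixes=("_a", "_b"),
            how="inner",
        )
        assert len(common) >= len(a) * 0.9
        for col in ("age", "edss", "dmt_history_category", "outcome_label"):
            assert (common[f"{col}_a"] == common[f"{col}_b"]).all()


class TestSplit:
    @pytest.mark.parametrize("seed", range(20))
    def test_patient_disjoint_for_many_seeds(self, seed, included_records):
        rows = build_landmark_dataset(included_records[:120], "clinical")
        train, test = split_by_patient(rows, seed=seed)
        assert set(train.patient_id).isdisjoint(set(test.patient_id))
        assert len(train) + len(test) == len(rows)

    def test_eighty_twenty_patient_counts(self):
        records = [
            _rec(f"p{i}", [0, 180], spms=B + dt.timedelta(days=600))
            for i in range(100)
        ]
        rows = build_landmark_dataset(records, "clinical")
        train, test = split_by_patient(rows, seed=3)
        assert train.patient_id.nunique() == 80
        assert test.patient_id.nunique() == 20

    def test_same_seed_same_split(self, included_records):
        rows = build_landmark_dataset(included_records[:60], "clinical")
        a_train, _ = split_by_patient(rows, seed=7)
        b_train, _ = split_by_patient(rows, seed=7)
        pd.testing.assert_frame_equal(a_train, b_train)


def _toy_rows(n_patients=60, rows_per_patient=3, seed=0, signal=1.5):
    """Synthetic landmark rows with a known EDSS effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        edss_base = rng.uniform(0, 6)
        for j in range(rows_per_patient):
            edss = round(min(9.5, edss_base + 0.5 * j) * 2) / 2
            eta = -2.0 + signal * (edss - 2.5)
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "landmark_date": B + dt.timedelta(days=180 * j),
                    "age": float(rng.normal(40, 10)),
                    "disease_duration": float(rng.gamma(2, 3)),
                    "edss": edss,
                    "age_at_onset": float(rng.normal(30, 8)),
                    "time_since_baseline": 180 * j / 365.25,
                    "dmt_history_category": str(
                        rng.choice(["never_treated", "stable_low", "stable_high"])
                    ),
                    "outcome_label": int(rng.random() < 1 / (1 + np.exp(-eta))),
                    "outcome_source": "clinical",
                }
            )
    df = pd.DataFrame(rows)
    # guarantee both classes
    df.loc[df.index[0], "outcome_label"] = 0
    df.loc[df.index[1], "outcome_label"] = 1
    return df


class TestModelFit:
    def test_strong_edss_signal_recovered(self):
        rows = _toy_rows(n_patients=150, seed=1)
        res = ElieModel(rows).fit(seed=0, n_penalties=25)
        assert res.params["edss"] > 0

    def test_pure_noise_at_heavy_penalty_gives_base_rate(self):
        rows = _toy_rows(n_patients=80, seed=2, signal=0.0)
        res = ElieModel(rows).fit(
            seed=0, n_penalties=3, penalty_range=(1e3, 1e4)
        )
        assert (res.params.iloc[1:] == 0).all()
        preds = res.predict()
        assert np.allclose(preds, preds[0])

    def test_refit_same_seed_identical(self):
        rows = _toy_rows(n_patients=80, seed=3)
        a = ElieModel(rows).fit(seed=4, n_penalties=10)
        b = ElieModel(rows).fit(seed=4, n_penalties=10)
        pd.testing.assert_series_equal(a.params, b.params)
        assert a.penalty == b.penalty

    def test_single_class_rejected(self):
        rows = _toy_rows(n_patients=30, seed=5)
        rows["outcome_label"] = 0
        with pytest.raises(ValueError, match="single class"):
            ElieModel(rows).fit()

    def test_summary_mentions_penalty_and_counts(self):
        rows = _toy_rows(n_patients=60, seed=6)
        res = ElieModel(rows).fit(seed=0, n_penalties=5)
        text = res.summary()
        assert "penalty" in text and "patients" in text

    def test_model_card_roundtrip(self):
        from msprogrisk.landmark import ElieResults

        rows = _toy_rows(n_patients=60, seed=7)
        res = ElieModel(rows).fit(seed=0, n_penalties=5)
        card = res.to_card()
        import json

        restored = ElieResults.from_card(json.loads(json.dumps(card)), rows)
        assert np.allclose(restored.predict(rows), res.predict(rows))


class TestPrediction:
    def test_predictions_match_dot_product_oracle(self):
        rows = _toy_rows(n_patients=80, seed=8)
        res = ElieModel(rows).fit(seed=0, n_penalties=10)
        sample = rows.head(10)
        X = res.recipe.transform(sample)
        eta = res.params["intercept"] + X @ res.params.iloc[1:].to_numpy()
        oracle = 1 / (1 + np.exp(-eta))
        assert np.allclose(res.predict(sample), oracle, atol=1e-12)

    def test_monotone_in_edss_with_positive_coefficient(self):
        rows = _toy_rows(n_patients=150, seed=9)
        res = ElieModel(rows).fit(seed=0, n_penalties=25)
        assert res.params["edss"] > 0
        probe = rows.head(1).copy()
        risks = []
        for e in (1.0, 3.0, 5.0, 7.0):
            probe["edss"] = e
            risks.append(res.predict(probe)[0])
        assert risks == sorted(risks)

    def test_unknown_category_rejected(self):
        rows = _toy_rows(n_patients=60, seed=10)
        res = ElieModel(rows).fit(seed=0, n_penalties=5)
        bad = rows.head(1).copy()
        bad["dmt_history_category"] = "mystery"
        with pytest.raises(ValueError, match="unknown treatment-history"):
            res.predict(bad)

    def test_recipe_learned_constants_reapplied(self):
        rows = _toy_rows(n_patients=60, seed=11)
        recipe = Recipe.learn(rows)
        X = recipe.transform(rows)
        cont = X[:, :5]
        assert np.allclose(cont.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(cont.std(axis=0), 1, atol=1e-9)


class TestDeciles:
    def test_uniform_train_deciles_near_equal(self):
        rng = np.random.default_rng(12)
        p = rng.random(1000)
        train_dec, _, _ = stratify_deciles(p)
        counts = np.bincount(train_dec, minlength=11)[1:]
        assert counts.min() >= 99 and counts.max() <= 101

    def test_test_rows_below_first_boundary_clamp_to_one(self):
        train = np.linspace(0.2, 0.9, 100)
        _, test_dec, _ = stratify_deciles(train, [0.01, 0.95])
        assert test_dec[0] == 1 and test_dec[1] == 10

    def test_boundaries_match_quantile_oracle(self):
        rng = np.random.default_rng(13)
        p = rng.random(500)
        _, _, boundaries = stratify_deciles(p)
        oracle = np.quantile(np.sort(p), np.linspace(0.1, 0.9, 9))
        assert np.allclose(boundaries, oracle)

    def test_few_distinct_values_warn(self):
        with pytest.warns(UserWarning, match="distinct"):
            stratify_deciles([0.2] * 50)
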