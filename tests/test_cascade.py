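"""Enrollment, gate probabilities, 1-to-K matching and evaluation modes."""

import numpy as np
import pandas as pd
import pytest

import ecgid as E
from ecgid.ablation import build_database
from ecgid.cascade import _query_views, threshold_candidates
from ecgid.wavelet import select_levels, wdist


class TestEnroll:
    def test_cohort_count(self, trained_db):
        assert trained_db.N == 10

    def test_reenrollment_idempotent(self, noisy_cohort):
        rec = noisy_cohort[0]
        db = E.SubjectDatabase()
        E.enroll(rec, db)
        t1 = db.template(rec.subject_id)
        n_rows = len(db.subjects[rec.subject_id].feature_rows)
        E.enroll(rec, db)
        t2 = db.template(rec.subject_id)
        assert len(db.subjects[rec.subject_id].feature_rows) == n_rows
        for p in t1.levels:
            assert np.array_equal(t1.details[p], t2.details[p])

    def test_unlabelled_record_rejected(self, noisy_cohort):
        rec = noisy_cohort[0].copy()
        rec.subject_id = None
        with pytest.raises(ValueError, match="subject_id"):
            E.enroll(rec, E.SubjectDatabase())

    def test_too_few_beats_rejected(self):
        spec = E.CohortSpec(n_subjects=2, sessions_per_subject=1, duration=2.2,
                            snr_db=np.inf, baseline_amp=0.0, powerline_amp=0.0, seed=1)
        rec = E.synthesize_record(E.make_subject(1), spec)
        rec.subject_id = "s000"
        with pytest.raises(ValueError, match="rejected"):
            E.enroll(rec, E.SubjectDatabase())


class TestTrainGate:
    def test_seeded_determinism(self, noisy_cohort):
        q = [r for r in noisy_cohort if r.session_id == "2"][0]
        probs = []
        for _ in range(2):
            db = build_database(noisy_cohort, forest=E.ForestConfig(n_trees=50, seed=3))
            fv, _, _ = _query_views(q, db)
            probs.append(E.gate(fv, db).probabilities)
        pd.testing.assert_series_equal(probs[0], probs[1])

    def test_probabilities_normalized(self, trained_db, noisy_cohort):
        for q in [r for r in noisy_cohort if r.session_id == "2"][:5]:
            fv, _, _ = _query_views(q, trained_db)
            g = E.gate(fv, trained_db)
            assert g.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert (g.probabilities >= 0).all()
            assert g.K <= trained_db.N

    def test_training_requires_two_subjects(self, noisy_cohort):
        db = E.SubjectDatabase()
        E.enroll(noisy_cohort[0], db)
        with pytest.raises(ValueError, match="2 enrolled"):
            E.train_gate(db)

    def test_separable_training_argmax_is_truth(self, cohort5):
        db = build_database(cohort5)
        for q in [r for r in cohort5 if r.session_id == "1"]:
            fv, _, _ = _query_views(q, db)
            assert E.gate(fv, db).probabilities.idxmax() == q.subject_id


class TestGateThreshold:
    def test_all_above(self):
        probs = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        assert threshold_candidates(probs, 0.15) == ["a", "b", "c"]

    def test_single_candidate(self):
        probs = pd.Series([0.9, 0.1, 0.0], index=["a", "b", "c"])
        assert threshold_candidates(probs, 0.15) == ["a"]

    def test_fallback_to_argmax(self):
        probs = pd.Series(np.full(10, 0.1), index=[f"s{i}" for i in range(10)])
        assert threshold_candidates(probs, 0.15) == ["s0"]  # lowest id on ties

    def test_pth_zero_passes_everyone(self):
        probs = pd.Series([1.0, 0.0, 0.0], index=["a", "b", "c"])
        assert threshold_candidates(probs, 0.0) == ["a", "b", "c"]

    def test_feature_mode_mismatch_errors(self, trained_db):
        fv = E.FiducialFeatureVector(np.zeros(6), E.FEATURE_NAMES["ml3"], "ml3", 0.9)
        with pytest.raises(ValueError, match="mismatch"):
            E.gate(fv, trained_db)


class TestVerify:
    def test_self_match_clean(self):
        spec = E.CohortSpec(n_subjects=3, sessions_per_subject=1, duration=20.0,
                            snr_db=np.inf, baseline_amp=0.0, powerline_amp=0.0, seed=12)
        recs = E.generate_cohort(spec)
        db = build_database(recs, forest=E.ForestConfig(n_trees=100, seed=0))
        for rec in recs:
            assert E.verify(rec, db).predicted_subject == rec.subject_id

    def test_k_equal_one_decided_by_gate(self, trained_db, noisy_cohort):
        for q in [r for r in noisy_cohort if r.session_id == "2"]:
            res = E.verify(q, trained_db, pth=0.45)
            if res.gate.K == 1:
                assert res.stage_decided == "gate_only"
                assert res.predicted_subject == res.gate.candidates[0]
                break
        else:  # pragma: no cover
            pytest.fail("no K=1 query found")

    def test_pth_zero_equals_one_to_n_oracle(self, cohort5):
        db = build_database(cohort5)
        for q in [r for r in cohort5 if r.session_id == "2"]:
            res = E.verify(q, db, pth=0.0)
            assert res.gate.K == db.N
            fv, qt, _ = _query_views(q, db)
            qr = select_levels(qt, "S2")
            dists = {s: wdist(qr, db.restricted_template(s)) for s in db.subject_ids()}
            oracle = min(sorted(dists), key=lambda s: dists[s])
            assert res.predicted_subject == oracle
            assert res.distances == pytest.approx(dists)


class TestEvaluate:
    def test_accuracy_definition(self, cohort5):
        db = build_database(cohort5)
        queries = [r for r in cohort5 if r.session_id == "1"][:2]
        wrong = queries[1].copy()
        wrong.subject_id = "imposter"
        acc = E.evaluate(db, [queries[0], wrong], mode="gate_only")
        assert acc == 0.5

    def test_self_queries_perfect_all_modes(self):
        spec = E.CohortSpec(n_subjects=3, sessions_per_subject=1, duration=20.0,
                            snr_db=np.inf, baseline_amp=0.0, powerline_amp=0.0, seed=12)
        recs = E.generate_cohort(spec)
        db = build_database(recs, forest=E.ForestConfig(n_trees=100, seed=0))
        for mode in ("gate_only", "wdist_only", "two_stage"):
            assert E.evaluate(db, recs, mode=mode) == 1.0

    def test_empty_queries_error(self, trained_db):
        with pytest.raises(ValueError, match="empty"):
            E.evaluate(trained_db, [])

    def test_unknown_mode_error(self, trained_db, noisy_cohort):
        with pytest.raises(ValueError, match="unknown evaluation mode"):
            E.evaluate(trained_db, noisy_cohort[:1], mode="psychic")
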