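"""Laplacian-corrected NB training, exact LOO, selection gates, prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from persig import kinase_models
from persig.kinase_models import (
    DegenerateSliceError,
    KinaseModel,
    aggregate_activity,
    laplacian_weight,
    loo_roc,
    loo_scores,
    predict_profile,
    predict_profiles,
    randomize_predictions,
    roc_auc,
    select_models,
    train_model,
)
from persig.profiles import BinaryFingerprint

from conftest import random_fingerprints


def fp(*bits):
    return BinaryFingerprint(space_id="chem", bits=frozenset(bits))


def slice_frame(pairs, kinase="K1"):
    return pd.DataFrame(
        {"compound_id": [c for c, _ in pairs], "kinase_id": kinase,
         "pic50": [p for _, p in pairs]}
    )


class TestAggregate:
    @pytest.mark.parametrize(
        "values,expected",
        [([5.8, 6.4, 7.0], 6.4), ([7.1], 7.1), ([6.0, 8.0], 7.0)],
    )
    def test_median_collapse(self, values, expected):
        raw = slice_frame([("C1", v) for v in values])
        agg = aggregate_activity(raw)
        assert len(agg) == 1
        assert agg.iloc[0]["pic50"] == expected


class TestTrainModel:
    def make_training(self):
        # T=4, A=2 (P=0.5); feature f present in exactly the two actives
        fps = {
            "A1": fp("f", "x1"), "A2": fp("f", "x2"),
            "I1": fp("x3"), "I2": fp("x4"),
        }
        act = slice_frame([("A1", 7.0), ("A2", 7.5), ("I1", 5.0), ("I2", 4.0)])
        return act, fps

    def test_hand_computed_weight(self):
        act, fps = self.make_training()
        model = train_model(act, fps)
        assert model.prior_active == 0.5
        assert model.feature_weights["f"] == pytest.approx(math.log(3 / 2), abs=1e-12)

    def test_uninformative_feature_weight_zero(self):
        # A_f = P * T_f exactly -> ln((A_f+1)/(A_f+1)) = 0
        assert laplacian_weight(1, 2, 0.5) == 0.0

    def test_feature_absent_from_actives_negative(self):
        assert laplacian_weight(0, 10, 0.5) == pytest.approx(math.log(1 / 6), abs=1e-12)

    def test_boundary_pic50_is_inactive(self):
        fps = {"C1": fp("a"), "C2": fp("b"), "C3": fp("c")}
        act = slice_frame([("C1", 6.0), ("C2", 6.0), ("C3", 6.1)])
        model = train_model(act, fps)
        assert model.n_active == 1  # 6.0 exactly is inactive

    def test_degenerate_slice_rejected(self):
        fps = {"C1": fp("a"), "C2": fp("b")}
        with pytest.raises(DegenerateSliceError):
            train_model(slice_frame([("C1", 7.0), ("C2", 8.0)]), fps)

    def test_adding_active_with_feature_never_decreases_weight_at_fixed_prior(self):
        """Monotonicity of the Laplacian estimator in the per-feature counts.

        At a fixed class prior, observing one more active that carries the
        feature can only raise (never lower) its weight.  The prior itself
        also shifts when a compound is added, and that shift can dominate,
        so the guarantee is exactly the fixed-prior one.
        """
        for a_f in range(6):
            for t_f in range(a_f, 9):
                for prior in (0.1, 0.3, 0.5, 0.7, 0.9):
                    before = laplacian_weight(a_f, t_f, prior)
                    after = laplacian_weight(a_f + 1, t_f + 1, prior)
                    assert after >= before - 1e-12


class TestLooRoc:
    def test_loo_decrement_matches_fresh_retrain(self, rng):
        """Count decrement is exact: held-out scores equal full retraining."""
        fps = random_fingerprints(rng, 24, n_features=20, density=0.3)
        ids = sorted(fps)
        pic50 = np.where(rng.random(24) < 0.4, 7.0, 5.0) + rng.normal(0, 0.2, 24)
        act = slice_frame(list(zip(ids, pic50)))
        scores, labels = loo_scores(act, fps)
        for i, cid in enumerate(ids):
            rest = act[act["compound_id"] != cid]
            fresh = train_model(rest, fps)
            assert scores[i] == pytest.approx(fresh.score(fps[cid]), abs=0)

    def test_perfect_separation(self):
        assert roc_auc(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0])) == 1.0

    def test_matches_pairwise_oracle(self, rng):
        """Rank-based AUC equals the explicit pairwise-comparison statistic."""
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 6, size=n).astype(float)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_permuted_labels_centered_at_half(self, rng):
        fps = random_fingerprints(rng, 200, n_features=40, density=0.2)
        ids = sorted(fps)
        aucs = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            labels = np.zeros(200, dtype=bool)
            labels[local.choice(200, size=60, replace=False)] = True
            act = slice_frame([(c, 7.0 if lab else 5.0) for c, lab in zip(ids, labels)])
            aucs.append(loo_roc(act, fps))
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1


class TestSelection:
    @pytest.mark.parametrize(
        "auc,n,na,expected",
        [
            (0.90, 100, 50, False),   # strictly greater than 0.9 required
            (0.95, 19, 10, False),    # at least 20 data points required
            (0.95, 25, 10, True),     # 10 actives is enough
            (0.95, 25, 9, False),
            (math.nan, 25, 10, False),
        ],
    )
    def test_gate_boundaries(self, auc, n, na, expected):
        report = pd.DataFrame(
            [{"kinase_id": "K1", "n_total": n, "n_active": na, "loo_roc_auc": auc,
              "retained": False}]
        )
        assert bool(select_models(report)["retained"].iloc[0]) is expected


class TestPredict:
    def toy_models(self):
        shared = dict(n_total=10, n_active=5, prior_active=0.5)
        m1 = KinaseModel(kinase_id="K1", feature_total={"f1": 5, "f2": 6},
                         feature_active={"f1": 5, "f2": 1}, **shared)
        m2 = KinaseModel(kinase_id="K2", feature_total={"f3": 5},
                         feature_active={"f3": 0}, **shared)
        return {"K1": m1, "K2": m2}

    def test_empty_fingerprint_all_off(self):
        profile = predict_profile(fp(), self.toy_models())
        assert profile.bits == frozenset()

    def test_positive_evidence_turns_bit_on(self):
        models = self.toy_models()
        # f1: W = ln(6/3.5) > 0 and large enough to dominate
        profile = predict_profile(fp("f1"), models)
        assert profile.bits == frozenset({"K1"})

    def test_profile_length_equals_retained_count(self, rng):
        fps = random_fingerprints(rng, 5, n_features=10)
        frame = predict_profiles(fps, self.toy_models())
        assert frame.shape == (5, 2)
        assert list(frame.columns) == ["K1", "K2"]


class TestRandomize:
    def test_column_sums_conserved_and_seeded(self, rng):
        frame = pd.DataFrame(rng.random((40, 6)) < 0.3,
                             index=[f"C{i}" for i in range(40)],
                             columns=[f"K{j}" for j in range(6)])
        perm1 = randomize_predictions(frame, seed=3)
        perm2 = randomize_predictions(frame, seed=3)
        assert (perm1.sum() == frame.sum()).all()
        pd.testing.assert_frame_equal(perm1, perm2)
        assert not perm1.equals(frame)
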