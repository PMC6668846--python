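"""Under-sampled forest ensemble, applicability domain, CV and screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ddimine.ade_classifier import (
    EnsembleModel,
    ScreenSummary,
    assign_drug_folds,
    balanced_accuracy,
    compound_out_cv,
    confusion_rates,
    evaluate_external,
    fit_undersampled_forest,
    predict_pair,
    screen_pair_library,
)
from ddimine.dataset_builder import PairDataset
from ddimine.synthetic_data import generate_labeled_pairs, generate_target_profiles


@pytest.fixture(scope="module")
def small_sep():
    """Separable 300-pair dataset over 30 drugs (module-scoped, reused)."""
    profiles, w = generate_target_profiles(30, 40, seed=21)
    ps = generate_labeled_pairs(profiles, w, 300, noise=0.05, seed=21)
    X = profiles.descriptor_matrix(ps.pairs)
    ds = PairDataset("ade", ps.pairs, ps.labels)
    return ds, X


class TestEnsembleFit:
    def test_balanced_input_undersample_is_identity(self, small_sep):
        ds, X = small_sep
        n_pos = ds.n_positive
        sub = np.arange(len(ds))[ds.labels == 1][: n_pos]
        # force an exactly balanced input
        idx = np.concatenate(
            [np.where(ds.labels == 1)[0][:40], np.where(ds.labels == 0)[0][:40]]
        )
        m = fit_undersampled_forest(X[idx], ds.labels[idx], M=3, n_trees=20, seed=0)
        for s in m.sample_indices:
            assert np.array_equal(s, np.arange(80))

    def test_seed_determinism(self, small_sep):
        ds, X = small_sep
        m1 = fit_undersampled_forest(X, ds.labels, M=2, n_trees=30, seed=5)
        m2 = fit_undersampled_forest(X, ds.labels, M=2, n_trees=30, seed=5)
        probe = X[:25]
        assert np.array_equal(m1.predict_proba(probe), m2.predict_proba(probe))
        assert m1.tau == m2.tau

    def test_probabilities_are_submodel_mean_and_bounded(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=3, n_trees=25, seed=1)
        probe = X[:50]
        per_sub = np.stack(
            [rf.predict_proba(probe)[:, list(rf.classes_).index(1)] for rf in m.submodels]
        )
        assert np.allclose(m.predict_proba(probe), per_sub.mean(axis=0))
        p = m.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_m_one_is_single_forest_vote_fraction(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=1, n_trees=40, seed=2)
        rf = m.submodels[0]
        probe = X[:20]
        assert np.allclose(
            m.predict_proba(probe), rf.predict_proba(probe)[:, list(rf.classes_).index(1)]
        )

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError, match="at least 5"):
            fit_undersampled_forest(X, y, M=1, n_trees=5, seed=0)

    def test_training_oob_auc_on_separable_data(self, small_sep):
        from sklearn.metrics import roc_auc_score

        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=3, n_trees=100, seed=3)
        assert roc_auc_score(ds.labels, m.predict_proba(X)) >= 0.85


class TestApplicabilityDomain:
    def test_unanimous_trees_in_ad(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=1, n_trees=10, seed=4)
        # a heavily replicated training point gets near-unanimous votes
        probe = X[:1]
        assert m.vote_dispersion(probe)[0] <= m.tau + 0.5  # sanity: finite
        m.tau = float(m.vote_dispersion(probe)[0])
        assert m.in_ad(probe)[0]

    def test_full_coverage_accepts_training_dispersions(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=2, n_trees=30, seed=5,
                                    ad_coverage=1.0)
        disp = m.vote_dispersion(X)
        # nearly all training pairs fall inside at coverage 1.0 (the
        # calibration uses OOB votes, prediction uses all trees)
        assert m.in_ad(X).mean() > 0.9

    def test_off_manifold_probes_excluded_more(self, small_sep):
        ds, X = small_sep
        rng = np.random.default_rng(6)
        m = fit_undersampled_forest(X, ds.labels, M=2, n_trees=60, seed=6)
        noise = rng.uniform(-3, 3, size=(200, X.shape[1]))
        in_rate = m.in_ad(X).mean()
        out_rate = m.in_ad(noise).mean()
        assert out_rate <= in_rate

    def test_hash_mismatch_rejected(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=1, n_trees=10, seed=7,
                                    target_order_hash="abc")
        with pytest.raises(ValueError, match="hash"):
            predict_pair(m, X[:2], target_order_hash="xyz")
        prob, ad = predict_pair(m, X[:2], target_order_hash="abc")
        assert prob.shape == (2,)


class TestMetrics:
    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(8)
        y = (rng.random(200) < 0.4).astype(int)
        prob = rng.random(200)
        sens, spec = confusion_rates(y, prob, 0.5)
        assert balanced_accuracy(sens, spec) == pytest.approx((sens + spec) / 2)

    def test_hand_confusion_matrix(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=1, n_trees=20, seed=9)
        # 10-probe fixture with known predictions
        probe = X[:10]
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        rep = evaluate_external(m, ds.pairs[:10], probe, y)
        prob, ad = predict_pair(m, probe)
        pred = prob[ad] > 0.5
        ya = y[ad]
        sens = (pred & (ya == 1)).sum() / max((ya == 1).sum(), 1)
        spec = (~pred & (ya == 0)).sum() / max((ya == 0).sum(), 1)
        assert rep.sensitivity == pytest.approx(sens)
        assert rep.specificity == pytest.approx(spec)
        assert rep.balanced_accuracy == pytest.approx((sens + spec) / 2)


class TestCompoundOutCV:
    def test_disjointness_and_exactly_once(self, small_sep):
        ds, X = small_sep
        rep = compound_out_cv(ds, X, k=4, seed=10, M=1, n_trees=15)
        preds = rep.predictions
        # every pair evaluated exactly once
        tested = list(zip(preds["drug1"], preds["drug2"]))
        evaluable = [
            p for p in ds.pairs
        ]
        assert len(tested) == len(set(tested))
        fold_of = assign_drug_folds(ds.roster, 4, seed=10)
        for row in preds.itertuples():
            f = row.fold
            # the tested pair's first drug belongs to the test fold set,
            # hence is absent from every training pair of that fold
            assert fold_of[min(row.drug1, row.drug2)] == f

    def test_fold_partition_properties(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            drugs = [f"d{i}" for i in range(int(rng.integers(10, 40)))]
            k = int(rng.integers(2, 5))
            fold_of = assign_drug_folds(drugs, k, seed=trial)
            assert set(fold_of) == set(drugs)
            assert set(fold_of.values()) <= set(range(k))
            # every fold nonempty
            assert len(set(fold_of.values())) == k

    def test_label_shuffle_gives_chance_auc(self, small_sep):
        ds, X = small_sep
        rng = np.random.default_rng(12)
        shuffled = PairDataset(ds.ade, ds.pairs, rng.permutation(ds.labels))
        rep = compound_out_cv(shuffled, X, k=4, seed=12, M=1, n_trees=40)
        assert abs(rep.auc - 0.5) < 0.12


class TestLibraryScreen:
    def _const_model(self, small_sep, seed=13):
        ds, X = small_sep
        return fit_undersampled_forest(X, ds.labels, M=1, n_trees=20, seed=seed), X

    def test_hand_counts(self):
        summary = ScreenSummary(total=3, in_ad=3, counts={0.5: 2, 0.8: 1})
        assert summary.counts[0.5] == 2

    def test_nesting_enforced(self):
        with pytest.raises(ValueError):
            ScreenSummary(total=3, in_ad=1, counts={0.5: 1, 0.8: 2})

    def test_empty_library(self, small_sep):
        m, X = self._const_model(small_sep)
        summary, table, hist = screen_pair_library(m, [], np.empty((0, X.shape[1])))
        assert summary.total == 0 and summary.in_ad == 0
        assert all(v == 0 for v in summary.counts.values())

    def test_counts_and_nesting_on_probes(self, small_sep):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=2, n_trees=30, seed=14)
        summary, table, hist = screen_pair_library(m, ds.pairs, X)
        assert summary.counts[0.8] <= summary.counts[0.5] <= summary.in_ad <= summary.total
        # summary counts equal recomputation from the per-pair table
        assert summary.counts[0.5] == int(((table["prob"] > 0.5) & table["in_ad"]).sum())
        assert hist[0].sum() == summary.total

    def test_model_round_trip(self, small_sep, tmp_path):
        ds, X = small_sep
        m = fit_undersampled_forest(X, ds.labels, M=2, n_trees=15, seed=15,
                                    target_order_hash="h1")
        m.save(tmp_path / "model")
        m2 = EnsembleModel.load(tmp_path / "model")
        assert m2.tau == m.tau and m2.target_order_hash == "h1"
        assert np.allclose(m.predict_proba(X[:20]), m2.predict_proba(X[:20]))
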