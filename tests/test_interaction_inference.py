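"""Propensity scores, phi relevance ranking, interaction LASSO and verdicts."""

from __future__ import annotations

import numpy as np
import pytest

from ddimine.interaction_inference import (
    BETA_EPS,
    LassoConfig,
    LassoFit,
    classify_interaction,
    fit_pair_pt_lasso,
    fit_propensity,
    phi_relevance,
    select_ps_features,
)
from ddimine._l1path import l1_logistic_path, lambda_max
from ddimine.signal_screen import PairPtSignal, ScreenConfig, chi_square
from ddimine.sr_model import ContingencyTable, DrugAdeLabels, SpontaneousReport, SRDatabase
from ddimine.synthetic_data import SimConfig, generate_sr_database

from conftest import make_db, random_db


class TestPhiRelevance:
    def test_perfect_cooccurrence(self):
        rows = [(["d1"], ["i1"], ["p"])] * 10 + [(["d2"], [], ["p"])] * 10
        db = make_db(rows)
        assert phi_relevance(db, "d1", "i1") == pytest.approx(1.0)

    def test_independence_near_zero(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(4000):
            d = ["d1"] if rng.random() < 0.5 else ["d2"]
            ind = ["i1"] if rng.random() < 0.5 else []
            rows.append((d, ind, ["p"]))
        db = make_db(rows)
        assert phi_relevance(db, "d1", "i1") < 0.05

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(1)
        db = random_db(rng, n_reports=20)
        for feat in ["i0", "d1"]:
            drug_mask = np.array([("d0" in r.drugs) for r in db.reports])
            if feat.startswith("i"):
                feat_mask = np.array([(feat in r.indications) for r in db.reports])
            else:
                feat_mask = np.array([(feat in r.drugs) for r in db.reports])
            a = int((drug_mask & feat_mask).sum())
            b = int((~drug_mask & feat_mask).sum())
            c = int((drug_mask & ~feat_mask).sum())
            d = 20 - a - b - c
            expected = np.sqrt(chi_square(ContingencyTable(a, b, c, d)) / 20)
            assert phi_relevance(db, "d0", feat) == pytest.approx(expected)

    def test_feature_equal_drug_rejected(self, five_report_db):
        with pytest.raises(ValueError):
            phi_relevance(five_report_db, "d1", "d1")


class TestFeatureSelection:
    def test_short_list_returned_fully(self, five_report_db):
        inds, codrugs = select_ps_features(five_report_db, "d1", k=100)
        assert {i for i, _ in inds} == {"i1", "i2"}
        assert len(codrugs) == 3  # d2, d3, d4

    def test_tie_breaks_lexicographic(self):
        # i1 and i2 co-occur identically with d1 -> equal phi, i1 first
        rows = [(["d1"], ["i1", "i2"], ["p"])] * 5 + [(["d2"], [], ["p"])] * 5
        db = make_db(rows)
        inds, _ = select_ps_features(db, "d1")
        assert inds[0][0] == "i1" and inds[1][0] == "i2"
        assert inds[0][1] == pytest.approx(inds[1][1])

    def test_topk_equals_full_sort(self):
        rng = np.random.default_rng(2)
        db = random_db(rng, n_reports=300, n_inds=8)
        inds, codrugs = select_ps_features(db, "d0", k=3)
        all_inds, all_codrugs = select_ps_features(db, "d0", k=100)
        assert inds == all_inds[:3]
        assert codrugs == all_codrugs[:3]


class TestPropensity:
    def test_constant_exposure_intercept_only(self):
        rows = [(["d1", "d2"], ["i1"], ["p"])] * 6
        db = make_db(rows)
        pm = fit_propensity(db, "d1")
        assert np.allclose(pm.ps, pm.ps[0])

    def test_confounder_raises_ps(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(2000):
            conf = rng.random() < 0.4
            drug = rng.random() < (0.6 if conf else 0.1)
            rows.append(
                (
                    ["d1", "d2"] if drug else ["d2"],
                    ["i1"] if conf else [],
                    ["p"],
                )
            )
        db = make_db(rows)
        pm = fit_propensity(db, "d1")
        conf_ps = [pm.ps[i] for i, r in enumerate(db.reports) if "i1" in r.indications]
        other_ps = [pm.ps[i] for i, r in enumerate(db.reports) if "i1" not in r.indications]
        assert np.mean(conf_ps) > np.mean(other_ps)

    def test_parameter_recovery_on_simulated_exposure(self):
        # exposure logit = -2 + 1.2*i1 - 0.8*i2; recovery within ~3 SE
        rng = np.random.default_rng(4)
        n = 50_000
        i1 = rng.random(n) < 0.4
        i2 = rng.random(n) < 0.3
        logit = -2.0 + 1.2 * i1 - 0.8 * i2
        drug = rng.random(n) < 1 / (1 + np.exp(-logit))
        reports = [
            SpontaneousReport(
                f"r{k}",
                frozenset(["d1", "dz"] if drug[k] else ["dz"]),
                frozenset((["i1"] if i1[k] else []) + (["i2"] if i2[k] else [])),
                frozenset(["p"]),
            )
            for k in range(n)
        ]
        db = SRDatabase(reports)
        pm = fit_propensity(db, "d1", features=([("i1", 1.0), ("i2", 1.0)], []))
        assert pm.intercept == pytest.approx(-2.0, abs=0.12)
        assert pm.coef_indications[0] == pytest.approx(1.2, abs=0.12)
        assert pm.coef_indications[1] == pytest.approx(-0.8, abs=0.12)


@pytest.fixture(scope="module")
def planted_sim():
    """Small but strongly planted interaction for LASSO recovery tests."""
    cfg = SimConfig(
        n_reports=30_000,
        n_drugs=12,
        n_indications=8,
        n_pts=8,
        planted_interactions=(("d000", "d001", "pt000", np.log(6.0)),),
        seed=5,
    )
    db, truth = generate_sr_database(cfg)
    ps1 = fit_propensity(db, "d000").ps
    ps2 = fit_propensity(db, "d001").ps
    return db, truth, ps1, ps2


class TestPairPtLasso:
    def test_planted_interaction_recovered(self, planted_sim):
        db, truth, ps1, ps2 = planted_sim
        fit = fit_pair_pt_lasso(db, ("d000", "d001"), "pt000", ps1, ps2,
                                LassoConfig(seed=0))
        assert fit.beta5 > 0

    def test_noise_pt_fully_shrunk(self, planted_sim):
        db, truth, ps1, ps2 = planted_sim
        # pick a PT with no planted interaction for this pair
        pt = "pt004"
        assert ("d000", "d001", pt) not in truth.planted_pair_pts
        fit = fit_pair_pt_lasso(db, ("d000", "d001"), pt, ps1, ps2, LassoConfig(seed=0))
        assert abs(fit.beta5) <= BETA_EPS

    def test_drug_order_symmetry(self, planted_sim):
        db, truth, ps1, ps2 = planted_sim
        f12 = fit_pair_pt_lasso(db, ("d000", "d001"), "pt000", ps1, ps2, LassoConfig(seed=0))
        f21 = fit_pair_pt_lasso(db, ("d001", "d000"), "pt000", ps1, ps2, LassoConfig(seed=0))
        # pairs are canonicalized, so the fits must be identical
        assert np.allclose(f12.beta, f21.beta)

    def test_unseen_pt_degenerate(self, planted_sim):
        db, truth, ps1, ps2 = planted_sim
        fit = fit_pair_pt_lasso(db, ("d000", "d001"), "no_such_pt", ps1, ps2)
        assert fit.degenerate

    def test_solver_matches_liblinear(self):
        # dual-route check of the path solver against scikit-learn
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(8)
        n = 5000
        X = np.column_stack(
            [
                rng.normal(size=n),
                rng.normal(size=n),
                rng.random(n) < 0.1,
                rng.random(n) < 0.1,
            ]
        ).astype(float)
        logit = -2.5 + 0.5 * X[:, 0] + 0.8 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        lm = lambda_max(X, y)
        lams = np.geomspace(lm, 1e-3 * lm, 12)
        b0s, betas = l1_logistic_path(X, y, lams, tol=1e-9)
        for i in (3, 7, 11):
            ref = LogisticRegression(
                solver="liblinear", l1_ratio=1.0, C=1 / (lams[i] * n),
                intercept_scaling=1e4, tol=1e-10, max_iter=5000,
            ).fit(X, y)
            assert np.abs(ref.coef_.ravel() - betas[i]).max() < 2e-4
            assert abs(float(ref.intercept_[0]) - b0s[i]) < 2e-3


def _fit(b3, b4, b5):
    beta = np.array([0.0, 0.1, 0.1, b3, b4, b5])
    return LassoFit(("a", "b"), "pt", beta, 0.01)


def _screen(passed=True):
    t = ContingencyTable(10, 50, 40, 900)
    return PairPtSignal(("a", "b"), "pt", t, 3.0, 25.0, passed)


def _labels(a="causes", b="causes"):
    lab = DrugAdeLabels()
    lab.set("a", "ade", a)
    lab.set("b", "ade", b)
    return lab


class TestVerdictRules:
    def test_positive_interaction_is_synergistic(self):
        call = classify_interaction(_fit(0.1, 0.1, 0.3), _screen(), 600, _labels(), "ade")
        assert call.verdict == "synergistic"

    def test_zero_interaction_positive_mains_causal_is_additive(self):
        call = classify_interaction(_fit(0.2, 0.1, 0.0), _screen(), 600, _labels(), "ade")
        assert call.verdict == "additive"

    def test_additive_requires_both_causal(self):
        call = classify_interaction(
            _fit(0.2, 0.1, 0.0), _screen(), 600, _labels(b="not_causes"), "ade"
        )
        assert call.verdict == "undetermined"

    def test_nonpositive_main_and_interaction_is_no_ddi(self):
        call = classify_interaction(_fit(-0.1, 0.2, 0.0), _screen(), 600, _labels(), "ade")
        assert call.verdict == "no_ddi"

    def test_screen_failed_well_reported_is_no_ddi(self):
        call = classify_interaction(None, _screen(False), 600, _labels(), "ade")
        assert call.verdict == "no_ddi"

    def test_screen_failed_sparse_is_undetermined(self):
        call = classify_interaction(None, _screen(False), 499, _labels(), "ade")
        assert call.verdict == "undetermined"

    def test_verdict_invariant_to_drug_order(self):
        # swapping the drugs swaps (beta1,beta3)<->(beta2,beta4), keeps beta5
        f_ab = _fit(0.2, -0.1, 0.0)
        f_ba = _fit(-0.1, 0.2, 0.0)
        c1 = classify_interaction(f_ab, _screen(), 600, _labels(), "ade")
        c2 = classify_interaction(f_ba, _screen(), 600, _labels(), "ade")
        assert c1.verdict == c2.verdict == "no_ddi"
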