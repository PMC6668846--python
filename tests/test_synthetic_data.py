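"""Seeded generators: determinism, planted effects, label and score structure."""

from __future__ import annotations

import numpy as np
import pytest

from ddimine.dataset_builder import PairDataset, score_dataset, validate_dataset
from ddimine.signal_screen import prr
from ddimine.sr_model import DrugAdeLabels, count_pair_pt, write_sr_database
from ddimine.synthetic_data import (
    SimConfig,
    emit_fixture_dir,
    generate_inference_scores,
    generate_labeled_pairs,
    generate_sr_database,
    generate_target_profiles,
)

SMALL = dict(n_reports=15_000, n_drugs=10, n_indications=6, n_pts=8)


class TestSrGenerator:
    def test_seed_determinism_byte_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            db, _ = generate_sr_database(SimConfig(**SMALL, seed=9))
            p = tmp_path / f"{run}.tsv"
            write_sr_database(db, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_null_interaction_prr_near_one(self):
        cfg = SimConfig(
            **SMALL,
            interaction_logodds=0.0,
            drug_effect_fraction=0.0,
            conf_ind_pt=0.0,
            seed=10,
        )
        db, truth = generate_sr_database(cfg)
        ratios = []
        for d1, d2, pt, _ in truth.planted:
            t = count_pair_pt(db, d1, d2, pt)
            if t.A + t.C > 0 and t.A > 0:
                ratios.append(prr(t))
        assert ratios, "planted pairs should be co-mentioned"
        assert 0.5 < np.mean(ratios) < 1.6

    def test_planted_interaction_inflates_a(self):
        cfg = SimConfig(
            **SMALL,
            planted_interactions=(("d000", "d001", "pt000", np.log(6.0)),),
            drug_effect_fraction=0.0,
            conf_ind_pt=0.0,
            seed=11,
        )
        db, truth = generate_sr_database(cfg)
        t = count_pair_pt(db, "d000", "d001", "pt000")
        # expected A under independence: comention * marginal pt rate
        base = db.reports_with_reaction("pt000").size / db.n
        expected = (t.A + t.C) * base
        assert t.A / expected > 2

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_reports=0)
        with pytest.raises(ValueError):
            SimConfig(planted_interactions=(("a", "b", "p", 1.0), ("b", "a", "p", 1.0)))

    def test_reports_well_formed(self):
        db, truth = generate_sr_database(SimConfig(**SMALL, seed=12))
        assert all(r.drugs and r.reactions for r in db.reports)
        assert set(truth.drug_labels.drugs) == set(db.drugs)


class TestProfilesAndLabels:
    def test_profile_determinism_and_bounds(self):
        p1, w1 = generate_target_profiles(6, 30, seed=3)
        p2, w2 = generate_target_profiles(6, 30, seed=3)
        assert np.array_equal(p1.pa, p2.pa) and np.array_equal(w1, w2)
        assert ((p1.pa > 0) & (p1.pa < 1)).all()
        # i.i.d. Beta(1.2, 3.5) draws: empirical mean near 1.2/4.7
        assert abs(p1.pa.mean() - 1.2 / 4.7) < 0.03

    def test_identical_profiles_zero_difference_half(self):
        p, w = generate_target_profiles(4, 10, seed=4)
        uniform = np.tile(p.pa[0], (4, 1))
        from ddimine.pair_descriptors import TargetProfileMatrix

        m = TargetProfileMatrix(list(p.drugs), list(p.targets), uniform, np.tile(p.pi[0], (4, 1)))
        X = m.descriptor_matrix([("d000", "d001"), ("d002", "d003")])
        assert np.allclose(X[:, 10:], 0.0)

    def test_noise_zero_perfectly_separable(self):
        p, w = generate_target_profiles(20, 40, seed=5)
        ps = generate_labeled_pairs(p, w, 150, noise=0.0, seed=5)
        assert ps.oracle_auc == pytest.approx(1.0)

    def test_noise_lowers_oracle_auc(self):
        p, w = generate_target_profiles(30, 40, seed=6)
        clean = generate_labeled_pairs(p, w, 400, noise=0.0, seed=6)
        noisy = generate_labeled_pairs(p, w, 400, noise=0.2, seed=6)
        assert noisy.oracle_auc < clean.oracle_auc
        # balanced 20% flips cap the oracle at .8*.8*1 + 2*(.8*.2)*0.5 = 0.80
        assert noisy.oracle_auc == pytest.approx(0.80, abs=0.05)

    def test_class_balance_controlled(self):
        p, w = generate_target_profiles(110, 30, seed=7)
        ps = generate_labeled_pairs(p, w, 5000, noise=0.0, class_balance=0.3, seed=7)
        assert abs(ps.labels.mean() - 0.3) < 0.02


class TestInferenceScores:
    def _pairs(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        pairs = [(f"d{2*i}", f"d{2*i+1}") for i in range(n)]
        labels = (rng.random(n) < 0.5).astype(int)
        return pairs, labels

    def _auc(self, pairs, labels, table):
        ds = PairDataset("ade", pairs, labels)
        return validate_dataset(ds, score_dataset(ds, table, DrugAdeLabels())).auc

    def test_zero_effect_auc_near_half(self):
        pairs, labels = self._pairs(400, seed=1)
        table = generate_inference_scores(pairs, labels, "ade", effect_size=0.0, seed=1)
        assert abs(self._auc(pairs, labels, table) - 0.5) < 0.08

    def test_large_effect_auc_high(self):
        pairs, labels = self._pairs(400, seed=2)
        table = generate_inference_scores(pairs, labels, "ade", effect_size=6.0, seed=2)
        assert self._auc(pairs, labels, table) > 0.9

    def test_determinism(self):
        pairs, labels = self._pairs(50, seed=3)
        t1 = generate_inference_scores(pairs, labels, "ade", seed=4)
        t2 = generate_inference_scores(pairs, labels, "ade", seed=4)
        assert all(
            t1.get(d, "ade") == t2.get(d, "ade") for p in pairs for d in p
        )


class TestEffectMonotonicity:
    def test_recovery_signal_monotone_in_effect_size(self):
        """Planted contingency excess grows with the interaction log-odds."""
        excesses = []
        for logodds in (0.0, np.log(3.0), np.log(8.0)):
            reps = []
            for seed in range(3):
                cfg = SimConfig(
                    **SMALL,
                    planted_interactions=(("d000", "d001", "pt000", logodds),),
                    drug_effect_fraction=0.0,
                    conf_ind_pt=0.0,
                    seed=100 + seed,
                )
                db, _ = generate_sr_database(cfg)
                t = count_pair_pt(db, "d000", "d001", "pt000")
                base = db.reports_with_reaction("pt000").size / db.n
                reps.append(t.A / max((t.A + t.C) * base, 1e-9))
            excesses.append(np.mean(reps))
        assert excesses[0] < excesses[1] < excesses[2]


class TestFixtureEmission:
    def test_complete_directory(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=20)
        paths = emit_fixture_dir(cfg, tmp_path / "fix", n_targets=12)
        for key in ("sr", "ontology", "labels", "profiles", "inference_scores", "truth"):
            assert paths[key].exists(), key
        from ddimine.sr_model import load_sr_database

        db = load_sr_database(paths["sr"])
        assert db.n == cfg.n_reports
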