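"""Synthetic spontaneous-report and drug-profile generators with planted truth.

The report generator emulates the causal structure the mining pipeline must
untangle: indications confound both drug exposure (an indication makes its
treating drugs more likely to appear in a report) and outcome (some
indications raise the rate of particular reaction PTs), individual drugs
carry their own adverse-effect signals, and a configured set of drug pairs
carries a genuine multiplicative (synergistic) interaction effect on one PT
each.  Every quantity is drawn from a single seeded generator, so a
configuration maps deterministically to a database.

Per-report sampling scheme:

1. indications: independent Bernoulli with per-indication prevalences drawn
   once from a Beta distribution;
2. drugs: independent Bernoulli with logit = per-drug baseline +
   confounding boost when a treated indication is present (reports with no
   drug get the highest-logit drug, keeping the drug set nonempty);
3. reactions: independent Bernoulli with logit = baseline + indication
   effects + individual drug effects + planted interaction effect when both
   pair drugs are present; every report additionally receives one uniform
   "background complaint" PT drawn from PTs carrying no planted
   interaction, which guarantees a nonempty reaction set without touching
   the planted signals.

Companion generators produce the other pipeline inputs: per-drug target
activity profiles (independent Beta-distributed Pa/Pi), mechanism-labeled
drug pairs (labels from a sparse linear score over pair descriptors, with
a balanced label-flip noise), and inference-score tables whose positive-pair
drugs score stochastically higher by a configurable effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .pair_descriptors import TargetProfileMatrix
from .signal_screen import canonical_pair
from .sr_model import (
    AdeOntology,
    DrugAdeLabels,
    InferenceScoreTable,
    SRDatabase,
    SpontaneousReport,
    write_sr_database,
)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the spontaneous-report simulator.

    Defaults plant eight synergistic (pair, PT) effects with an interaction
    odds ratio of 6 in 120,000 reports over 60 drugs, 30 indications and
    24 PTs, with confounding by indication switched on.
    """

    n_reports: int = 120_000
    n_drugs: int = 60
    n_indications: int = 30
    n_pts: int = 24
    seed: int = 42

    # exposure model
    mean_drugs_per_report: float = 3.0
    drug_logit_sd: float = 0.3
    indication_prev_alpha: float = 2.0
    indication_prev_beta: float = 28.0

    # confounding by indication (log-odds); 0 switches the pathway off
    conf_ind_drug: float = 1.5
    conf_ind_pt: float = 1.0
    conf_pt_fraction: float = 0.5  # fraction of indications that affect a PT

    # outcome model
    base_pt_rate: float = 0.02
    drug_effect_logodds: float = 0.7
    drug_effect_fraction: float = 0.3  # fraction of drugs with an own PT effect

    # planted synergy; pairs auto-drawn when planted_interactions is None
    n_planted: int = 8
    interaction_logodds: float = math.log(6.0)
    planted_interactions: tuple[tuple[str, str, str, float], ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_reports, self.n_drugs, self.n_indications, self.n_pts) <= 0:
            raise ValueError("all counts must be positive")
        if self.mean_drugs_per_report <= 0:
            raise ValueError("mean drugs per report must be positive")
        for v in (self.conf_ind_drug, self.conf_ind_pt, self.drug_effect_logodds,
                  self.interaction_logodds):
            if not math.isfinite(v):
                raise ValueError("log-odds parameters must be finite")
        if self.planted_interactions is not None:
            keys = [
                (*canonical_pair(a, b), pt)
                for a, b, pt, _ in self.planted_interactions
            ]
            if len(set(keys)) != len(keys):
                raise ValueError("planted (pair, PT) effects must be distinct")

    def drug_name(self, i: int) -> str:
        return f"d{i:03d}"

    def indication_name(self, i: int) -> str:
        return f"ind{i:03d}"

    def pt_name(self, i: int) -> str:
        return f"pt{i:03d}"


@dataclass
class GroundTruth:
    """Planted structure of one simulated database."""

    planted: list[tuple[str, str, str, float]]  # (drug1, drug2, pt, log-odds)
    drug_causal_pts: dict[str, set[str]]  # individual drug -> affected PTs
    indication_treated_by: dict[str, str]  # drug -> indication boosting it
    indication_pt_effects: dict[str, str]  # indication -> affected PT
    ontology: AdeOntology
    drug_labels: DrugAdeLabels
    true_pair_labels: dict[str, set[tuple[str, str]]]  # ade -> positive pairs

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b, _, _ in self.planted}

    @property
    def planted_pair_pts(self) -> set[tuple[str, str, str]]:
        return {(*canonical_pair(a, b), pt) for a, b, pt, _ in self.planted}


def _sim_ontology(cfg: SimConfig, planted_pts: Sequence[str]) -> AdeOntology:
    """Group the simulated PTs into synthetic ADEs (2 main + 2 supporting).

    Planted PTs are placed first so that each synthetic ADE's main slots are
    occupied by PTs that can carry interaction signal.
    """
    ordered = list(planted_pts) + [
        cfg.pt_name(i) for i in range(cfg.n_pts) if cfg.pt_name(i) not in planted_pts
    ]
    mapping: dict[str, tuple[list[str], list[str]]] = {}
    group = 4  # PTs per synthetic ADE
    for k in range(max(1, cfg.n_pts // group)):
        block = ordered[k * group : (k + 1) * group]
        if len(block) < 2:
            break
        mapping[f"ade{k:02d}"] = (block[:2], block[2:])
    return AdeOntology(mapping)


def generate_sr_database(cfg: SimConfig = SimConfig()) -> tuple[SRDatabase, GroundTruth]:
    """Draw a spontaneous-report database under the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    n, nd, ni, npt = cfg.n_reports, cfg.n_drugs, cfg.n_indications, cfg.n_pts
    drugs = [cfg.drug_name(i) for i in range(nd)]
    inds = [cfg.indication_name(i) for i in range(ni)]
    pts = [cfg.pt_name(i) for i in range(npt)]

    # --- structural draws ---------------------------------------------------
    ind_prev = rng.beta(cfg.indication_prev_alpha, cfg.indication_prev_beta, size=ni)
    if not np.any(ind_prev > 0):
        raise ValueError("degenerate config: zero indication prevalence everywhere")
    treats = rng.integers(0, ni, size=nd)  # drug -> confounding indication
    base_drug_logit = _logit(
        min(cfg.mean_drugs_per_report / nd, 0.5)
    ) + rng.normal(0.0, cfg.drug_logit_sd, size=nd)

    # indication -> PT effects (confounding path to the outcome)
    n_conf = int(round(cfg.conf_pt_fraction * ni))
    conf_inds = rng.choice(ni, size=n_conf, replace=False)
    ind_pt = {int(i): int(rng.integers(0, npt)) for i in conf_inds}

    # individual drug -> PT effects
    n_eff = int(round(cfg.drug_effect_fraction * nd))
    eff_drugs = rng.choice(nd, size=n_eff, replace=False)
    drug_pt = {int(d): int(rng.integers(0, npt)) for d in eff_drugs}

    # planted interactions
    if cfg.planted_interactions is None:
        di = {d: i for i, d in enumerate(drugs)}
        pool_pts = rng.choice(npt, size=min(cfg.n_planted, npt), replace=False)
        chosen: list[tuple[str, str, str, float]] = []
        used: set[tuple[int, int]] = set()
        while len(chosen) < cfg.n_planted:
            i, j = sorted(rng.choice(nd, size=2, replace=False).tolist())
            if (i, j) in used:
                continue
            used.add((i, j))
            pt = pts[int(pool_pts[len(chosen) % len(pool_pts)])]
            chosen.append((drugs[i], drugs[j], pt, cfg.interaction_logodds))
        planted = chosen
    else:
        planted = [
            (*canonical_pair(a, b), pt, float(delta))
            for a, b, pt, delta in cfg.planted_interactions
        ]
    pt_index = {p: i for i, p in enumerate(pts)}
    drug_index = {d: i for i, d in enumerate(drugs)}

    # --- vectorized sampling ------------------------------------------------
    ind_mat = rng.random((n, ni)) < ind_prev

    drug_logits = np.tile(base_drug_logit, (n, 1))
    if cfg.conf_ind_drug != 0.0:
        boost = np.zeros((n, nd))
        for d in range(nd):
            boost[:, d] = cfg.conf_ind_drug * ind_mat[:, treats[d]]
        drug_logits += boost
    drug_mat = rng.random((n, nd)) < _sigmoid(drug_logits)
    empty = ~drug_mat.any(axis=1)
    if empty.any():  # force >=1 drug: seeded Gumbel-max over the logits
        g = rng.gumbel(size=(int(empty.sum()), nd))
        drug_mat[np.where(empty)[0], np.argmax(drug_logits[empty] + g, axis=1)] = True

    pt_logits = np.full((n, npt), _logit(cfg.base_pt_rate))
    for i, j in ind_pt.items():
        pt_logits[:, j] += cfg.conf_ind_pt * ind_mat[:, i]
    for d, j in drug_pt.items():
        pt_logits[:, j] += cfg.drug_effect_logodds * drug_mat[:, d]
    for d1, d2, pt, delta in planted:
        both = drug_mat[:, drug_index[d1]] & drug_mat[:, drug_index[d2]]
        pt_logits[:, pt_index[pt]] += delta * both
    pt_mat = rng.random((n, npt)) < _sigmoid(pt_logits)

    planted_pts = sorted({pt for _, _, pt, _ in planted})
    background_pool = [p for p in pts if p not in planted_pts] or pts
    complaint = rng.choice(len(background_pool), size=n)
    bg_idx = np.array([pt_index[p] for p in background_pool])
    pt_mat[np.arange(n), bg_idx[complaint]] = True

    reports = []
    for r in range(n):
        reports.append(
            SpontaneousReport(
                report_id=f"r{r:07d}",
                drugs=frozenset(drugs[i] for i in np.where(drug_mat[r])[0]),
                indications=frozenset(inds[i] for i in np.where(ind_mat[r])[0]),
                reactions=frozenset(pts[i] for i in np.where(pt_mat[r])[0]),
            )
        )
    db = SRDatabase(reports)

    # --- ground truth -------------------------------------------------------
    ontology = _sim_ontology(cfg, planted_pts)
    drug_causal = {drugs[d]: {pts[j]} for d, j in drug_pt.items()}
    labels = DrugAdeLabels()
    for d in drugs:
        for ade in ontology.ades:
            caused = bool(drug_causal.get(d, set()) & ontology.main_pts(ade))
            labels.set(d, ade, "causes" if caused else "not_causes")
    true_pair_labels: dict[str, set[tuple[str, str]]] = {a: set() for a in ontology.ades}
    for ade in ontology.ades:
        main, supp = ontology.main_pts(ade), ontology.supporting_pts(ade)
        per_pair: dict[tuple[str, str], set[str]] = {}
        for d1, d2, pt, delta in planted:
            if delta != 0 and (pt in main or pt in supp):
                per_pair.setdefault(canonical_pair(d1, d2), set()).add(pt)
        for pair, hit in per_pair.items():
            if len(hit & main) >= 2 or (hit & main and hit & supp):
                true_pair_labels[ade].add(pair)
    truth = GroundTruth(
        planted=planted,
        drug_causal_pts=drug_causal,
        indication_treated_by={drugs[d]: inds[treats[d]] for d in range(nd)},
        indication_pt_effects={inds[i]: pts[j] for i, j in ind_pt.items()},
        ontology=ontology,
        drug_labels=labels,
        true_pair_labels=true_pair_labels,
    )
    return db, truth


# ---------------------------------------------------------------------------
# Target profiles, mechanism labels, inference scores
# ---------------------------------------------------------------------------


def generate_target_profiles(
    n_drugs: int,
    n_targets: int,
    mechanism_sparsity: float = 0.02,
    seed: int = 0,
    pa_beta: tuple[float, float] = (1.2, 3.5),
    pi_beta: tuple[float, float] = (1.2, 3.5),
) -> tuple[TargetProfileMatrix, np.ndarray]:
    """I.i.d. Beta-distributed Pa/Pi profiles plus a sparse mechanism vector.

    The mechanism vector has length 2*n_targets and weights the pair
    descriptor (sum half then difference half); it drives label generation
    in :func:`generate_labeled_pairs`.
    """
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    rng = np.random.default_rng(seed)
    drugs = [f"d{i:03d}" for i in range(n_drugs)]
    targets = [f"t{i:04d}" for i in range(n_targets)]
    pa = rng.beta(*pa_beta, size=(n_drugs, n_targets))
    pi = rng.beta(*pi_beta, size=(n_drugs, n_targets))
    profiles = TargetProfileMatrix(drugs, targets, pa, pi)
    k = max(1, int(round(mechanism_sparsity * 2 * n_targets)))
    weights = np.zeros(2 * n_targets)
    active = rng.choice(2 * n_targets, size=k, replace=False)
    weights[active] = rng.normal(0.0, 1.0, size=k)
    return profiles, weights


@dataclass
class SyntheticPairSet:
    """Mechanism-labeled drug pairs with the generating score retained."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    scores: np.ndarray  # latent mechanism score before label noise
    oracle_auc: float  # AUC of the generating score against the noisy labels
    flipped: np.ndarray


def generate_labeled_pairs(
    profiles: TargetProfileMatrix,
    weights: np.ndarray,
    n_pairs: int,
    noise: float = 0.1,
    class_balance: float = 0.5,
    seed: int = 0,
) -> SyntheticPairSet:
    """Label pairs by thresholding a sparse linear mechanism score.

    The threshold is the (1 - class_balance) quantile of scores, so the
    positive fraction matches class_balance in expectation; `noise` flips
    that fraction of labels within each class (balanced flips).
    """
    rng = np.random.default_rng(seed)
    nd = len(profiles.drugs)
    all_pairs = [(i, j) for i in range(nd) for j in range(i + 1, nd)]
    if n_pairs > len(all_pairs):
        raise ValueError("more pairs requested than distinct drug pairs exist")
    take = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    pairs = [
        canonical_pair(profiles.drugs[all_pairs[t][0]], profiles.drugs[all_pairs[t][1]])
        for t in take
    ]
    X = profiles.descriptor_matrix(pairs)
    scores = X @ weights
    thr = np.quantile(scores, 1.0 - class_balance)
    labels = (scores > thr).astype(int)
    flipped = np.zeros(n_pairs, dtype=bool)
    if noise > 0:
        for cls in (0, 1):
            idx = np.where(labels == cls)[0]
            m = int(round(noise * idx.size))
            if m:
                chosen = rng.choice(idx, size=m, replace=False)
                labels[chosen] = 1 - cls
                flipped[chosen] = True
    from sklearn.metrics import roc_auc_score

    oracle = (
        float(roc_auc_score(labels, scores)) if 0 < labels.sum() < n_pairs else 1.0
    )
    return SyntheticPairSet(pairs, labels, scores, oracle, flipped)


def generate_inference_scores(
    pairs: Sequence[tuple[str, str]],
    labels: np.ndarray,
    disease: str,
    effect_size: float = 1.5,
    seed: int = 0,
) -> InferenceScoreTable:
    """Inference scores where drugs of positive pairs score higher.

    Each drug gets an Exponential(1) baseline; drugs appearing in at least
    one positive pair receive an additional Exponential(effect_size) bump.
    effect_size 0 yields exchangeable scores (validation AUC ~ 0.5).
    """
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    rng = np.random.default_rng(seed)
    roster = sorted({d for p in pairs for d in p})
    pos_drugs = {d for p, lab in zip(pairs, np.asarray(labels)) if lab == 1 for d in p}
    table = InferenceScoreTable()
    for d in roster:
        score = rng.exponential(1.0)
        if effect_size > 0 and d in pos_drugs:
            score += rng.exponential(effect_size)
        table.set(d, disease, score)
    return table


# ---------------------------------------------------------------------------
# Fixture emission (complete five-input directory)
# ---------------------------------------------------------------------------


def emit_fixture_dir(
    cfg: SimConfig,
    outdir: str | Path,
    n_targets: int = 200,
) -> dict[str, Path]:
    """Write a complete synthetic input set in the formats the loaders read.

    Emits sr.tsv, ontology.yaml, labels.tsv, target_profiles.tsv,
    inference_scores.tsv and truth.yaml; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db, truth = generate_sr_database(cfg)
    profiles, _ = generate_target_profiles(cfg.n_drugs, n_targets, seed=cfg.seed + 1)
    pair_list = sorted(truth.planted_pairs)
    pos_labels = np.ones(len(pair_list), dtype=int)
    is_table = generate_inference_scores(
        pair_list if pair_list else [("d000", "d001")],
        pos_labels if pair_list else np.zeros(1, int),
        disease=truth.ontology.ades[0],
        seed=cfg.seed + 2,
    )
    paths = {
        "sr": outdir / "sr.tsv",
        "ontology": outdir / "ontology.yaml",
        "labels": outdir / "labels.tsv",
        "profiles": outdir / "target_profiles.tsv",
        "inference_scores": outdir / "inference_scores.tsv",
        "truth": outdir / "truth.yaml",
    }
    write_sr_database(db, paths["sr"])
    truth.ontology.to_yaml(paths["ontology"])
    truth.drug_labels.to_tsv(paths["labels"])
    profiles.to_long_tsv(paths["profiles"])
    is_table.to_tsv(paths["inference_scores"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(
            {
                "planted": [list(p) for p in truth.planted],
                "drug_causal_pts": {d: sorted(v) for d, v in truth.drug_causal_pts.items()},
                "true_pair_labels": {
                    a: sorted(map(list, v)) for a, v in truth.true_pair_labels.items()
                },
            },
            fh,
            sort_keys=True,
        )
    return paths
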