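"""Random-Forest classification of drug pairs with an applicability domain.

Class imbalance is handled by multiple under-sampling: the majority class
is repeatedly sampled down to the minority size, one forest is fitted per
balanced sample, and the ensemble probability is the arithmetic mean of the
sub-model probabilities.

The applicability domain (AD) uses a local tree-vote criterion: the
standard deviation of per-tree predicted probabilities pooled over all
sub-models.  The threshold tau is calibrated at fit time on out-of-bag
votes so that a configured fraction (default 95%) of training pairs fall
inside the domain; probes whose vote dispersion exceeds tau are outside.

Accuracy is estimated by compound-out cross-validation: drugs are
partitioned into k disjoint sets and every test pair contains at least one
drug absent from all training pairs of its fold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .dataset_builder import PairDataset
from .sr_model import normalize_id

logger = logging.getLogger(__name__)

try:  # OOB bootstrap membership (pinned sklearn); fallback below if absent
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )
except ImportError:  # pragma: no cover
    _generate_unsampled_indices = None
    _get_n_samples_bootstrap = None


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def confusion_rates(
    y_true: np.ndarray, prob: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """(sensitivity, specificity) at a probability threshold."""
    y_true = np.asarray(y_true, int)
    pred = np.asarray(prob) > threshold
    pos, neg = y_true == 1, y_true == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


@dataclass
class EnsembleModel:
    """Under-sampled forest ensemble with AD calibration for one ADE."""

    ade: str
    submodels: list[RandomForestClassifier]
    sample_indices: list[np.ndarray]  # training rows used by each sub-model
    seed: int
    n_trees: int
    target_order_hash: str
    tau: float
    ad_coverage: float

    @property
    def M(self) -> int:
        return len(self.submodels)

    def _check_hash(self, target_order_hash: str | None) -> None:
        if target_order_hash is not None and target_order_hash != self.target_order_hash:
            raise ValueError(
                "descriptor target-order hash does not match the model "
                f"({target_order_hash} != {self.target_order_hash})"
            )

    def predict_proba(
        self, X: np.ndarray, target_order_hash: str | None = None
    ) -> np.ndarray:
        """Mean of sub-model probabilities for the positive class."""
        self._check_hash(target_order_hash)
        X = np.atleast_2d(X)
        probs = np.zeros(X.shape[0])
        for rf in self.submodels:
            probs += rf.predict_proba(X)[:, list(rf.classes_).index(1)]
        return probs / self.M

    def tree_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(total_trees x n_probes) per-tree positive-class probabilities."""
        X = np.atleast_2d(X)
        rows = []
        for rf in self.submodels:
            pos = list(rf.classes_).index(1)
            for tree in rf.estimators_:
                rows.append(tree.predict_proba(X)[:, pos])
        return np.asarray(rows)

    def vote_dispersion(self, X: np.ndarray) -> np.ndarray:
        """Std of per-tree probabilities pooled over all sub-models."""
        return self.tree_probabilities(X).std(axis=0)

    def in_ad(self, X: np.ndarray, target_order_hash: str | None = None) -> np.ndarray:
        self._check_hash(target_order_hash)
        return self.vote_dispersion(X) <= self.tau + 1e-12

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "ade": self.ade,
            "seed": self.seed,
            "n_trees": self.n_trees,
            "M": self.M,
            "target_order_hash": self.target_order_hash,
            "tau": self.tau,
            "ad_coverage": self.ad_coverage,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        for m, rf in enumerate(self.submodels):
            joblib.dump(rf, directory / f"submodel_{m:02d}.joblib")
        np.savez(
            directory / "sample_indices.npz",
            **{f"m{m:02d}": idx for m, idx in enumerate(self.sample_indices)},
        )

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        subs = [
            joblib.load(directory / f"submodel_{m:02d}.joblib")
            for m in range(meta["M"])
        ]
        with np.load(directory / "sample_indices.npz") as z:
            idx = [z[f"m{m:02d}"] for m in range(meta["M"])]
        return cls(
            ade=meta["ade"],
            submodels=subs,
            sample_indices=idx,
            seed=meta["seed"],
            n_trees=meta["n_trees"],
            target_order_hash=meta["target_order_hash"],
            tau=meta["tau"],
            ad_coverage=meta["ad_coverage"],
        )


def _oob_tree_mask(rf: RandomForestClassifier, n_samples: int) -> np.ndarray:
    """(n_trees x n_samples) bool: True where the sample is OOB for the tree."""
    oob = np.zeros((len(rf.estimators_), n_samples), dtype=bool)
    if _generate_unsampled_indices is None:  # pragma: no cover
        return oob
    n_boot = _get_n_samples_bootstrap(n_samples, rf.max_samples, None)
    for t, tree in enumerate(rf.estimators_):
        idx = _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
        oob[t, idx] = True
    return oob


def fit_undersampled_forest(
    X: np.ndarray,
    y: np.ndarray,
    M: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    ad_coverage: float = 0.95,
    ade: str = "",
    target_order_hash: str = "",
) -> EnsembleModel:
    """Fit M forests on balanced under-samples and calibrate the AD.

    Each under-sample keeps every minority-class pair and a seeded
    without-replacement sample of the majority class of equal size; a
    balanced input makes the under-sample the full set.  The AD threshold
    is the ad_coverage quantile of training-pair out-of-bag vote
    dispersions.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n = y.size
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    if min(pos_idx.size, neg_idx.size) < 5:
        raise ValueError("each class needs at least 5 pairs")
    minority, majority = sorted((pos_idx, neg_idx), key=lambda a: a.size)
    rng = np.random.default_rng(seed)

    submodels, samples = [], []
    # per-sample OOB vote accumulators across all sub-models
    disp_sum = np.zeros(n)
    disp_sumsq = np.zeros(n)
    disp_count = np.zeros(n)
    for m in range(M):
        take = (
            majority
            if majority.size == minority.size
            else rng.choice(majority, size=minority.size, replace=False)
        )
        idx = np.sort(np.concatenate([minority, take]))
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X[idx], y[idx])
        submodels.append(rf)
        samples.append(idx)

        pos = list(rf.classes_).index(1)
        tree_p = np.asarray([t.predict_proba(X[idx])[:, pos] for t in rf.estimators_])
        oob = _oob_tree_mask(rf, idx.size)
        if oob.any():
            votes = np.where(oob, tree_p, np.nan)
            cnt = oob.sum(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                s = np.nansum(votes, axis=0)
                ss = np.nansum(votes**2, axis=0)
            disp_sum[idx] += s
            disp_sumsq[idx] += ss
            disp_count[idx] += cnt

    seen = disp_count > 1
    if seen.any():
        mean = disp_sum[seen] / disp_count[seen]
        var = np.maximum(disp_sumsq[seen] / disp_count[seen] - mean**2, 0.0)
        oob_disp = np.sqrt(var)
    else:  # pragma: no cover - only without the OOB helpers
        oob_disp = np.zeros(1)
    tau = float(np.quantile(oob_disp, ad_coverage))
    return EnsembleModel(
        ade=ade,
        submodels=submodels,
        sample_indices=samples,
        seed=seed,
        n_trees=n_trees,
        target_order_hash=target_order_hash,
        tau=tau,
        ad_coverage=ad_coverage,
    )


def predict_pair(
    model: EnsembleModel, X: np.ndarray, target_order_hash: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(probability, in_AD) for one or more descriptor vectors."""
    prob = model.predict_proba(X, target_order_hash)
    ad = model.in_ad(X, target_order_hash)
    return prob, ad


def applicability_domain(
    model: EnsembleModel, X: np.ndarray, target_order_hash: str | None = None
) -> np.ndarray:
    return model.in_ad(X, target_order_hash)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Accuracy summary of a cross-validation or external evaluation."""

    ade: str
    fold_aucs: list[float]
    auc: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    ad_fraction: float
    predictions: pd.DataFrame  # drug1, drug2, fold, y, prob, in_ad
    skipped_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ade": self.ade,
            "auc": self.auc,
            "fold_aucs": self.fold_aucs,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "ad_fraction": self.ad_fraction,
            "skipped_folds": self.skipped_folds,
        }


def _metrics_report(
    ade: str,
    preds: pd.DataFrame,
    fold_aucs: list[float],
    skipped: list[int],
    threshold: float = 0.5,
) -> CVReport:
    y, prob, in_ad = preds["y"].to_numpy(), preds["prob"].to_numpy(), preds["in_ad"].to_numpy()
    auc = float(roc_auc_score(y, prob)) if len(np.unique(y)) == 2 else float("nan")
    if in_ad.any():
        sens, spec = confusion_rates(y[in_ad], prob[in_ad], threshold)
    else:
        sens = spec = float("nan")
    return CVReport(
        ade=ade,
        fold_aucs=fold_aucs,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        ad_fraction=float(in_ad.mean()),
        predictions=preds,
        skipped_folds=skipped,
    )


def assign_drug_folds(drugs: Sequence[str], k: int, seed: int) -> dict[str, int]:
    """Seeded partition of distinct drugs into k disjoint fold sets."""
    drugs = sorted({normalize_id(d) for d in drugs})
    if len(drugs) < 2 * k:
        raise ValueError(f"need at least {2 * k} distinct drugs for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drugs))
    return {drugs[i]: f for f, chunk in enumerate(np.array_split(order, k)) for i in chunk}


def compound_out_cv(
    dataset: PairDataset,
    X: np.ndarray,
    k: int = 5,
    seed: int = 0,
    M: int = 10,
    n_trees: int = 500,
    ad_coverage: float = 0.95,
    threshold: float = 0.5,
    target_order_hash: str = "",
) -> CVReport:
    """Compound-out k-fold cross-validation.

    Fold f tests the pairs whose lexicographically-first drug lies in drug
    set f and trains on pairs with both drugs outside set f, so every test
    pair contains a drug absent from all its training pairs and every pair
    is evaluated exactly once.  Sensitivity/specificity/balanced accuracy
    are computed on in-AD test pairs at the probability threshold; AUC is
    pooled over all test predictions.
    """
    fold_of = assign_drug_folds(dataset.roster, k, seed)
    pair_fold = np.array([fold_of[min(p)] for p in dataset.pairs])
    y = dataset.labels
    frames, fold_aucs, skipped = [], [], []
    for f in range(k):
        test_mask = pair_fold == f
        train_mask = np.array(
            [fold_of[p[0]] != f and fold_of[p[1]] != f for p in dataset.pairs]
        )
        if not test_mask.any():
            continue
        ytr = y[train_mask]
        if ytr.sum() < 5 or (ytr.size - ytr.sum()) < 5:
            logger.warning("fold %d skipped: a training class has <5 pairs", f)
            skipped.append(f)
            continue
        model = fit_undersampled_forest(
            X[train_mask],
            ytr,
            M=M,
            n_trees=n_trees,
            seed=seed + 1000 + f,
            ad_coverage=ad_coverage,
            ade=dataset.ade,
            target_order_hash=target_order_hash,
        )
        prob, ad = predict_pair(model, X[test_mask])
        yte = y[test_mask]
        if len(np.unique(yte)) == 2:
            fold_aucs.append(float(roc_auc_score(yte, prob)))
        frames.append(
            pd.DataFrame(
                {
                    "drug1": [p[0] for p, m in zip(dataset.pairs, test_mask) if m],
                    "drug2": [p[1] for p, m in zip(dataset.pairs, test_mask) if m],
                    "fold": f,
                    "y": yte,
                    "prob": prob,
                    "in_ad": ad,
                }
            )
        )
    if not frames:
        raise ValueError("no evaluable folds")
    preds = pd.concat(frames, ignore_index=True)
    return _metrics_report(dataset.ade, preds, fold_aucs, skipped, threshold)


def evaluate_external(
    model: EnsembleModel,
    pairs: Sequence[tuple[str, str]],
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
    target_order_hash: str | None = None,
) -> CVReport:
    """CV-shaped accuracy report on an externally labeled pair set."""
    prob, ad = predict_pair(model, X, target_order_hash)
    preds = pd.DataFrame(
        {
            "drug1": [p[0] for p in pairs],
            "drug2": [p[1] for p in pairs],
            "fold": 0,
            "y": np.asarray(y, int),
            "prob": prob,
            "in_ad": ad,
        }
    )
    auc = [float(roc_auc_score(y, prob))] if len(np.unique(y)) == 2 else []
    return _metrics_report(model.ade, preds, auc, [], threshold)


# ---------------------------------------------------------------------------
# Library screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSummary:
    """Counts of a large-library screen at nested probability thresholds."""

    total: int
    in_ad: int
    counts: dict[float, int]  # threshold -> in-AD pairs above it

    def __post_init__(self) -> None:
        prev = self.in_ad
        for thr in sorted(self.counts):
            if self.counts[thr] > prev:
                raise ValueError("threshold counts must be nested")
            prev = self.counts[thr]
        if self.in_ad > self.total:
            raise ValueError("in-AD count cannot exceed total")


def screen_pair_library(
    model: EnsembleModel,
    pairs: Sequence[tuple[str, str]],
    X: np.ndarray,
    thresholds: Sequence[float] = (0.5, 0.8),
    target_order_hash: str | None = None,
    hist_bins: int = 20,
) -> tuple[ScreenSummary, pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Predict a pair library; summarize in-AD counts above each threshold.

    Returns (summary, per-pair table, probability histogram (counts, edges)).
    """
    if len(pairs) == 0:
        hist = np.histogram(np.empty(0), bins=hist_bins, range=(0.0, 1.0))
        empty = pd.DataFrame(columns=["drug1", "drug2", "prob", "in_ad"])
        return ScreenSummary(0, 0, {t: 0 for t in thresholds}), empty, hist
    prob, ad = predict_pair(model, X, target_order_hash)
    table = pd.DataFrame(
        {
            "drug1": [p[0] for p in pairs],
            "drug2": [p[1] for p in pairs],
            "prob": prob,
            "in_ad": ad,
        }
    )
    counts = {float(t): int(((prob > t) & ad).sum()) for t in thresholds}
    summary = ScreenSummary(total=len(pairs), in_ad=int(ad.sum()), counts=counts)
    hist = np.histogram(prob, bins=hist_bins, range=(0.0, 1.0))
    return summary, table, hist
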