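"""Propensity-adjusted LASSO inference of drug-drug interaction signals.

For each drug in a candidate pair, a per-report propensity score (PS) is
estimated by unpenalized logistic regression of drug presence on the top-100
most relevant indications and top-100 co-administered drugs (relevance =
phi correlation, sqrt(chi2/N)).  The PS is kept on the logit (linear
predictor) scale.

For each screened (pair, PT) association, PT presence is regressed on

    PS1, PS2, Drug1, Drug2, Drug1*Drug2

with an L1 penalty on the slopes (intercept unpenalized).  The penalty
weight is chosen by 3-fold cross-validation (stratified by PT presence,
minimum mean held-out deviance) over a 50-point log-spaced grid descending
from the smallest weight that zeroes all slopes.  Sign patterns of the
drug-main-effect and interaction coefficients then classify the pair-PT
association as a synergistic interaction, an additive combination of two
individually causal drugs, no interaction, or undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._l1path import l1_logistic_path, lambda_max

from .signal_screen import PairPtSignal, ScreenConfig, canonical_pair, chi_square
from .sr_model import ContingencyTable, DrugAdeLabels, SRDatabase, normalize_id

logger = logging.getLogger(__name__)

Verdict = Literal["synergistic", "additive", "no_ddi", "undetermined"]

#: operationalizes "interaction coefficient equals zero"; L1 produces exact
#: zeros, so this only guards floating-point noise.
BETA_EPS = 1e-10

# absolute-coefficient cap above which the propensity fit is considered
# separated and refit with a mild ridge penalty
_SEPARATION_CAP = 30.0


# ---------------------------------------------------------------------------
# Relevance ranking and propensity scores
# ---------------------------------------------------------------------------


def _phi_from_masks(target: np.ndarray, feature: np.ndarray) -> float:
    a = int(np.count_nonzero(target & feature))
    b = int(np.count_nonzero(~target & feature))
    c = int(np.count_nonzero(target & ~feature))
    d = target.size - a - b - c
    t = ContingencyTable(a, b, c, d)
    return float(np.sqrt(chi_square(t) / target.size))


def phi_relevance(db: SRDatabase, drug: str, feature: str) -> float:
    """Phi correlation of drug presence with an indication or co-drug.

    Phi = sqrt(chi2 / N) on the 2x2 presence table over all reports; a zero
    marginal yields 0.  The feature id is looked up among indications first,
    then among drugs.
    """
    drug_key = normalize_id(drug)
    feat_key = normalize_id(feature)
    if feat_key == drug_key:
        raise ValueError("feature must differ from the drug itself")
    target = db.drug_mask(drug_key)
    if feat_key in db._indication_index:
        feat = db.indication_mask(feat_key)
    else:
        feat = db.drug_mask(feat_key)
    return _phi_from_masks(target, feat)


def _phi_vector(target: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Vectorized phi of one target mask against many feature columns."""
    n = target.size
    n1 = int(target.sum())
    f = features.sum(axis=0).astype(float)
    a = target @ features  # co-occurrence counts
    row1, row2 = float(n1), float(n - n1)
    col1, col2 = f, n - f
    denom = row1 * row2 * col1 * col2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * (n - n1 - f + a) - (f - a) * (n1 - a)) ** 2 / denom
    chi2 = np.where(denom > 0, chi2, 0.0)
    return np.sqrt(chi2 / n)


def select_ps_features(
    db: SRDatabase, drug: str, k: int = 100
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top-k indications and top-k co-drugs by phi relevance to the drug.

    Ties are broken by lexicographic id; fewer than k available features are
    all returned.  Returns ([(indication, phi)...], [(co_drug, phi)...]).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    drug_key = normalize_id(drug)
    target = db.drug_mask(drug_key)

    def top(ids: list[str], kind: str) -> list[tuple[str, float]]:
        if not ids:
            return []
        phis = _phi_vector(target, db.presence_matrix(ids, kind=kind))
        ranked = sorted(zip(ids, phis), key=lambda x: (-x[1], x[0]))
        return [(i, float(p)) for i, p in ranked[:k]]

    inds = top(db.indications, "indication")
    codrugs = top([d for d in db.drugs if d != drug_key], "drug")
    return inds, codrugs


@dataclass
class PropensityModel:
    """Fitted per-report exposure propensity for one drug (logit scale)."""

    drug: str
    indication_features: list[tuple[str, float]]
    codrug_features: list[tuple[str, float]]
    intercept: float
    coef_indications: np.ndarray
    coef_codrugs: np.ndarray
    ps: np.ndarray  # linear predictor per report
    ridge_fallback: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ps)):
            raise ValueError("propensity scores must be finite")


def fit_propensity(
    db: SRDatabase,
    drug: str,
    features: tuple[list[tuple[str, float]], list[tuple[str, float]]] | None = None,
    k: int = 100,
) -> PropensityModel:
    """Logistic regression of drug presence on selected binary features.

    The fit is effectively unpenalized (very weak L2); if any coefficient
    exceeds an absolute cap — the symptom of quasi-complete separation — the
    model is refit with a mild ridge penalty and flagged.
    """
    drug_key = normalize_id(drug)
    if features is None:
        features = select_ps_features(db, drug_key, k=k)
    inds, codrugs = features
    y = db.drug_mask(drug_key).astype(int)
    cols = [i for i, _ in inds] + [c for c, _ in codrugs]
    if not cols or y.all() or not y.any():
        # constant exposure or no features: intercept-only propensity
        p = max(min(y.mean(), 1 - 1e-12), 1e-12)
        intercept = float(np.log(p / (1 - p)))
        return PropensityModel(
            drug_key, inds, codrugs, intercept,
            np.zeros(len(inds)), np.zeros(len(codrugs)),
            np.full(db.n, intercept),
        )
    X = np.hstack(
        [
            db.presence_matrix([i for i, _ in inds], kind="indication"),
            db.presence_matrix([c for c, _ in codrugs], kind="drug"),
        ]
    ).astype(np.float64)

    def _fit(c_val: float) -> LogisticRegression:
        clf = LogisticRegression(C=c_val, solver="lbfgs", max_iter=1000, tol=1e-8)
        clf.fit(X, y)
        return clf

    clf = _fit(1e8)
    fallback = False
    if np.max(np.abs(clf.coef_)) > _SEPARATION_CAP:
        logger.warning("propensity fit for %s separated; ridge fallback", drug_key)
        clf = _fit(1e3)
        fallback = True
    ps = X @ clf.coef_.ravel() + float(clf.intercept_[0])
    return PropensityModel(
        drug_key,
        inds,
        codrugs,
        float(clf.intercept_[0]),
        clf.coef_.ravel()[: len(inds)].copy(),
        clf.coef_.ravel()[len(inds):].copy(),
        ps,
        ridge_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# Per-(pair, PT) LASSO
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LassoConfig:
    """Settings of the per-(pair, PT) penalized fit.

    selection: "one_se" picks the largest penalty whose mean CV deviance is
    within one standard error of the minimum (parsimony rule); "min_cv"
    picks the deviance minimum.  standardize_binary controls whether the
    0/1 drug and interaction indicators are scaled to unit variance before
    penalization; on their natural scale the penalty is paid per log-odds
    unit, which keeps rare indicator columns from being spuriously cheap.
    """

    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    cv_folds: int = 3
    selection: str = "one_se"  # or "min_cv"
    standardize_binary: bool = False
    subsample: int | None = None  # seeded report subsample; None = all reports
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection not in ("one_se", "min_cv"):
            raise ValueError(f"unknown selection rule {self.selection!r}")


@dataclass
class LassoFit:
    """L1-penalized interaction fit for one (pair, PT).

    Coefficients are on the original predictor scale and ordered
    (intercept, PS1, PS2, Drug1, Drug2, Drug1*Drug2).
    """

    pair: tuple[str, str]
    pt: str
    beta: np.ndarray  # length 6
    lam: float
    cv_deviance: np.ndarray | None = None
    lambda_grid: np.ndarray | None = None
    degenerate: bool = False

    @property
    def beta3(self) -> float:
        return float(self.beta[3])

    @property
    def beta4(self) -> float:
        return float(self.beta[4])

    @property
    def beta5(self) -> float:
        return float(self.beta[5])


def _l1_path_fit(
    X: np.ndarray, y: np.ndarray, lams: np.ndarray, tol: float = 1e-5
) -> list[tuple[np.ndarray, float]]:
    """Fit the L1 logistic path; returns (slopes, intercept) per lambda."""
    b0s, betas = l1_logistic_path(X, y, np.asarray(lams, float), tol=tol)
    return [(betas[i], float(b0s[i])) for i in range(len(lams))]


def fit_pair_pt_lasso(
    db: SRDatabase,
    pair: tuple[str, str],
    pt: str,
    ps1: np.ndarray,
    ps2: np.ndarray,
    cfg: LassoConfig = LassoConfig(),
) -> LassoFit:
    """Cross-validated L1 logistic fit of PT presence for one drug pair."""
    d1, d2 = canonical_pair(*pair)
    pt_key = normalize_id(pt)
    y = db.reaction_mask(pt_key).astype(int)
    m1 = db.drug_mask(d1).astype(float)
    m2 = db.drug_mask(d2).astype(float)
    X = np.column_stack([ps1, ps2, m1, m2, m1 * m2])

    if cfg.subsample is not None and cfg.subsample < db.n:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(db.n, size=cfg.subsample, replace=False)
        X, y = X[idx], y[idx]

    if y.sum() == 0 or y.sum() == y.size:
        return LassoFit((d1, d2), pt_key, np.zeros(6), 0.0, degenerate=True)

    if cfg.standardize_binary:
        mu, sd = X.mean(axis=0), X.std(axis=0)
    else:  # center/scale the continuous PS columns only
        binary = np.array([False, False, True, True, True])
        mu = np.where(binary, 0.0, X.mean(axis=0))
        sd = np.where(binary, 1.0, X.std(axis=0))
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd

    lam_max = lambda_max(Xs, y)
    if lam_max <= 0:
        return LassoFit((d1, d2), pt_key, np.zeros(6), 0.0, degenerate=True)
    lams = np.geomspace(lam_max, cfg.lambda_min_ratio * lam_max, cfg.n_lambdas)

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    dev_folds = np.zeros((cfg.cv_folds, cfg.n_lambdas))
    for f, (train, val) in enumerate(skf.split(Xs, y)):
        # lambda selection tolerates a looser fit than the final coefficients
        fits = _l1_path_fit(Xs[train], y[train], lams, tol=1e-4)
        Xv, yv = Xs[val], y[val]
        for i, (w, b) in enumerate(fits):
            p = 1.0 / (1.0 + np.exp(-(Xv @ w + b)))
            p = np.clip(p, 1e-15, 1 - 1e-15)
            dev_folds[f, i] = -2.0 * float(
                np.mean(yv * np.log(p) + (1 - yv) * np.log1p(-p))
            )
    dev = dev_folds.mean(axis=0)
    i_min = int(np.argmin(dev))  # ties resolve to the larger penalty
    if cfg.selection == "one_se":
        se = float(dev_folds[:, i_min].std(ddof=1) / np.sqrt(cfg.cv_folds))
        best = int(np.argmax(dev <= dev[i_min] + se))  # largest qualifying penalty
    else:
        best = i_min

    # final fit: warm-started full-data path, truncated at the selected lambda
    w, b = _l1_path_fit(Xs, y, lams[: best + 1])[-1]
    slopes = w / sd
    intercept = b - float(slopes @ mu)
    beta = np.concatenate([[intercept], slopes])
    return LassoFit((d1, d2), pt_key, beta, float(lams[best]), dev, lams)


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionCall:
    pair: tuple[str, str]
    pt: str
    verdict: Verdict
    rule: str
    fit: LassoFit | None = None


def classify_interaction(
    fit: LassoFit | None,
    screen: PairPtSignal | None,
    comention: int,
    labels: DrugAdeLabels,
    ade: str,
    cfg: ScreenConfig = ScreenConfig(),
    pair: tuple[str, str] | None = None,
    pt: str | None = None,
) -> InteractionCall:
    """Sign-based interaction verdict for one (pair, PT).

    Screened associations: a positive interaction coefficient is a
    synergistic interaction; a zero interaction with two positive main
    effects of individually causal drugs is additive; non-positive main
    effect(s) with a non-positive interaction mean no interaction.
    Unscreened associations of well-reported pairs (>= 500 co-mentions)
    are negative evidence; otherwise the verdict is undetermined.
    """
    if screen is not None:
        pair = screen.pair
        pt = screen.pt
    elif fit is not None:
        pair, pt = fit.pair, fit.pt
    elif pair is None or pt is None:
        raise ValueError("need a screen result, a fit, or explicit pair and pt")
    pair = canonical_pair(*pair)
    pt = normalize_id(pt)

    if screen is None or not screen.passed:
        if comention >= cfg.negative_comention_min:
            return InteractionCall(pair, pt, "no_ddi", "unscreened_well_reported")
        return InteractionCall(pair, pt, "undetermined", "unscreened_sparse")

    if fit is None or fit.degenerate:
        return InteractionCall(pair, pt, "undetermined", "degenerate_fit", fit)

    b3, b4, b5 = fit.beta3, fit.beta4, fit.beta5
    if b5 > BETA_EPS:
        return InteractionCall(pair, pt, "synergistic", "interaction_positive", fit)
    if abs(b5) <= BETA_EPS and b3 > 0 and b4 > 0:
        if labels.causes(pair[0], ade) and labels.causes(pair[1], ade):
            return InteractionCall(pair, pt, "additive", "main_effects_causal", fit)
    if (b3 <= 0 or b4 <= 0) and b5 <= BETA_EPS:
        return InteractionCall(pair, pt, "no_ddi", "no_positive_effects", fit)
    return InteractionCall(pair, pt, "undetermined", "ambiguous_coefficients", fit)


# ---------------------------------------------------------------------------
# Driver over a screened database
# ---------------------------------------------------------------------------


def infer_interactions(
    db: SRDatabase,
    signals: pd.DataFrame,
    labels: DrugAdeLabels,
    pt_to_ade: Mapping[str, str],
    screen_cfg: ScreenConfig = ScreenConfig(),
    lasso_cfg: LassoConfig = LassoConfig(),
    ps_k: int = 100,
) -> list[InteractionCall]:
    """Interaction calls for every (pair, PT) row of a bulk screen table.

    Propensity models are fitted once per drug involved in at least one
    screened association and reused across pairs.
    """
    calls: list[InteractionCall] = []
    passed = signals[signals["passed"]]
    ps_cache: dict[str, PropensityModel] = {}

    def ps_for(drug: str) -> np.ndarray:
        if drug not in ps_cache:
            ps_cache[drug] = fit_propensity(db, drug, k=ps_k)
        return ps_cache[drug].ps

    for row in signals.itertuples(index=False):
        pair = (row.drug1, row.drug2)
        table = ContingencyTable(row.A, row.B, row.C, row.D)
        ade = pt_to_ade.get(normalize_id(row.pt), "")
        if row.passed:
            sig = PairPtSignal(pair, row.pt, table, row.prr, row.chi2, True)
            fit = fit_pair_pt_lasso(
                db, pair, row.pt, ps_for(row.drug1), ps_for(row.drug2), lasso_cfg
            )
            calls.append(
                classify_interaction(
                    fit, sig, int(row.comention), labels, ade, screen_cfg
                )
            )
        else:
            calls.append(
                classify_interaction(
                    None,
                    None,
                    int(row.comention),
                    labels,
                    ade,
                    screen_cfg,
                    pair=pair,
                    pt=row.pt,
                )
            )
    return calls


def calls_to_frame(calls: Sequence[InteractionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        beta = c.fit.beta if c.fit is not None else np.full(6, np.nan)
        rows.append(
            {
                "drug1": c.pair[0],
                "drug2": c.pair[1],
                "pt": c.pt,
                "verdict": c.verdict,
                "rule": c.rule,
                **{f"beta{i}": float(beta[i]) for i in range(6)},
                "lam": c.fit.lam if c.fit is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["drug1", "drug2", "pt", "verdict", "rule"]
        + [f"beta{i}" for i in range(6)]
        + ["lam"],
    )
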