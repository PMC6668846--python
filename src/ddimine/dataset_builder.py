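"""Integration of per-PT interaction calls into ADE-level pair datasets.

A drug pair is a positive example for an adverse effect when its
interaction calls (synergistic or additive) touch at least two main PTs of
the effect, or at least one main and one supporting PT.  It is a negative
example when every PT of the effect carries an explicit no-interaction
verdict; any undetermined verdict excludes the pair.  Negative pairs in
which both drugs individually cause the effect are removed as probable
false negatives.

Datasets are externally validated with literature inference scores (IS):
a pair's score is the sum of its drugs' IS for the disease (substituting
the roster-wide maximum IS for drugs already known to cause the effect),
and separation of positives from negatives is quantified by the rank AUC
and a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interaction_inference import InteractionCall
from .signal_screen import canonical_pair
from .sr_model import AdeOntology, DrugAdeLabels, InferenceScoreTable, normalize_id

logger = logging.getLogger(__name__)

PairLabel = Literal["positive", "negative", "excluded"]

LINKED_VERDICTS = frozenset({"synergistic", "additive"})


def integrate_pts(
    calls: Iterable[InteractionCall], ontology: AdeOntology, ade: str
) -> tuple[PairLabel, str]:
    """Collapse one pair's per-PT calls into an ADE-level label.

    Returns (label, provenance); provenance records the PTs that drove the
    decision.  Calls for PTs outside the ADE's ontology entry are ignored.
    """
    main = ontology.main_pts(ade)
    supporting = ontology.supporting_pts(ade)
    verdict_by_pt: dict[str, str] = {}
    for c in calls:
        if c.pt in main or c.pt in supporting:
            verdict_by_pt[c.pt] = c.verdict

    linked_main = sorted(
        pt for pt, v in verdict_by_pt.items() if pt in main and v in LINKED_VERDICTS
    )
    linked_supp = sorted(
        pt
        for pt, v in verdict_by_pt.items()
        if pt in supporting and v in LINKED_VERDICTS
    )
    if len(linked_main) >= 2 or (linked_main and linked_supp):
        return "positive", "linked:" + ",".join(linked_main + linked_supp)

    all_pts = main | supporting
    if all_pts and all(verdict_by_pt.get(pt) == "no_ddi" for pt in all_pts):
        return "negative", "no_ddi:all_pts"
    return "excluded", "insufficient_evidence"


@dataclass
class PairDataset:
    """Labeled drug pairs (positive / negative) for one adverse effect."""

    ade: str
    pairs: list[tuple[str, str]]
    labels: np.ndarray  # 1 = positive, 0 = negative
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [canonical_pair(*p) for p in self.pairs]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in dataset")
        if not self.provenance:
            self.provenance = [""] * len(self.pairs)

    @property
    def roster(self) -> list[str]:
        return sorted({d for p in self.pairs for d in p})

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug1": [p[0] for p in self.pairs],
                "drug2": [p[1] for p in self.pairs],
                "ade": self.ade,
                "label": np.where(self.labels == 1, "positive", "negative"),
                "provenance": self.provenance,
            }
        )

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "PairDataset":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        ades = df["ade"].unique()
        if len(ades) != 1:
            raise ValueError(f"{path}: expected one ADE per dataset, got {list(ades)}")
        return cls(
            ade=ades[0],
            pairs=list(zip(df["drug1"], df["drug2"])),
            labels=(df["label"] == "positive").astype(int).to_numpy(),
            provenance=list(df["provenance"]),
        )


def build_pair_dataset(
    calls: Sequence[InteractionCall],
    ontology: AdeOntology,
    ade: str,
    labels: DrugAdeLabels | None = None,
) -> PairDataset:
    """Integrate calls pair-by-pair and (optionally) filter false negatives."""
    by_pair: dict[tuple[str, str], list[InteractionCall]] = {}
    for c in calls:
        by_pair.setdefault(c.pair, []).append(c)
    pairs, labs, prov = [], [], []
    for pair in sorted(by_pair):
        label, why = integrate_pts(by_pair[pair], ontology, ade)
        if label == "excluded":
            continue
        pairs.append(pair)
        labs.append(1 if label == "positive" else 0)
        prov.append(why)
    ds = PairDataset(ade=normalize_id(ade), pairs=pairs, labels=np.array(labs, int), provenance=prov)
    if labels is not None:
        ds = filter_false_negatives(ds, labels)
    return ds


def filter_false_negatives(dataset: PairDataset, labels: DrugAdeLabels) -> PairDataset:
    """Drop negative pairs whose both drugs individually cause the ADE."""
    keep = [
        not (
            lab == 0
            and labels.causes(p[0], dataset.ade)
            and labels.causes(p[1], dataset.ade)
        )
        for p, lab in zip(dataset.pairs, dataset.labels)
    ]
    idx = [i for i, k in enumerate(keep) if k]
    return PairDataset(
        ade=dataset.ade,
        pairs=[dataset.pairs[i] for i in idx],
        labels=dataset.labels[idx],
        provenance=[dataset.provenance[i] for i in idx],
    )


# ---------------------------------------------------------------------------
# Inference-score validation
# ---------------------------------------------------------------------------


def pair_inference_score(
    d1: str,
    d2: str,
    ade: str,
    is_table: InferenceScoreTable,
    labels: DrugAdeLabels,
    roster: Sequence[str] | None = None,
) -> float:
    """Sum of per-drug inference scores for the ADE's disease.

    A drug known to cause the ADE contributes the maximal IS over the
    roster (its own low IS would understate an established causal link);
    other drugs contribute their own IS.  A drug absent from the table
    contributes 0 with a warning.
    """
    total = 0.0
    for d in (d1, d2):
        if labels.causes(d, ade):
            total += is_table.max_for_disease(ade, drugs=roster)
        else:
            v = is_table.get(d, ade)
            if v is None:
                logger.warning("no inference score for %s / %s; using 0", d, ade)
                v = 0.0
            total += v
    return total


def score_dataset(
    dataset: PairDataset, is_table: InferenceScoreTable, labels: DrugAdeLabels
) -> np.ndarray:
    roster = dataset.roster
    return np.array(
        [
            pair_inference_score(d1, d2, dataset.ade, is_table, labels, roster)
            for d1, d2 in dataset.pairs
        ]
    )


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counting 1/2."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


@dataclass
class ValidationReport:
    ade: str
    auc: float
    wilcoxon_p: float
    n_positive: int
    n_negative: int
    scores: np.ndarray

    def to_dict(self) -> dict:
        return {
            "ade": self.ade,
            "auc": self.auc,
            "wilcoxon_p": self.wilcoxon_p,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def validate_dataset(dataset: PairDataset, scores: np.ndarray) -> ValidationReport:
    """Rank-AUC and Wilcoxon rank-sum separation of pair scores by label."""
    scores = np.asarray(scores, float)
    if scores.shape[0] != len(dataset):
        raise ValueError("one score per pair required")
    pos = scores[dataset.labels == 1]
    neg = scores[dataset.labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(f"dataset {dataset.ade!r}: a class is empty")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return ValidationReport(
        ade=dataset.ade,
        auc=float(res.statistic / (pos.size * neg.size)),
        wilcoxon_p=float(res.pvalue),
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        scores=scores,
    )
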