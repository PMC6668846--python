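"""Disproportionality screen for (drug pair, preferred term) associations.

The screen computes the proportional reporting ratio

    PRR = A (B + D) / (B (A + C))

on the 2x2 exposure-event table of a drug pair versus a reaction PT, plus
the uncorrected Pearson chi-square, and flags a candidate association when
PRR >= 2, A >= 3 and chi-square >= 4 (boundaries inclusive).  Candidate
pairs are all unordered pairs of labeled drugs co-mentioned in at least
100 reports.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sr_model import ContingencyTable, SRDatabase, co_mention_count, normalize_id


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the disproportionality screen.

    negative_comention_min is used downstream: a pair failing the screen for
    a PT but co-mentioned in at least this many reports is called a
    no-interaction pair for that PT.
    """

    prr_min: float = 2.0
    a_min: int = 3
    chi2_min: float = 4.0
    min_comention: int = 100
    negative_comention_min: int = 500
    yates: bool = False  # continuity correction; off by default

    def __post_init__(self) -> None:
        if min(self.prr_min, self.a_min, self.chi2_min) < 0:
            raise ValueError("screen thresholds must be nonnegative")
        if min(self.min_comention, self.negative_comention_min) < 0:
            raise ValueError("co-mention thresholds must be nonnegative")


@dataclass(frozen=True)
class PairPtSignal:
    pair: tuple[str, str]
    pt: str
    table: ContingencyTable
    prr: float
    chi2: float
    passed: bool


def canonical_pair(d1: str, d2: str) -> tuple[str, str]:
    a, b = sorted((normalize_id(d1), normalize_id(d2)))
    if a == b:
        raise ValueError("a drug pair requires two distinct drugs")
    return a, b


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio of a 2x2 table; 0 if A=0, inf if B=0<A."""
    if t.A + t.C == 0:
        raise ValueError("PRR undefined: pair absent from every report (A+C=0)")
    if t.A == 0:
        return 0.0
    if t.B == 0:
        return math.inf
    return (t.A * (t.B + t.D)) / (t.B * (t.A + t.C))


def chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 {pair, no pair} x {PT, no PT} table.

    A zero row or column marginal makes the statistic 0 by convention.
    """
    n = t.N
    if n <= 0:
        raise ValueError("empty table")
    row1, row2 = t.A + t.B, t.C + t.D
    col1, col2 = t.A + t.C, t.B + t.D
    if 0 in (row1, row2, col1, col2):
        return 0.0
    diff = abs(t.A * t.D - t.B * t.C)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / (row1 * row2 * col1 * col2)


def screen_pair_pt(
    pair: tuple[str, str],
    pt: str,
    table: ContingencyTable,
    cfg: ScreenConfig = ScreenConfig(),
) -> PairPtSignal:
    """Evaluate the screen conjunction on a precomputed contingency table."""
    ratio = prr(table)
    chi2 = chi_square(table, yates=cfg.yates)
    passed = ratio >= cfg.prr_min and table.A >= cfg.a_min and chi2 >= cfg.chi2_min
    return PairPtSignal(canonical_pair(*pair), normalize_id(pt), table, ratio, chi2, passed)


def enumerate_candidate_pairs(
    db: SRDatabase,
    drugs: Sequence[str],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[tuple[str, str]]:
    """All unordered pairs of the given drugs co-mentioned often enough."""
    uniq = sorted({normalize_id(d) for d in drugs})
    out = []
    for d1, d2 in itertools.combinations(uniq, 2):
        if co_mention_count(db, d1, d2) >= cfg.min_comention:
            out.append((d1, d2))
    return out


def screen_database(
    db: SRDatabase,
    pairs: Sequence[tuple[str, str]],
    pts: Sequence[str],
    cfg: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Bulk screen of many (pair, PT) combinations.

    Vectorizes the contingency counting with boolean presence matrices;
    results are identical to per-query :func:`ddimine.sr_model.count_pair_pt`.
    Returns one row per (pair, pt) with counts, PRR, chi2, comention and the
    passed flag, in deterministic (pair, pt) order.
    """
    pts = sorted({normalize_id(p) for p in pts})
    pairs = sorted({canonical_pair(*p) for p in pairs})
    pt_mat = db.presence_matrix(pts, kind="reaction")
    drug_ids = sorted({d for p in pairs for d in p})
    drug_mat = db.presence_matrix(drug_ids, kind="drug")
    col = {d: j for j, d in enumerate(drug_ids)}
    n = db.n
    pt_totals = pt_mat.sum(axis=0)

    rows = []
    for d1, d2 in pairs:
        pair_mask = drug_mat[:, col[d1]] & drug_mat[:, col[d2]]
        comention = int(pair_mask.sum())
        a_vec = pt_mat[pair_mask].sum(axis=0)
        for j, pt in enumerate(pts):
            a = int(a_vec[j])
            b = int(pt_totals[j]) - a
            c = comention - a
            d = n - a - b - c
            table = ContingencyTable(a, b, c, d)
            if a + c == 0:
                ratio, chi2v, passed = float("nan"), 0.0, False
            else:
                sig = screen_pair_pt((d1, d2), pt, table, cfg)
                ratio, chi2v, passed = sig.prr, sig.chi2, sig.passed
            rows.append(
                {
                    "drug1": d1,
                    "drug2": d2,
                    "pt": pt,
                    "A": a,
                    "B": b,
                    "C": c,
                    "D": d,
                    "comention": comention,
                    "prr": ratio,
                    "chi2": chi2v,
                    "passed": passed,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "drug1",
            "drug2",
            "pt",
            "A",
            "B",
            "C",
            "D",
            "comention",
            "prr",
            "chi2",
            "passed",
        ],
    )
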