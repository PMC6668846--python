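"""Symmetric drug-pair descriptors from per-drug target-interaction profiles.

A target-interaction predictor assigns each (drug, protein target) a
probability of activity Pa and of inactivity Pi.  Each drug is summarized by
the per-target score s_t = Pa/(Pa+Pi); a drug pair is described by the
concatenation of per-target sums s1+s2 and absolute differences |s1-s2|
(2T values for T targets), which is invariant under swapping the drugs.

The target ordering is frozen (lexicographic) when a profile matrix is
loaded and fingerprinted with a short hash; models trained on a descriptor
matrix refuse probes built under a different target order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sr_model import content_hash, normalize_id


def drug_score(pa: float, pi: float) -> float:
    """Activity score Pa/(Pa+Pi); undefined when both probabilities are 0."""
    if pa < 0 or pi < 0:
        raise ValueError("Pa and Pi must be nonnegative")
    if pa + pi == 0:
        raise ValueError("Pa + Pi = 0: activity score undefined")
    return pa / (pa + pi)


@dataclass(frozen=True)
class TargetProfile:
    """One drug's per-target activity profile (aligned to a target order)."""

    drug: str
    targets: tuple[str, ...]
    pa: np.ndarray
    pi: np.ndarray

    @property
    def scores(self) -> np.ndarray:
        return self.pa / (self.pa + self.pi)


class TargetProfileMatrix:
    """All drugs' Pa/Pi values on a common, frozen target panel."""

    def __init__(
        self,
        drugs: Sequence[str],
        targets: Sequence[str],
        pa: np.ndarray,
        pi: np.ndarray,
    ):
        order = np.argsort(np.asarray(targets, dtype=object))
        self.targets: tuple[str, ...] = tuple(np.asarray(targets, dtype=object)[order])
        self.drugs: tuple[str, ...] = tuple(normalize_id(d) for d in drugs)
        self.pa = np.asarray(pa, dtype=float)[:, order]
        self.pi = np.asarray(pi, dtype=float)[:, order]
        if self.pa.shape != (len(self.drugs), len(self.targets)):
            raise ValueError("profile matrix shape mismatch")
        if np.isnan(self.pa).any() or np.isnan(self.pi).any():
            bad = sorted(
                {
                    self.drugs[i]
                    for i in np.unique(np.where(np.isnan(self.pa) | np.isnan(self.pi))[0])
                }
            )
            raise ValueError(f"drugs missing target values: {bad}")
        if np.any(self.pa + self.pi <= 0):
            raise ValueError("Pa + Pi must be positive for every (drug, target)")
        self._row = {d: i for i, d in enumerate(self.drugs)}
        self.scores = self.pa / (self.pa + self.pi)
        self.target_order_hash = content_hash(list(self.targets))

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def profile(self, drug: str) -> TargetProfile:
        i = self._index(drug)
        return TargetProfile(self.drugs[i], self.targets, self.pa[i], self.pi[i])

    def _index(self, drug: str) -> int:
        key = normalize_id(drug)
        if key not in self._row:
            raise KeyError(f"no target profile for drug {key!r}")
        return self._row[key]

    # -- descriptors ---------------------------------------------------------

    def pair_descriptor_vector(self, d1: str, d2: str) -> np.ndarray:
        """2T-vector: per-target score sums then absolute differences."""
        s1 = self.scores[self._index(d1)]
        s2 = self.scores[self._index(d2)]
        return np.concatenate([s1 + s2, np.abs(s1 - s2)])

    def descriptor_matrix(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Stacked descriptor vectors for many pairs (vectorized)."""
        i1 = np.array([self._index(a) for a, _ in pairs], dtype=np.int64)
        i2 = np.array([self._index(b) for _, b in pairs], dtype=np.int64)
        s1, s2 = self.scores[i1], self.scores[i2]
        return np.hstack([s1 + s2, np.abs(s1 - s2)])

    def targets_above_threshold(
        self, drug: str, pa_min: float = 0.3
    ) -> list[tuple[str, float]]:
        """High-confidence targets: Pa strictly above pa_min and Pa > Pi.

        Returns (target, Pa) sorted by Pa descending (ties by target id).
        """
        i = self._index(drug)
        keep = (self.pa[i] > pa_min) & (self.pa[i] > self.pi[i])
        hits = [(self.targets[j], float(self.pa[i, j])) for j in np.where(keep)[0]]
        return sorted(hits, key=lambda x: (-x[1], x[0]))

    # -- IO ------------------------------------------------------------------

    @classmethod
    def from_long_tsv(cls, path: str | Path, sep: str = "\t") -> "TargetProfileMatrix":
        """Read a long-format table with columns drug_id, target_id, pa, pi."""
        df = pd.read_csv(path, sep=sep)
        for col in ("drug_id", "target_id", "pa", "pi"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        df["drug_id"] = df["drug_id"].map(normalize_id)
        df["target_id"] = df["target_id"].map(normalize_id)
        pa = df.pivot(index="drug_id", columns="target_id", values="pa")
        pi = df.pivot(index="drug_id", columns="target_id", values="pi")
        return cls(list(pa.index), list(pa.columns), pa.to_numpy(), pi.to_numpy())

    def to_long_tsv(self, path: str | Path, sep: str = "\t") -> None:
        rows = []
        for i, drug in enumerate(self.drugs):
            for j, tgt in enumerate(self.targets):
                rows.append(
                    {
                        "drug_id": drug,
                        "target_id": tgt,
                        "pa": repr(float(self.pa[i, j])),
                        "pi": repr(float(self.pi[i, j])),
                    }
                )
        pd.DataFrame(rows, columns=["drug_id", "target_id", "pa", "pi"]).to_csv(
            path, sep=sep, index=False
        )
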