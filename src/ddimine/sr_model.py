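"""Data model for spontaneous-report (SR) pharmacovigilance databases.

A spontaneous report lists the drugs a patient received, the indications
(diseases) they were treated for, and the adverse reactions observed — all
coded as MedDRA preferred terms (PTs) for indications/reactions and opaque
ids for drugs.  This module provides the in-memory containers, delimited-text
readers/writers, and the fast counting queries (2x2 contingency tables,
co-mention counts) on which disproportionality screening is built.

Identifiers are case-normalized (trimmed, lower-cased) at load time; no
further standardization (synonym resolution, de-duplication) is attempted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SR_COLUMNS = ("report_id", "drugs", "indications", "reactions")

PtRole = Literal["main", "supporting", "none"]
AdeLabel = Literal["causes", "not_causes", "unknown"]


def normalize_id(s: str) -> str:
    """Canonical identifier form: stripped and lower-cased."""
    return str(s).strip().lower()


# ---------------------------------------------------------------------------
# Reports and the indexed database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpontaneousReport:
    """One spontaneous report: drug set, indication PTs, reaction PTs."""

    report_id: str
    drugs: frozenset[str]
    indications: frozenset[str]
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: empty drug set")
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: empty reaction set")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-event counts for a (drug pair, PT) query.

    A: reports mentioning both drugs of the pair and the PT among reactions;
    B: reports with the PT but not the pair; C: reports with the pair and at
    least one other reaction PT but not this one; D: the remainder.
    """

    A: int
    B: int
    C: int
    D: int
    flagged: bool = False  # set when a queried id is unknown to the database

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def N(self) -> int:
        return self.A + self.B + self.C + self.D


class SRDatabase:
    """Indexed collection of spontaneous reports.

    Builds inverted indexes (drug -> report positions, reaction PT ->
    positions, indication -> positions) so contingency queries run as set
    intersections / boolean-mask operations rather than full scans.
    """

    def __init__(self, reports: Sequence[SpontaneousReport]):
        if not reports:
            raise ValueError("SR database must contain at least one report")
        self.reports: list[SpontaneousReport] = list(reports)
        self._drug_index: dict[str, np.ndarray] = {}
        self._reaction_index: dict[str, np.ndarray] = {}
        self._indication_index: dict[str, np.ndarray] = {}
        self._build_indexes()

    def _build_indexes(self) -> None:
        d: dict[str, list[int]] = {}
        r: dict[str, list[int]] = {}
        ind: dict[str, list[int]] = {}
        for pos, rep in enumerate(self.reports):
            for x in rep.drugs:
                d.setdefault(x, []).append(pos)
            for x in rep.reactions:
                r.setdefault(x, []).append(pos)
            for x in rep.indications:
                ind.setdefault(x, []).append(pos)
        self._drug_index = {k: np.asarray(v, dtype=np.int64) for k, v in d.items()}
        self._reaction_index = {k: np.asarray(v, dtype=np.int64) for k, v in r.items()}
        self._indication_index = {k: np.asarray(v, dtype=np.int64) for k, v in ind.items()}

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.reports)

    @property
    def drugs(self) -> list[str]:
        return sorted(self._drug_index)

    @property
    def reaction_pts(self) -> list[str]:
        return sorted(self._reaction_index)

    @property
    def indications(self) -> list[str]:
        return sorted(self._indication_index)

    def reports_with_drug(self, drug: str) -> np.ndarray:
        return self._drug_index.get(normalize_id(drug), np.empty(0, dtype=np.int64))

    def reports_with_reaction(self, pt: str) -> np.ndarray:
        return self._reaction_index.get(normalize_id(pt), np.empty(0, dtype=np.int64))

    def reports_with_indication(self, ind: str) -> np.ndarray:
        return self._indication_index.get(normalize_id(ind), np.empty(0, dtype=np.int64))

    def drug_mask(self, drug: str) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        m[self.reports_with_drug(drug)] = True
        return m

    def reaction_mask(self, pt: str) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        m[self.reports_with_reaction(pt)] = True
        return m

    def indication_mask(self, ind: str) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        m[self.reports_with_indication(ind)] = True
        return m

    def presence_matrix(self, ids: Sequence[str], kind: str = "drug") -> np.ndarray:
        """Boolean (n_reports x len(ids)) presence matrix for bulk queries."""
        getter = {
            "drug": self.reports_with_drug,
            "reaction": self.reports_with_reaction,
            "indication": self.reports_with_indication,
        }[kind]
        out = np.zeros((self.n, len(ids)), dtype=bool)
        for j, x in enumerate(ids):
            out[getter(x), j] = True
        return out


def count_pair_pt(db: SRDatabase, d1: str, d2: str, pt: str) -> ContingencyTable:
    """2x2 contingency table for an unordered drug pair vs a reaction PT."""
    d1, d2, pt = normalize_id(d1), normalize_id(d2), normalize_id(pt)
    if d1 == d2:
        raise ValueError("a drug pair requires two distinct drugs")
    flagged = (
        d1 not in db._drug_index
        or d2 not in db._drug_index
        or pt not in db._reaction_index
    )
    r1, r2 = db.reports_with_drug(d1), db.reports_with_drug(d2)
    pair = np.intersect1d(r1, r2, assume_unique=True)
    ptr = db.reports_with_reaction(pt)
    a = int(np.intersect1d(pair, ptr, assume_unique=True).size)
    b = int(ptr.size - a)
    c = int(pair.size - a)  # every report carries >=1 reaction PT
    d = db.n - a - b - c
    return ContingencyTable(a, b, c, d, flagged=flagged)


def co_mention_count(db: SRDatabase, d1: str, d2: str) -> int:
    """Number of reports mentioning both drugs, regardless of reactions."""
    d1, d2 = normalize_id(d1), normalize_id(d2)
    if d1 == d2:
        raise ValueError("a drug pair requires two distinct drugs")
    return int(
        np.intersect1d(
            db.reports_with_drug(d1), db.reports_with_drug(d2), assume_unique=True
        ).size
    )


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------


def _parse_cell(cell: object, list_sep: str) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    parts = (normalize_id(p) for p in str(cell).split(list_sep))
    return frozenset(p for p in parts if p)


def load_sr_database(
    path: str | Path, sep: str = "\t", list_sep: str = ";"
) -> SRDatabase:
    """Load a spontaneous-report table from delimited text.

    Expected header: report_id, drugs, indications, reactions; list-valued
    cells joined by ``list_sep``.  Rows without drugs or reactions are
    skipped with a warning carrying the 1-based data line number.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in SR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    reports: list[SpontaneousReport] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        drugs = _parse_cell(row.drugs, list_sep)
        reactions = _parse_cell(row.reactions, list_sep)
        if not drugs or not reactions:
            logger.warning(
                "%s line %d: skipped (empty %s cell)",
                path,
                line_no,
                "drug" if not drugs else "reaction",
            )
            continue
        reports.append(
            SpontaneousReport(
                report_id=str(row.report_id).strip(),
                drugs=drugs,
                indications=_parse_cell(row.indications, list_sep),
                reactions=reactions,
            )
        )
    if not reports:
        raise ValueError(f"{path}: no valid reports")
    return SRDatabase(reports)


def write_sr_database(
    db: SRDatabase, path: str | Path, sep: str = "\t", list_sep: str = ";"
) -> None:
    rows = [
        {
            "report_id": r.report_id,
            "drugs": list_sep.join(sorted(r.drugs)),
            "indications": list_sep.join(sorted(r.indications)),
            "reactions": list_sep.join(sorted(r.reactions)),
        }
        for r in db.reports
    ]
    pd.DataFrame(rows, columns=list(SR_COLUMNS)).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ADE ontology (main / supporting preferred terms per adverse effect)
# ---------------------------------------------------------------------------


class AdeOntology:
    """Mapping of each adverse effect to its main and supporting MedDRA PTs.

    Main PTs name the adverse effect itself; supporting PTs are similar or
    indirectly related conditions.  The two sets are disjoint per effect.
    """

    def __init__(self, mapping: Mapping[str, tuple[Iterable[str], Iterable[str]]]):
        self._map: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
        for ade, (main, supporting) in mapping.items():
            m = frozenset(normalize_id(x) for x in main)
            s = frozenset(normalize_id(x) for x in supporting)
            if not m:
                raise ValueError(f"ADE {ade!r}: main PT set must be nonempty")
            if m & s:
                raise ValueError(f"ADE {ade!r}: main and supporting PTs overlap")
            self._map[normalize_id(ade)] = (m, s)
        if not self._map:
            raise ValueError("ontology is empty")

    @property
    def ades(self) -> list[str]:
        return sorted(self._map)

    def main_pts(self, ade: str) -> frozenset[str]:
        return self._lookup(ade)[0]

    def supporting_pts(self, ade: str) -> frozenset[str]:
        return self._lookup(ade)[1]

    def pts_for(self, ade: str) -> frozenset[str]:
        m, s = self._lookup(ade)
        return m | s

    def all_pts(self) -> frozenset[str]:
        out: set[str] = set()
        for m, s in self._map.values():
            out |= m | s
        return frozenset(out)

    def _lookup(self, ade: str) -> tuple[frozenset[str], frozenset[str]]:
        key = normalize_id(ade)
        if key not in self._map:
            raise KeyError(f"unknown ADE {ade!r}")
        return self._map[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AdeOntology":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            {
                ade: (entry.get("main", []), entry.get("supporting") or [])
                for ade, entry in raw.items()
            }
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            ade: {"main": sorted(m), "supporting": sorted(s)}
            for ade, (m, s) in sorted(self._map.items())
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def pt_role(ontology: AdeOntology, ade: str, pt: str) -> PtRole:
    """Role of a PT for an ADE: 'main', 'supporting' or 'none'."""
    key = normalize_id(pt)
    main, supporting = ontology._lookup(ade)
    if key in main:
        return "main"
    if key in supporting:
        return "supporting"
    return "none"


def cardio_ontology() -> AdeOntology:
    """The shipped ontology of the five cardiovascular adverse effects."""
    ref = resources.files("ddimine.data").joinpath("cardio_ontology.yaml")
    with resources.as_file(ref) as path:
        return AdeOntology.from_yaml(path)


# ---------------------------------------------------------------------------
# Per-drug ADE labels and inference scores
# ---------------------------------------------------------------------------


class DrugAdeLabels:
    """Per-drug labels: does this drug on its own cause a given ADE?"""

    LABELS = ("causes", "not_causes", "unknown")

    def __init__(self, mapping: Mapping[tuple[str, str], str] | None = None):
        self._map: dict[tuple[str, str], AdeLabel] = {}
        for (drug, ade), label in (mapping or {}).items():
            self.set(drug, ade, label)

    def set(self, drug: str, ade: str, label: str) -> None:
        if label not in self.LABELS:
            raise ValueError(f"invalid label {label!r}")
        key = (normalize_id(drug), normalize_id(ade))
        if key in self._map:
            raise ValueError(f"duplicate label for drug/ADE {key}")
        self._map[key] = label  # type: ignore[assignment]

    def get(self, drug: str, ade: str) -> AdeLabel:
        return self._map.get((normalize_id(drug), normalize_id(ade)), "unknown")

    def causes(self, drug: str, ade: str) -> bool:
        return self.get(drug, ade) == "causes"

    @property
    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self._map})

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "DrugAdeLabels":
        df = pd.read_csv(path, sep=sep, dtype=str)
        for col in ("drug_id", "ade_id", "label"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        out = cls()
        for row in df.itertuples(index=False):
            out.set(row.drug_id, row.ade_id, str(row.label).strip())
        return out

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        rows = [
            {"drug_id": d, "ade_id": a, "label": lab}
            for (d, a), lab in sorted(self._map.items())
        ]
        pd.DataFrame(rows, columns=["drug_id", "ade_id", "label"]).to_csv(
            path, sep=sep, index=False
        )


class InferenceScoreTable:
    """Literature-network inference scores (IS) per (drug, disease)."""

    def __init__(self, mapping: Mapping[tuple[str, str], float] | None = None):
        self._map: dict[tuple[str, str], float] = {}
        for (drug, disease), score in (mapping or {}).items():
            self.set(drug, disease, score)

    def set(self, drug: str, disease: str, score: float) -> None:
        score = float(score)
        if not np.isfinite(score) or score < 0:
            raise ValueError(f"inference score must be finite and >= 0, got {score}")
        self._map[(normalize_id(drug), normalize_id(disease))] = score

    def get(self, drug: str, disease: str, default: float | None = None) -> float | None:
        return self._map.get((normalize_id(drug), normalize_id(disease)), default)

    def max_for_disease(self, disease: str, drugs: Iterable[str] | None = None) -> float:
        key = normalize_id(disease)
        if drugs is None:
            vals = [v for (_, dis), v in self._map.items() if dis == key]
        else:
            vals = [
                v
                for d in drugs
                if (v := self._map.get((normalize_id(d), key))) is not None
            ]
        if not vals:
            raise ValueError(f"no inference scores for disease {disease!r}")
        return max(vals)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "InferenceScoreTable":
        df = pd.read_csv(path, sep=sep)
        for col in ("drug_id", "disease_id", "score"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        out = cls()
        for row in df.itertuples(index=False):
            out.set(str(row.drug_id), str(row.disease_id), float(row.score))
        return out

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        rows = [
            {"drug_id": d, "disease_id": dis, "score": repr(v)}
            for (d, dis), v in sorted(self._map.items())
        ]
        pd.DataFrame(rows, columns=["drug_id", "disease_id", "score"]).to_csv(
            path, sep=sep, index=False
        )


def content_hash(items: Sequence[str]) -> str:
    """Short stable hash of an ordered id sequence (target-order fingerprints)."""
    h = hashlib.sha256("\n".join(items).encode()).hexdigest()
    return h[:16]
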