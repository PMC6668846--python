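"""Shared fixtures: tiny hand-built report databases and profile panels."""

from __future__ import annotations

import numpy as np
import pytest

from ddimine.sr_model import SpontaneousReport, SRDatabase
from ddimine.pair_descriptors import TargetProfileMatrix


def make_db(rows):
    """Build a database from (drugs, indications, reactions) iterables."""
    reports = [
        SpontaneousReport(
            report_id=f"r{i}",
            drugs=frozenset(d),
            indications=frozenset(ind),
            reactions=frozenset(rx),
        )
        for i, (d, ind, rx) in enumerate(rows)
    ]
    return SRDatabase(reports)


def random_db(rng, n_reports=200, n_drugs=8, n_inds=4, n_pts=5):
    """Random small database; every report has >=1 drug and >=1 reaction."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    inds = [f"i{i}" for i in range(n_inds)]
    pts = [f"p{i}" for i in range(n_pts)]
    rows = []
    for _ in range(n_reports):
        d = [x for x in drugs if rng.random() < 0.25] or [rng.choice(drugs)]
        ind = [x for x in inds if rng.random() < 0.3]
        rx = [x for x in pts if rng.random() < 0.3] or [rng.choice(pts)]
        rows.append((d, ind, rx))
    return make_db(rows)


@pytest.fixture
def five_report_db():
    """Two reports with {d1,d2,ptx}, one with ptx alone, two unrelated."""
    return make_db(
        [
            (["d1", "d2"], [], ["ptx"]),
            (["d1", "d2"], ["i1"], ["ptx", "pty"]),
            (["d3"], [], ["ptx"]),
            (["d1"], [], ["pty"]),
            (["d4"], ["i2"], ["ptz"]),
        ]
    )


@pytest.fixture
def tiny_profiles():
    drugs = ["a", "b", "c"]
    targets = ["t1", "t2", "t3", "t4"]
    rng = np.random.default_rng(0)
    pa = rng.uniform(0.05, 0.95, size=(3, 4))
    pi = rng.uniform(0.05, 0.95, size=(3, 4))
    return TargetProfileMatrix(drugs, targets, pa, pi)
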