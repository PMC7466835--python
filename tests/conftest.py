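"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emonet.ges import PooledScorer
from emonet.graphs import cpdag_of, enumerate_dags
from emonet.simulate import RoiTimeSeries


def make_series(array, rois=None, subject="s", group="g", condition="c"):
    a = np.asarray(array, dtype=float)
    rois = rois or [f"R{i}" for i in range(a.shape[1])]
    return RoiTimeSeries(
        subject=subject,
        group=group,
        condition=condition,
        data=pd.DataFrame(a, columns=list(rois)),
    )


def exhaustive_best_cpdag(datasets, c):
    """Independent search oracle: enumerate every DAG, score by the pooled
    decomposable BIC, return the CPDAG of the maximum (ties must land in
    the same equivalence class for the comparison to be meaningful)."""
    scorer = PooledScorer(datasets, c)
    best_score, best_dag = -np.inf, None
    for dag in enumerate_dags(scorer.nodes):
        s = scorer.total(dag)
        if s > best_score + 1e-12:
            best_score, best_dag = s, dag
    return cpdag_of(best_dag)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
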