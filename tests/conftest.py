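"""Shared fixtures and independent oracles.

The Efron partial-likelihood oracle below is deliberately written as a
direct transcription of the partial-likelihood definition and maximized by
brute-force grid search — independent of the model-fitting path under
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def efron_partial_loglik(beta: float, times, events, x) -> float:
    """Efron-approximation Cox partial log-likelihood, one binary covariate.

    For each distinct event time with tied event set D (size m) and risk
    set R::

        l(beta) += sum_{i in D} beta x_i
                   - sum_{l=0}^{m-1} log( S_R - (l/m) S_D )

    where S_R = sum_{j in R} exp(beta x_j), S_D = sum_{j in D} exp(beta x_j).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    eb = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        d_mask = (times == t) & (events == 1)
        r_mask = times >= t
        m = int(d_mask.sum())
        s_d = eb[d_mask].sum()
        s_r = eb[r_mask].sum()
        ll += beta * x[d_mask].sum()
        for l in range(m):
            ll -= np.log(s_r - (l / m) * s_d)
    return ll


def grid_search_beta(times, events, x, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Argmax of the Efron partial likelihood over a dense beta grid."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.array([efron_partial_loglik(b, times, events, x) for b in grid])
    return float(grid[np.argmax(ll)])


# Toy right-censored two-group datasets, all with <= 10 records, covering
# untied, tied, and censored configurations.
TOY_COX_DATASETS = {
    # groups interleaved in time so the partial likelihood has an interior
    # maximum (grouped event times with one arm's events strictly first give
    # a monotone likelihood, i.e. separation, by construction)
    "untied": pd.DataFrame(
        {
            "time": [1, 2, 3, 4, 5, 6],
            "event": [1, 1, 1, 1, 1, 0],
            "group": ["A", "B", "A", "B", "A", "B"],
        }
    ),
    "tied": pd.DataFrame(
        {
            "time": [1, 1, 2, 2, 3],
            "event": [1, 1, 1, 1, 1],
            "group": ["A", "B", "A", "B", "A"],
        }
    ),
    "censored": pd.DataFrame(
        {
            "time": [2, 3, 3, 4, 5, 6, 7],
            "event": [1, 0, 1, 1, 0, 1, 1],
            "group": ["A", "A", "B", "B", "A", "B", "B"],
        }
    ),
    "mixed": pd.DataFrame(
        {
            "time": [1, 2, 2, 2, 3, 4, 4, 5, 6, 7],
            "event": [1, 1, 1, 0, 1, 1, 1, 0, 1, 1],
            "group": ["A", "B", "A", "B", "A", "B", "A", "A", "B", "B"],
        }
    ),
}


@pytest.fixture(params=sorted(TOY_COX_DATASETS))
def toy_cox_dataset(request):
    return TOY_COX_DATASETS[request.param].copy()


@pytest.fixture
def small_tracks() -> pd.DataFrame:
    """Hand-written 3-cell track table exercising every event rule."""
    rows = []

    def obs(cell, day, cv, alive, exp="exp1", genotype="WT", mean=500.0):
        rows.append(
            {
                "cell_id": cell,
                "experiment_id": exp,
                "well": "w1",
                "genotype": genotype,
                "day": day,
                "reporter_mean": mean if alive else np.nan,
                "reporter_sd": cv * mean if alive else np.nan,
                "cv": cv if alive else np.nan,
                "alive": alive,
            }
        )

    # crosses the threshold on day 3, survives to day 4
    for day, cv in zip([1, 2, 3, 4], [0.4, 0.5, 0.7, 0.8]):
        obs("c1", day, cv, True)
    # diffuse throughout, dies on day 3
    for day, cv in zip([1, 2], [0.4, 0.5]):
        obs("c2", day, cv, True)
    obs("c2", 3, np.nan, False)
    # prevalent punctate on day 1, survives to day 2
    obs("c3", 1, 0.7, True)
    obs("c3", 2, 0.75, True)
    return pd.DataFrame(rows)
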