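"""Nonparametric discrete-time hazard and survivor estimation.

The life-table hazard at presentation t is the fraction of at-risk trials
whose event occurs at t, ``h(t) = n_events(t) / n_at_risk(t)``; the survivor
function is the cumulative product ``S(t) = prod_{j<=t} (1 - h(j))``.
Presentations with an empty risk set yield missing (not zero) hazards.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["estimate_lifetable", "LifeTableEstimator", "FIGURE_CONDITION_COLS"]

#: the condition grouping used for the study's predicted-function figures
FIGURE_CONDITION_COLS = ["is_patient", "category", "symmetric", "complex", "fragment_type"]


def _one_group(g: pd.DataFrame, time_col: str, event_col: str) -> pd.DataFrame:
    tmax = int(g[time_col].max())
    counts = (
        g.groupby(time_col)[event_col]
        .agg(n_at_risk="size", n_events="sum")
        .reindex(range(1, tmax + 1), fill_value=0)
    )
    n_risk = counts["n_at_risk"].to_numpy(dtype=float)
    events = counts["n_events"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = np.where(n_risk > 0, events / np.where(n_risk > 0, n_risk, 1.0), np.nan)
    if np.isnan(hazard).any():
        warnings.warn(
            "empty risk set at some presentations; hazard reported as missing",
            stacklevel=3,
        )
    survivor = np.cumprod(np.where(np.isnan(hazard), np.nan, 1.0 - hazard))
    return pd.DataFrame(
        {
            "TIME": np.arange(1, tmax + 1),
            "n_at_risk": n_risk.astype(int),
            "n_events": events.astype(int),
            "hazard": hazard,
            "survivor": survivor,
        }
    )


def estimate_lifetable(
    table: pd.DataFrame,
    by: list[str] | str | None = None,
    time_col: str = "TIME",
    event_col: str = "EVENT",
) -> pd.DataFrame:
    """Life table from a person-period table, optionally per condition group."""
    if table.empty:
        raise ValueError("empty person-period table")
    if by is None:
        return _one_group(table, time_col, event_col)
    by = [by] if isinstance(by, str) else list(by)
    pieces = []
    for key, g in table.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        lt = _one_group(g, time_col, event_col)
        for col, val in zip(by, key):
            lt.insert(0, col, val)
        pieces.append(lt)
    return pd.concat(pieces, ignore_index=True)


class LifeTableEstimator(BaseEstimator):
    """Estimator wrapper: ``fit`` computes ``lifetable_`` from person-period data."""

    def __init__(self, by=None, time_col: str = "TIME", event_col: str = "EVENT"):
        self.by = by
        self.time_col = time_col
        self.event_col = event_col

    def fit(self, X: pd.DataFrame, y=None):
        self.lifetable_ = estimate_lifetable(
            X, by=self.by, time_col=self.time_col, event_col=self.event_col
        )
        return self
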