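"""Person-period expansion of subject-by-trial identification records.

A trial whose event (correct naming) occurred at presentation ``k`` is at risk
for presentations 1..k and contributes k rows with ``EVENT = 0,...,0,1``; a
right-censored trial contributes ``max_presentations`` rows, all ``EVENT = 0``.
Hazard models are then ordinary binary regressions on this table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "encode_predictors",
    "expand_to_person_period",
    "collapse_person_period",
    "PersonPeriodExpander",
]

#: raw trial-file column -> model dummy produced by :func:`encode_predictors`
DUMMY_CODING = {
    "is_patient": "Patient",
    "category": "Manmade",  # 1 = manmade, 0 = natural
    "symmetric": "Symmetry",
    "complex": "Complex",
    "fragment_type": "MP",  # 1 = midpoint fragments, 0 = salient-point
    "repetition": "Repetition",
}

_OUTCOME_COLS = ("event_presentation", "censored")


def encode_predictors(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the binary model dummies (Patient, Manmade, Symmetry, Complex, MP,
    Repetition) alongside the raw trial columns."""
    out = trials.copy()
    for raw, dummy in DUMMY_CODING.items():
        if raw not in out.columns:
            continue
        col = out[raw]
        if raw == "category":
            out[dummy] = (col.astype(str).str.lower() == "manmade").astype(int)
        elif raw == "fragment_type":
            out[dummy] = (col.astype(str).str.upper() == "MP").astype(int)
        else:
            out[dummy] = col.astype(int)
    return out


def _durations(trials: pd.DataFrame, max_presentations: int) -> tuple[np.ndarray, np.ndarray]:
    event = pd.to_numeric(trials["event_presentation"], errors="coerce")
    censored = trials["censored"].astype(int).to_numpy()
    has_event = event.notna().to_numpy()
    if np.any(has_event == censored.astype(bool)):
        raise ValueError("each trial must have exactly one of event_presentation / censored=1")
    k = np.where(has_event, event.fillna(max_presentations).to_numpy(dtype=float), max_presentations)
    if np.any(k < 1) or np.any(k > max_presentations):
        raise ValueError("event_presentation must lie in [1, max_presentations]")
    return k.astype(int), has_event


def expand_to_person_period(trials: pd.DataFrame, max_presentations: int = 10) -> pd.DataFrame:
    """Expand trial outcomes into the one-row-per-presentation-at-risk table.

    All non-outcome columns are copied onto every row of their trial; the
    result gains ``trial_id`` (participant + trial index), ``TIME`` and
    ``EVENT`` columns.
    """
    if trials.empty:
        raise ValueError("no trials to expand")
    trials = trials.reset_index(drop=True)
    k, has_event = _durations(trials, max_presentations)

    rep = trials.loc[trials.index.repeat(k)].reset_index(drop=True)
    time = np.concatenate([np.arange(1, n + 1) for n in k])
    event = np.zeros(len(rep), dtype=int)
    last = np.cumsum(k) - 1
    event[last[has_event]] = 1

    if "trial_id" not in rep.columns:
        rep["trial_id"] = (
            rep["participant_id"].astype(str) + ":" + rep["trial_index"].astype(str)
        )
    rep["TIME"] = time
    rep["EVENT"] = event
    drop = [c for c in _OUTCOME_COLS if c in rep.columns]
    return rep.drop(columns=drop)


def collapse_person_period(table: pd.DataFrame, max_presentations: int = 10) -> pd.DataFrame:
    """Inverse of :func:`expand_to_person_period` (round-trip check)."""
    recs = []
    for _, g in table.groupby("trial_id", sort=False):
        g = g.sort_values("TIME")
        if not np.array_equal(g["TIME"].to_numpy(), np.arange(1, len(g) + 1)):
            raise ValueError("TIME must be consecutive 1..k within a trial")
        if g["EVENT"].iloc[:-1].any():
            raise ValueError("EVENT=1 only allowed on the last at-risk row")
        rec = g.iloc[-1].drop(labels=["TIME", "EVENT"]).to_dict()
        if g["EVENT"].iloc[-1] == 1:
            rec["event_presentation"] = int(g["TIME"].iloc[-1])
            rec["censored"] = 0
        else:
            if len(g) != max_presentations:
                raise ValueError("censored trials must span the full horizon")
            rec["event_presentation"] = pd.NA
            rec["censored"] = 1
        recs.append(rec)
    out = pd.DataFrame(recs)
    out["event_presentation"] = out["event_presentation"].astype("Int64")
    return out


class PersonPeriodExpander(BaseEstimator, TransformerMixin):
    """Transformer wrapper around the expansion, for pipeline composition.

    Parameters
    ----------
    max_presentations : censoring horizon (rows per censored trial).
    encode : also add the binary model dummies for the standard trial columns.
    """

    def __init__(self, max_presentations: int = 10, encode: bool = True):
        self.max_presentations = max_presentations
        self.encode = encode

    def fit(self, X: pd.DataFrame, y=None):
        self.n_trials_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.encode:
            X = encode_predictors(X)
        return expand_to_person_period(X, self.max_presentations)
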