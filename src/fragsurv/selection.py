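"""Backward elimination of hazard-model terms under the hierarchical principle.

A term may be removed only if no retained term contains it (same or superset
covariate product with the same or higher time power); at each step the
removable term with the largest Wald p-value above the threshold is dropped
and the model refitted, until every removable term is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .glm import FitResult, fit_hazard_model
from .model_spec import HazardModelSpec, Term

__all__ = ["removable_terms", "backward_select", "SelectionTrace", "BackwardSelector"]


def removable_terms(spec: HazardModelSpec) -> set[str]:
    """Terms not marginal to any retained term; the intercept never is."""
    terms = spec.all_terms()
    out = set()
    for t in terms:
        if t == Term():  # intercept
            continue
        if any(t.is_marginal_to(other) for other in terms):
            continue
        out.add(t.name)
    return out


@dataclass
class SelectionTrace:
    """Audit record of a backward-selection run."""

    steps: list[dict] = field(default_factory=list)
    final_spec: HazardModelSpec | None = None
    final_fit: FitResult | None = None

    def to_dict(self) -> dict:
        return {
            "steps": [
                {k: v for k, v in s.items()} for s in self.steps
            ],
            "final_spec": self.final_spec.to_dict() if self.final_spec else None,
            "final_loglik": self.final_fit.loglik if self.final_fit else None,
        }


def backward_select(
    table: pd.DataFrame,
    full_spec: HazardModelSpec,
    alpha_crit: float = 0.05,
    robust: bool = True,
    cluster: str = "participant_id",
    **fit_kw,
) -> SelectionTrace:
    """Backward elimination by Wald p-value (cluster-robust by default).

    Ties are broken by removing the higher time-power term first, then by
    name, so runs are deterministic.
    """
    spec = full_spec
    trace = SelectionTrace()
    step = 0
    while True:
        fit = fit_hazard_model(table, spec, cluster=cluster, **fit_kw)
        wald = fit.wald(robust=robust)
        # largest p first; ties: higher time power, then alphabetical name
        ranked = sorted(
            removable_terms(spec),
            key=lambda n: (-float(wald.loc[n, "p"]), -_power_of(n), n),
        )
        drop, worst_p = None, -1.0
        if ranked and float(wald.loc[ranked[0], "p"]) > alpha_crit:
            drop, worst_p = ranked[0], float(wald.loc[ranked[0], "p"])
        if drop is None:
            trace.final_spec = spec
            trace.final_fit = fit
            return trace
        step += 1
        spec = spec.drop_term(drop)
        trace.steps.append(
            {"step": step, "term_removed": drop, "p_at_removal": worst_p, "loglik_before": fit.loglik}
        )


def _power_of(name: str) -> int:
    from .model_spec import parse_term

    return parse_term(name).power


class BackwardSelector(BaseEstimator):
    """Estimator wrapper: ``fit`` runs backward selection on person-period data.

    Fitted attributes: ``trace_`` (step records), ``final_spec_`` and
    ``final_fit_`` (the retained model and its FitResult).
    """

    def __init__(
        self,
        full_spec: HazardModelSpec | None = None,
        alpha_crit: float = 0.05,
        robust: bool = True,
        cluster: str = "participant_id",
    ):
        self.full_spec = full_spec
        self.alpha_crit = alpha_crit
        self.robust = robust
        self.cluster = cluster

    def fit(self, X: pd.DataFrame, y=None):
        from .model_spec import full_model_spec

        spec = self.full_spec if self.full_spec is not None else full_model_spec()
        trace = backward_select(
            X, spec, alpha_crit=self.alpha_crit, robust=self.robust, cluster=self.cluster
        )
        self.trace_ = trace.steps
        self.final_spec_ = trace.final_spec
        self.final_fit_ = trace.final_fit
        return self
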