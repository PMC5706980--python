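"""Hazard-model term algebra: specs, design matrices, recentring.

A discrete-time hazard model on the complementary log-log scale is a linear
predictor built from products of binary covariates and powers of centred
presentation number (``PT = TIME - center``)::

    cloglog h(t) = a0 + a1*PT + ... + ad*PT^d  +  sum_j  b_j * X_j * PT^p_j

Terms are named in the conventional product style, e.g. ``Manmade``,
``Manmade*PT^2``, ``Patient*Symmetry*MP*PT``; ``PT^0`` is elided and the
covariate-free power-0 term is the ``Intercept``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Term",
    "HazardModelSpec",
    "parse_term",
    "full_model_spec",
    "recenter_matrix",
    "recenter_coefficients",
]

_PT_RE = re.compile(r"^PT(?:\^(\d+))?$")


@dataclass(frozen=True, order=True)
class Term:
    """One model term: a product of binary covariates times a power of centred time."""

    covariates: tuple[str, ...] = ()
    power: int = 0

    def __post_init__(self):
        if self.power < 0:
            raise ValueError("time power must be >= 0")
        object.__setattr__(self, "covariates", tuple(sorted(self.covariates)))

    @property
    def name(self) -> str:
        parts = list(self.covariates)
        if self.power == 1:
            parts.append("PT")
        elif self.power > 1:
            parts.append(f"PT^{self.power}")
        return "*".join(parts) if parts else "Intercept"

    def is_marginal_to(self, other: "Term") -> bool:
        """True if this term must be retained whenever ``other`` is retained
        (hierarchical principle): covariate subset and no higher time power."""
        return (
            self != other
            and set(self.covariates) <= set(other.covariates)
            and self.power <= other.power
        )

    def value(self, df: pd.DataFrame, time: np.ndarray, center: int) -> np.ndarray:
        col = np.ones(len(df))
        for c in self.covariates:
            col = col * np.asarray(df[c], dtype=float)
        if self.power:
            col = col * (time - center) ** self.power
        return col


def parse_term(name: str) -> Term:
    """Parse ``A*B*PT^2`` (or the colon variant ``A*B:PT^2``) into a Term."""
    name = name.strip()
    if name in ("Intercept", "ONE", "1", ""):
        return Term()
    covs: list[str] = []
    power = 0
    for tok in re.split(r"[*:]", name):
        tok = tok.strip()
        if not tok:
            continue
        m = _PT_RE.match(tok)
        if m:
            power += int(m.group(1) or 1)
        elif tok in ("Intercept", "ONE", "1"):
            continue
        else:
            covs.append(tok)
    return Term(tuple(covs), power)


@dataclass(frozen=True)
class HazardModelSpec:
    """Baseline time polynomial plus covariate/interaction terms.

    Parameters
    ----------
    baseline_degree : polynomial order of centred time in the baseline hazard.
    center : presentation number the time polynomial is centred on, so that
        power-0 coefficients describe effects *at* that presentation.
    terms : covariate-bearing terms (the baseline ``Intercept, PT..PT^d`` are
        implicit and always present).
    """

    baseline_degree: int = 4
    center: int = 1
    terms: tuple[Term, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")
        if self.center < 1:
            raise ValueError("center must be a presentation number >= 1")
        parsed = tuple(t if isinstance(t, Term) else parse_term(t) for t in self.terms)
        if any(not t.covariates for t in parsed):
            raise ValueError("baseline time terms are implicit; terms must carry covariates")
        if len(set(parsed)) != len(parsed):
            raise ValueError("duplicate terms in spec")
        object.__setattr__(self, "terms", parsed)

    # -- term bookkeeping ---------------------------------------------------
    def all_terms(self) -> list[Term]:
        baseline = [Term((), p) for p in range(self.baseline_degree + 1)]
        return baseline + list(self.terms)

    def term_names(self) -> list[str]:
        return [t.name for t in self.all_terms()]

    def covariate_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for c in t.covariates:
                seen.setdefault(c)
        return list(seen)

    def is_hierarchically_closed(self) -> bool:
        # every lower-power same-product term, and every one-covariate-smaller
        # product at each power, must be present
        have = set(self.all_terms())
        for t in have:
            if t.power > 0 and Term(t.covariates, t.power - 1) not in have:
                return False
            for i in range(len(t.covariates)):
                sub = t.covariates[:i] + t.covariates[i + 1 :]
                if Term(sub, t.power) not in have:
                    return False
        return True

    def drop_term(self, term: Term | str) -> "HazardModelSpec":
        term = term if isinstance(term, Term) else parse_term(term)
        if not term.covariates:
            if term.power != self.baseline_degree or term.power == 0:
                raise ValueError(f"cannot drop baseline term {term.name!r}")
            return replace(self, baseline_degree=self.baseline_degree - 1)
        if term not in self.terms:
            raise KeyError(term.name)
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def with_center(self, center: int) -> "HazardModelSpec":
        return replace(self, center=center)

    # -- design matrix ------------------------------------------------------
    def design_matrix(
        self, table: pd.DataFrame, time_col: str = "TIME"
    ) -> tuple[np.ndarray, list[str]]:
        """Build the numeric design matrix for a person-period table."""
        missing = [c for c in self.covariate_names() if c not in table.columns]
        if missing:
            raise KeyError(f"covariates missing from table: {missing}")
        if time_col not in table.columns:
            raise KeyError(f"time column {time_col!r} missing from table")
        time = np.asarray(table[time_col], dtype=float)
        cols = [t.value(table, time, self.center) for t in self.all_terms()]
        return np.column_stack(cols), self.term_names()

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseline_degree": self.baseline_degree,
            "center": self.center,
            "terms": [t.name for t in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HazardModelSpec":
        return cls(
            baseline_degree=int(d.get("baseline_degree", 4)),
            center=int(d.get("center", 1)),
            terms=tuple(parse_term(n) for n in d.get("terms", [])),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "HazardModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def full_model_spec(
    main_effects: tuple[str, ...] = ("Manmade", "Symmetry", "Complex", "MP", "Patient"),
    control_effects: tuple[str, ...] = ("Repetition",),
    baseline_degree: int = 4,
    time_interaction_degree: int = 2,
    center: int = 1,
) -> HazardModelSpec:
    """The saturated starting model for backward selection.

    All main effects, all two-way interactions among the condition dummies,
    and linear/quadratic time interactions for each of those products; the
    control effects (trial repetition) enter as time-invariant main effects.
    """
    products: list[tuple[str, ...]] = [(m,) for m in main_effects]
    for i in range(len(main_effects)):
        for j in range(i + 1, len(main_effects)):
            products.append((main_effects[i], main_effects[j]))
    terms: list[Term] = [Term((c,), 0) for c in control_effects]
    for prod in products:
        for p in range(time_interaction_degree + 1):
            terms.append(Term(prod, p))
    return HazardModelSpec(baseline_degree=baseline_degree, center=center, terms=tuple(terms))


# -- recentring -------------------------------------------------------------

def recenter_matrix(terms: list[Term], old_center: int, new_center: int) -> np.ndarray:
    """Exact linear map M with beta_new = M @ beta_old for a centre shift.

    Within each covariate product the polynomial in (TIME - c) is re-expanded
    around c' via the binomial theorem; this requires the power set of each
    product to be downward closed (guaranteed under hierarchical closure).
    """
    d = new_center - old_center
    idx = {t: i for i, t in enumerate(terms)}
    groups: dict[tuple[str, ...], list[int]] = {}
    for t in terms:
        groups.setdefault(t.covariates, []).append(t.power)
    m = np.zeros((len(terms), len(terms)))
    for covs, powers in groups.items():
        kmax = max(powers)
        if sorted(powers) != list(range(kmax + 1)):
            raise ValueError(
                f"cannot recentre exactly: powers {sorted(powers)} of "
                f"{'*'.join(covs) or 'baseline'} are not downward closed"
            )
        for k in powers:
            row = idx[Term(covs, k)]
            for j in range(k, kmax + 1):
                # (PT + d)^j contributes C(j,k) d^(j-k) to the PT^k coefficient
                col = idx[Term(covs, j)]
                m[row, col] += math.comb(j, k) * d ** (j - k)
    return m


def recenter_coefficients(
    coefficients: "pd.Series | dict[str, float]", old_center: int, new_center: int
) -> pd.Series:
    """Re-express a named coefficient vector around a new centring presentation."""
    s = pd.Series(coefficients, dtype=float)
    terms = [parse_term(n) for n in s.index]
    m = recenter_matrix(terms, old_center, new_center)
    return pd.Series(m @ s.to_numpy(), index=s.index)
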