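"""Simulate the build-up identification experiment.

The generator reproduces the study design: 7 controls plus one patient, 100
object outlines (51 manmade / 49 natural; symmetry more common among manmade
objects), each object shown once per fragmentation type (MP and SP) giving
200 trials per participant, presentation order randomized under the
constraint that an object never occupies two consecutive trials, and up to
10 presentations per trial following the geometric fragmentation schedule.
Identification outcomes are drawn presentation by presentation from a known
cloglog hazard model; trials with no success by the horizon are
right-censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .model_spec import HazardModelSpec, Term, parse_term
from .glm import inverse_cloglog
from .schedule import fragment_percentages

__all__ = [
    "SimulationConfig",
    "default_true_coefficients",
    "make_stimuli",
    "build_design",
    "simulate_dataset",
    "write_trials_csv",
]

TRIAL_COLUMNS = [
    "participant_id",
    "is_patient",
    "trial_index",
    "object_id",
    "category",
    "symmetric",
    "complex",
    "fragment_type",
    "repetition",
    "event_presentation",
    "censored",
]


def default_true_coefficients() -> dict[str, float]:
    """A ten-term reduced truth patterned on the study's fitted final model:
    quartic baseline time polynomial plus time-invariant main effects."""
    return {
        "Intercept": 0.4812,
        "PT": -1.7191,
        "PT^2": 0.6114,
        "PT^3": -0.0854,
        "PT^4": 0.00418,
        "Repetition": 0.5968,
        "Manmade": -0.3262,
        "Symmetry": -0.9747,
        "Complex": -0.7629,
        "Patient": -2.4522,
    }


@dataclass
class SimulationConfig:
    """Design and generative-model parameters for one synthetic dataset."""

    n_controls: int = 7
    include_patient: bool = True
    n_objects: int = 100
    n_manmade: int = 51
    p_symmetric_manmade: float = 0.51
    p_symmetric_natural: float = 0.31
    p_complex: float = 0.5
    max_presentations: int = 10
    alpha: float = 0.77
    center: int = 1
    true_coefficients: dict[str, float] = field(default_factory=default_true_coefficients)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_manmade <= self.n_objects:
            raise ValueError("n_manmade must lie in [0, n_objects]")
        for p in (self.p_symmetric_manmade, self.p_symmetric_natural, self.p_complex):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_controls + int(self.include_patient) < 1:
            raise ValueError("need at least one participant")
        fragment_percentages(self.alpha, self.max_presentations)  # validates alpha

    def participants(self) -> pd.DataFrame:
        rows = [
            {"participant_id": f"C{i:02d}", "is_patient": 0}
            for i in range(1, self.n_controls + 1)
        ]
        if self.include_patient:
            rows.append({"participant_id": "PAT", "is_patient": 1})
        return pd.DataFrame(rows)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls(**(yaml.safe_load(text) or {}))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_stimuli(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """The stimulus set: ids, category, symmetry and complexity flags.

    Symmetric counts per category are fixed at round(p * n) so every dataset
    carries the intended composition; complexity is Bernoulli(p_complex)
    independent of category.
    """
    n, nm = config.n_objects, config.n_manmade
    category = np.array(["manmade"] * nm + ["natural"] * (n - nm))
    sym = np.zeros(n, dtype=int)
    k_m = _round_half_up(config.p_symmetric_manmade * nm)
    k_n = _round_half_up(config.p_symmetric_natural * (n - nm))
    sym[rng.choice(nm, size=k_m, replace=False)] = 1
    sym[nm + rng.choice(n - nm, size=k_n, replace=False)] = 1
    return pd.DataFrame(
        {
            "object_id": [f"obj{i:03d}" for i in range(1, n + 1)],
            "category": category,
            "symmetric": sym,
            "complex": rng.binomial(1, config.p_complex, size=n),
        }
    )


def _constrained_order(n_slots: int, objects: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permutation of slot indices with no equal objects on adjacent trials.

    Rejection with local swap repair: shuffle, then move each offending slot
    to a random position where it creates no new adjacency; reshuffle if a
    repair pass stalls.
    """
    for _ in range(200):
        order = rng.permutation(n_slots)
        for _ in range(50):
            obj = objects[order]
            bad = np.nonzero(obj[1:] == obj[:-1])[0]
            if bad.size == 0:
                return order
            i = int(bad[0]) + 1
            positions = rng.permutation(n_slots)
            for j in positions:
                if j == i:
                    continue
                cand = order.copy()
                cand[i], cand[j] = cand[j], cand[i]
                o = objects[cand]
                touched = {i, j}
                ok = all(
                    o[k] != o[k + 1]
                    for t in touched
                    for k in (t - 1, t)
                    if 0 <= k < n_slots - 1
                )
                if ok:
                    order = cand
                    break
            else:
                break  # no repair found, reshuffle
    raise RuntimeError("could not satisfy the no-adjacent-object constraint")


def build_design(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Trial slots: participant x object x fragment type in randomized order.

    Each object appears exactly twice per participant (once MP, once SP),
    never on two consecutive trials; the repetition flag marks each object's
    second occurrence. Order is re-randomized per participant.
    """
    if config.n_objects < 2:
        raise ValueError("the no-adjacent-repeat constraint needs at least 2 objects")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    stimuli = make_stimuli(config, rng)
    slots = pd.concat(
        [stimuli.assign(fragment_type="MP"), stimuli.assign(fragment_type="SP")],
        ignore_index=True,
    )
    objects = slots["object_id"].to_numpy()
    frames = []
    for _, part in config.participants().iterrows():
        order = _constrained_order(len(slots), objects, rng)
        d = slots.iloc[order].reset_index(drop=True)
        d.insert(0, "is_patient", int(part["is_patient"]))
        d.insert(0, "participant_id", part["participant_id"])
        d["trial_index"] = np.arange(1, len(d) + 1)
        d["repetition"] = d.groupby("object_id").cumcount()
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    config: SimulationConfig,
    model: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw identification outcomes for every trial of the design.

    At each presentation t = 1..max_presentations an at-risk trial succeeds
    with probability ``h(t) = 1 - exp(-exp(eta(t)))``; the first success sets
    ``event_presentation = t``, otherwise the trial is right-censored.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coefs = dict(config.true_coefficients) if model is None else (
        model if isinstance(model, dict) else None
    )
    if coefs is None:
        raise TypeError("model must be a mapping term -> coefficient (or None)")
    design = build_design(config, rng)

    from .person_period import encode_predictors

    enc = encode_predictors(design)
    terms = [parse_term(n) for n in coefs]
    known = set(enc.columns)
    for t in terms:
        missing = [c for c in t.covariates if c not in known]
        if missing:
            raise KeyError(f"term {t.name!r} references unknown covariates {missing}")

    n = len(design)
    tgrid = np.arange(1, config.max_presentations + 1, dtype=float)
    eta = np.zeros((n, len(tgrid)))
    for term, b in zip(terms, coefs.values()):
        xprod = np.ones(n)
        for c in term.covariates:
            xprod = xprod * enc[c].to_numpy(dtype=float)
        eta += np.outer(xprod * b, (tgrid - config.center) ** term.power)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor in simulation")
    hazard = inverse_cloglog(eta)

    # one uniform per trial x presentation, consumed in trial order
    u = rng.random((n, len(tgrid)))
    success = u < hazard
    any_evt = success.any(axis=1)
    first = np.where(any_evt, success.argmax(axis=1) + 1, 0)

    out = design.copy()
    out["event_presentation"] = pd.array(
        np.where(any_evt, first, -1), dtype="Int64"
    )
    out.loc[~any_evt, "event_presentation"] = pd.NA
    out["censored"] = (~any_evt).astype(int)
    return out[TRIAL_COLUMNS]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Trial-level CSV; event_presentation is empty on censored trials."""
    trials.to_csv(path, index=False)
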