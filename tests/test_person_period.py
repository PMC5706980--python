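"""Person-period expansion, collapse round-trip, and design matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fragsurv import (
    HazardModelSpec,
    Term,
    collapse_person_period,
    expand_to_person_period,
)
from fragsurv.model_spec import parse_term, recenter_matrix


def _trial(pid="P1", idx=1, event=None, censored=0, **cov):
    rec = {
        "participant_id": pid,
        "trial_index": idx,
        "event_presentation": event,
        "censored": censored,
    }
    rec.update(cov)
    return rec


def test_event_trial_expands_to_k_rows():
    pp = expand_to_person_period(pd.DataFrame([_trial(event=3, A=1)]), 10)
    assert list(pp["TIME"]) == [1, 2, 3]
    assert list(pp["EVENT"]) == [0, 0, 1]
    assert (pp["A"] == 1).all()  # covariates copied to every row


def test_censored_trial_spans_the_horizon():
    pp = expand_to_person_period(pd.DataFrame([_trial(censored=1)]), 10)
    assert list(pp["TIME"]) == list(range(1, 11))
    assert pp["EVENT"].sum() == 0


def test_all_censored_row_count():
    trials = pd.DataFrame([_trial(idx=i, censored=1) for i in range(1600)])
    pp = expand_to_person_period(trials, 10)
    assert len(pp) == 16000 and pp["EVENT"].sum() == 0


def test_event_beyond_horizon_is_an_error():
    with pytest.raises(ValueError):
        expand_to_person_period(pd.DataFrame([_trial(event=11)]), 10)


def test_event_and_censored_flags_are_exclusive():
    with pytest.raises(ValueError):
        expand_to_person_period(pd.DataFrame([_trial(event=2, censored=1)]), 10)


def test_round_trip_identity(small_trials):
    from fragsurv import encode_predictors

    enc = encode_predictors(small_trials)
    pp = expand_to_person_period(enc, 10)
    back = collapse_person_period(pp, 10)
    cols = ["participant_id", "trial_index", "object_id", "censored"]
    lhs = back.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
    rhs = enc.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(lhs[cols], rhs[cols], check_dtype=False)
    assert lhs["event_presentation"].fillna(-1).astype(int).tolist() == \
        rhs["event_presentation"].fillna(-1).astype(int).tolist()


def test_row_count_is_sum_of_durations(small_trials):
    pp = expand_to_person_period(small_trials, 10)
    dur = small_trials["event_presentation"].fillna(10).astype(int)
    assert len(pp) == int(dur.sum())
    assert pp["EVENT"].sum() == (small_trials["censored"] == 0).sum()


# -- design matrices --------------------------------------------------------

def test_intercept_only_design():
    spec = HazardModelSpec(baseline_degree=0)
    df = pd.DataFrame({"TIME": [4], "EVENT": [0]})
    x, names = spec.design_matrix(df)
    assert names == ["Intercept"] and x.tolist() == [[1.0]]


def test_quartic_time_columns_are_centred_powers():
    spec = HazardModelSpec(baseline_degree=4, center=1)
    df = pd.DataFrame({"TIME": [3]})
    x, _ = spec.design_matrix(df)
    assert x.tolist() == [[1.0, 2.0, 4.0, 8.0, 16.0]]


def test_interaction_column_is_product_times_centred_time():
    spec = HazardModelSpec(baseline_degree=0, center=1, terms=(Term(("Manmade", "Symmetry"), 1),))
    df = pd.DataFrame({"TIME": [5], "Manmade": [1], "Symmetry": [1]})
    x, names = spec.design_matrix(df)
    assert names[-1] == "Manmade*Symmetry*PT"
    assert x[0, -1] == 4.0  # 1 * 1 * (5-1)


def test_missing_covariate_is_named_in_error():
    spec = HazardModelSpec(terms=("Manmade",))
    with pytest.raises(KeyError, match="Manmade"):
        spec.design_matrix(pd.DataFrame({"TIME": [1]}))


def test_term_name_parsing_round_trip():
    for name in ("Intercept", "PT", "PT^3", "Manmade", "MP*Patient*Symmetry*PT^2"):
        assert parse_term(name).name == name
    # covariate order is normalized alphabetically; colon convention accepted
    assert parse_term("Patient*Manmade").name == "Manmade*Patient"
    assert parse_term("A*B:PT^2") == Term(("A", "B"), 2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    c2=st.integers(min_value=1, max_value=9),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_recentring_is_an_invertible_linear_reparameterization(c2, seed):
    """Design matrices at two centres span the same space: X_c b == X_c' (M b)."""
    spec = HazardModelSpec(baseline_degree=3, center=1, terms=(Term(("A",), 0), Term(("A",), 1)))
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"TIME": rng.integers(1, 10, 30), "A": rng.integers(0, 2, 30)})
    x1, names = spec.design_matrix(df)
    x2, _ = spec.with_center(c2).design_matrix(df)
    terms = [parse_term(n) for n in names]
    m = recenter_matrix(terms, 1, c2)
    beta = rng.normal(size=len(names))
    assert np.allclose(x1 @ beta, x2 @ (m @ beta))
    assert np.linalg.matrix_rank(m) == len(names)  # invertible
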