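import numpy as np
import pandas as pd
import pytest

import evtbenefit as eb


@pytest.fixture(scope="session")
def true_model():
    return eb.default_true_model()


@pytest.fixture(scope="session")
def rct_cohort():
    """A mid-size randomized cohort drawn from the default generating model."""
    return eb.generate_cohort(eb.CohortSpec(n=4000, seed=101)).df


@pytest.fixture(scope="session")
def fitted_updated(rct_cohort):
    model = eb.fit_model(rct_cohort, eb.updated_spec())
    assert model.converged
    return model


@pytest.fixture
def profile():
    return eb.PredictorProfile(
        age=70.0,
        nihss=17,
        sbp=150.0,
        glucose=130.0,
        iv_alteplase=1,
        diabetes=0,
        prestroke_mrs=0,
        aspects=9,
        occlusion_location="M1",
        collateral_grade=2,
        onset_to_groin=180.0,
        prior_stroke=0,
        evt=1,
    )


def random_model(rng, spec=None):
    """A small random but valid cumulative-logit model."""
    spec = spec or eb.updated_spec()
    names = spec.design_columns()
    cuts = np.sort(rng.normal(scale=1.5, size=6))
    while np.any(np.diff(cuts) <= 1e-3):
        cuts = np.sort(rng.normal(scale=1.5, size=6))
    beta = rng.normal(scale=0.05, size=len(names))
    return eb.FittedOrdinalModel(
        spec=spec, cutpoints=cuts, coefficients=beta, coef_names=names
    )


def random_profiles(rng, n):
    """Random valid predictor rows as a DataFrame."""
    return pd.DataFrame(
        {
            "age": rng.uniform(30, 90, n),
            "nihss": rng.integers(0, 43, n),
            "sbp": rng.uniform(90, 220, n),
            "glucose": rng.uniform(60, 300, n),
            "iv_alteplase": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "prestroke_mrs": rng.integers(0, 6, n),
            "aspects": rng.integers(0, 11, n),
            "occlusion_location": rng.choice(["ICA/ICA-T", "M1", "M2"], n),
            "collateral_grade": rng.integers(0, 4, n),
            "onset_to_groin": rng.uniform(30, 500, n),
            "prior_stroke": rng.integers(0, 2, n),
            "evt": rng.integers(0, 2, n),
        }
    )


def concordance_oracle(scores, outcomes, larger_outcome_is_better):
    """Exhaustive O(n^2) pairwise enumeration of Harrell's C."""
    s = np.asarray(scores, float)
    o = np.asarray(outcomes, float)
    if not larger_outcome_is_better:
        o = -o
    num = den = 0.0
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            if o[i] == o[j]:
                continue
            den += 1
            better, worse = (i, j) if o[i] > o[j] else (j, i)
            if s[better] > s[worse]:
                num += 1
            elif s[better] == s[worse]:
                num += 0.5
    return num / den
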