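import numpy as np
import pandas as pd
import pytest

from traitspace.schema import Instrument, Item, QuestionnaireSchema
from traitspace.scoring import apply_key
from traitspace.synthetic import build_schema, generate_cohort, study_like_params


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def small_schema():
    """Two instruments: a 1-7 scale with one reverse item, and a graded 1-4
    instrument with binary alternative scoring (autism-quotient style)."""
    return QuestionnaireSchema(
        (
            Instrument(
                name="sens",
                trait="sens",
                items=(
                    Item("sens_q1"),
                    Item("sens_q2", reverse=True),
                    Item("sens_q3", subdomain="A"),
                    Item("sens_q4", subdomain="A"),
                    Item("sens_q5", subdomain="B"),
                ),
                scale=(1, 7),
                scoring="sum",
            ),
            Instrument(
                name="aq",
                trait="aq",
                items=(Item("aq_q1"), Item("aq_q2", reverse=True)),
                scale=(1, 4),
                scoring="sum",
                alt_scoring="binary",
            ),
        )
    )


@pytest.fixture
def small_raw():
    """Five subjects of raw (unkeyed) responses for small_schema."""
    return pd.DataFrame(
        {
            "sens_q1": [1, 2, 3, 4, 5],
            "sens_q2": [2, 2, 3, 6, 7],
            "sens_q3": [7, 6, 5, 4, 3],
            "sens_q4": [1, 1, 2, 2, 3],
            "sens_q5": [4, 4, 4, 5, 5],
            "aq_q1": [1, 2, 3, 4, 1],
            "aq_q2": [4, 3, 2, 1, 4],
        },
        index=pd.Index([f"S{i}" for i in range(1, 6)], name="subject"),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One generated cohort from the default study-like preset (seed 1)."""
    params = study_like_params(seed=1)
    rm, truth = generate_cohort(params)
    return params, rm, truth, build_schema(params)
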