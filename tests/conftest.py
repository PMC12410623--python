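import numpy as np
import pandas as pd
import pytest

import endopredict as ep


@pytest.fixture(scope="session")
def dyspareunia_card() -> ep.ModelCard:
    return ep.load_shipped_card("dyspareunia_external")


@pytest.fixture(scope="session")
def all_cards() -> dict[str, ep.ModelCard]:
    return ep.load_all_shipped_cards()


@pytest.fixture(scope="session")
def small_cohort(dyspareunia_card) -> ep.CohortTable:
    """A small deterministic synthetic cohort drawn from the shipped card."""
    return ep.generate(ep.GeneratorSpec(n=400, seed=1234, truth=dyspareunia_card))


def toy_table(rows: list[dict], scale: str = "vas", predictors: dict | None = None) -> ep.CohortTable:
    """Build a tiny cohort table from literal row dicts."""
    predictors = predictors or {"flag": ep.PredictorSpec(type="binary")}
    df = pd.DataFrame(rows)
    if "id" not in df.columns:
        df.insert(0, "id", [f"r{i}" for i in range(len(df))])
    for name in predictors:
        if name not in df.columns:
            df[name] = 0.0
    cb = ep.Codebook(outcome="pain", scale=scale, predictors=predictors)
    return ep.CohortTable(df, cb)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
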