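import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """Ten-patient single-covariate example dataset.

    Four index results are missing; the covariate is recoded to 0/1.
    Complete-case tally: TP=2, FN=1, TN=2, FP=1.
    """
    return pd.DataFrame(
        {
            "D": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
            "Y": [1, 1, 0, np.nan, np.nan, 0, 0, 1, np.nan, np.nan],
            "X1": [1, 1, 0, 0, 1, 0, 0, 1, 1, 0],
        }
    )


@pytest.fixture
def study_table() -> pd.DataFrame:
    """A generated-then-amputated study table (MAR, 30% missing)."""
    import diagmiss as dm

    sc = dm.ScenarioSpec(0.8, 0.8, "MAR", 0.3, 0.2, 800)
    model = dm.build_latent_model(sc)
    complete = dm.generate_complete(sc, model, 2024)
    return dm.ampute(complete, dm.AmputationConfig("MAR", 0.3), 11)


@pytest.fixture
def complete_table() -> pd.DataFrame:
    import diagmiss as dm

    sc = dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.3, 0.2, 400)
    return dm.generate_complete(sc, dm.build_latent_model(sc), 77)
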