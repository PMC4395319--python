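import numpy as np
import pandas as pd
import pytest

from idmspec import full_structure, generate, msdata, paper_like_config

#: single stratum covering all transitions — lets toy single-risk-set data
#: be fitted through the stratified engine
ONE_STRATUM = (frozenset({"01", "02", "12"}),)


def toy_table(times, status, x, covariate="x"):
    """Single-stratum stacked table from plain survival arrays."""
    return pd.DataFrame(
        {
            "id": np.arange(1, len(times) + 1),
            "transition": "01",
            "tstart": 0.0,
            "tstop": np.asarray(times, float),
            "status": np.asarray(status, int),
            covariate: np.asarray(x, float),
        }
    )


@pytest.fixture(scope="session")
def cohort434():
    """One frozen realistic-scale synthetic cohort."""
    return generate(paper_like_config(434), seed=20)


@pytest.fixture(scope="session")
def stacked434(cohort434):
    return msdata.prepare(cohort434)


@pytest.fixture(scope="session")
def fitted_full(stacked434):
    from idmspec import fit

    return fit(stacked434, full_structure())


@pytest.fixture(scope="session")
def profile_b():
    """A bad-prognosis profile: old, residual tumor, high stage."""
    return {"age": 70.0, "residual_tumor": 1, "figo_high": 1}
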