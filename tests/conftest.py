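import numpy as np
import pandas as pd
import pytest

import fluxpattern as fp
from fluxpattern import io as fio


@pytest.fixture(scope="session")
def toy_recons():
    return fp.toy_reconstructions()


@pytest.fixture(scope="session")
def m1_community(toy_recons):
    """Single-microbe community on 10 units of dietary glucose."""
    model = fp.build_community_model({"M1": 1.0}, toy_recons)
    return fp.apply_diet(model, {"glc": 10.0})


@pytest.fixture(scope="session")
def secretion_cohort():
    """Medium cohort under the secretion scenario, as aligned study tables."""
    params = fp.make_parameters(40, 3, 5, "secretion", effect_scale=1.0, seed=11)
    cohort = fp.simulate_cohort(params, 800, seed=12)
    return params, cohort, fio.cohort_to_tables(cohort, params)


@pytest.fixture(scope="session")
def small_tables():
    """Tiny hand-sized study tables with real-data quirks (zeros, covariates)."""
    rng = np.random.default_rng(7)
    n, n_sp, n_met = 60, 6, 3
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
    raw = rng.gamma(0.6, size=(n, n_sp))
    raw[rng.random((n, n_sp)) < 0.2] = 0.0
    raw[:, 0] += 0.3  # keep one species ubiquitous
    abundance = pd.DataFrame(raw / raw.sum(1, keepdims=True), index=idx,
                             columns=[f"sp{j}" for j in range(n_sp)])
    conc = rng.lognormal(0.0, 1.0, size=(n, n_met))
    conc[rng.random((n, n_met)) < 0.25] = 0.0  # below detection
    metabolome = pd.DataFrame(conc, index=idx, columns=[f"m{j}" for j in range(n_met)])
    flux = pd.DataFrame(rng.gamma(2.0, size=(n, n_met)), index=idx,
                        columns=metabolome.columns)
    covariates = pd.DataFrame({
        "age": rng.integers(30, 80, n).astype(float),
        "BMI": rng.normal(25, 4, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "group": rng.integers(0, 2, n).astype(float),
    }, index=idx)
    return fp.StudyTables(abundance=abundance, metabolome=metabolome,
                          covariates=covariates, flux=flux)
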