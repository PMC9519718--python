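import warnings

import pytest

from metfa import GenomicRelationship, VarianceModelSpec, fit, rotate, simulate_met
from metfa.reml import FitOptions


@pytest.fixture(autouse=True)
def _quiet_mixed_sign_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="first factor has mixed-sign")
        yield


@pytest.fixture(scope="session")
def small_ifa():
    """One small IFA simulation with its fit and rotation, shared across tests."""
    ds, truth = simulate_met(family="IFA", k=2, v=40, p=8, q=3, n_trials=1,
                             n_blocks=2, missing_rate=0.05, grm="markers",
                             n_markers=300, seed=5)
    grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
    fitted = fit(ds, grm, truth.basis, VarianceModelSpec("IFA", k=2), FitOptions())
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="first factor has mixed-sign")
        rot = rotate(fitted)
    return {"dataset": ds, "truth": truth, "grm": grm, "fit": fitted, "rot": rot}


@pytest.fixture(scope="session")
def small_fa():
    """One small FA simulation with its fit, for latent-only families."""
    ds, truth = simulate_met(family="FA", k=1, v=40, p=6, q=2, n_trials=1,
                             n_blocks=2, missing_rate=0.05, grm="markers",
                             n_markers=300, seed=1)
    grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
    fitted = fit(ds, grm, None, VarianceModelSpec("FA", k=1), FitOptions())
    return {"dataset": ds, "truth": truth, "grm": grm, "fit": fitted}
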