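import numpy as np
import pandas as pd
import pytest

from irlncpair import default_config, simulate_study
from irlncpair.datatypes import PairIndicatorMatrix
from irlncpair.pipeline import PipelineParams, StudyInputs, run_study


@pytest.fixture(scope="session")
def small_config():
    return default_config(
        n_tumor=120, n_normal=30, n_lnc=30, n_mrna=100, n_immune=50,
        n_coexpressed_lnc=12, n_de_lnc=10, seed=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_run(small_study, tmp_path_factory):
    """One full pipeline run on the small study, shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    params = PipelineParams(lasso_cycles=20, seed=3)
    runlog = run_study(StudyInputs.from_study(small_study), params, outdir)
    return runlog, outdir


def survival_cohort(rng, X, betas, baseline_hazard=0.1, censor=(1.0, 10.0)):
    """Exponential proportional-hazards cohort from a covariate matrix."""
    n = X.shape[0]
    lp = X @ np.asarray(betas, dtype=float)
    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    t_cens = rng.uniform(*censor, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def indicator_cohort(seed, n=400, p=50, planted_betas=(0.9, -0.85, 1.0),
                     baseline_hazard=0.1):
    """Binary pair-indicator matrix with a planted survival signal.

    Returns (PairIndicatorMatrix, clinical frame with time in days,
    planted pair ids).
    """
    rng = np.random.default_rng(seed)
    fractions = rng.uniform(0.25, 0.75, size=p)
    X = rng.binomial(1, fractions, size=(n, p)).astype(np.uint8)
    pairs = [f"G{i:03d}A|G{i:03d}B" for i in range(p)]
    planted_betas = tuple(planted_betas)[:p]
    betas = np.zeros(p)
    betas[: len(planted_betas)] = planted_betas
    time, event = survival_cohort(rng, X, betas, baseline_hazard=baseline_hazard)
    clinical = pd.DataFrame(
        {"time": np.round(time * 365.25), "event": event},
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample"),
    )
    pm = PairIndicatorMatrix(pd.DataFrame(X.T, index=pd.Index(pairs, name="pair"),
                                          columns=clinical.index))
    return pm, clinical, pairs[: len(planted_betas)]
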