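import numpy as np
import pytest

import shotadapt as sa


@pytest.fixture(scope="session")
def exp1_cohort():
    """Default-calibration exp1 cohort with the study's session counts."""
    return sa.simulate_experiment("exp1", seed=42)


@pytest.fixture(scope="session")
def exp1_fit(exp1_cohort):
    """One moderately sized posterior fit shared across inference tests."""
    data = sa.build_model_data(exp1_cohort)
    post = sa.sample_posterior(
        data, sa.ModelSpec(n_chains=3, n_samples=1500, burn_in=400, seed=42)
    )
    return data, post


def make_posterior(
    diff: float = 0.0,
    sigma2: float = 1.0,
    n_epochs: int = 2,
    n_subjects: int = 1,
    n_chains: int = 2,
    n_draws: int = 400,
    noise: float = 0.0,
    seed: int = 0,
) -> sa.PosteriorSamples:
    """Hand-built PosteriorSamples whose epoch-1 minus epoch-2 cell-mean
    difference is `diff` (plus optional draw noise) at residual variance
    `sigma2`; used to test summaries against known values."""
    rng = np.random.default_rng(seed)
    C, D, E, S = n_chains, n_draws, n_epochs, n_subjects
    a_epoch = np.zeros((C, D, E))
    a_epoch[:, :, 0] = diff + noise * rng.standard_normal((C, D))
    zeros = np.zeros((C, D))
    groups = ("baseline", "epoch", "subject", "interaction")
    return sa.PosteriorSamples(
        a_baseline=zeros.copy(),
        a_epoch=a_epoch,
        a_subject=np.zeros((C, D, S)),
        a_interaction=np.zeros((C, D, E, S)),
        sigma2=np.full((C, D), sigma2),
        hyper_means={g: zeros.copy() for g in groups},
        hyper_vars={g: np.ones((C, D)) for g in groups},
        n_epochs=E,
        n_subjects=S,
    )
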