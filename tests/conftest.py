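"""Shared fixtures: one small modulated session, its features, and one
nested-CV two-stage fit, all session-scoped because the fit is the expensive
step and many tests only inspect its outputs."""

import numpy as np
import pytest

from endomod import (
    PenaltyConfig,
    SessionConfig,
    build_feature_matrices,
    fit_two_stage,
    generate_session,
)

# Reduced lambda-path resolution keeps the suite fast: 8 points down to
# 0.02 lambda_max (the inner-CV optimum sits well inside that range; the
# densest, slowest path tail carries no selected solution).
FAST_PEN = PenaltyConfig(n_lambda=8, lambda_min_ratio=0.02)


def small_config(seed: int = 7, n_electrodes: int = 2) -> SessionConfig:
    return SessionConfig(n_electrodes=n_electrodes,
                         electrodes_per_category_network=min(2, n_electrodes),
                         rng_seed=seed)


@pytest.fixture(scope="session")
def session():
    return generate_session(small_config())


@pytest.fixture(scope="session")
def features0(session):
    return build_feature_matrices(session, 0)


@pytest.fixture(scope="session")
def labels0(session, features0):
    cat = session.trial_table.set_index("trial_index")["category"]
    return cat.loc[features0.kept_trials].to_numpy()


@pytest.fixture(scope="session")
def y0(labels0):
    return (labels0 == 1).astype(int)


@pytest.fixture(scope="session")
def two_stage_fit(features0, y0):
    return fit_two_stage(features0, y0, FAST_PEN, cv_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
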