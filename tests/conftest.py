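"""Shared fixtures: tiny fast mechanisms and packaged fixture paths."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pytest

from causalcf.dgm import ConfounderModel, DGMParams

FIXTURE_DIR = Path(__file__).parent / "fixtures"


def tiny_models() -> tuple[ConfounderModel, ...]:
    """One binary and three dependent Gaussians; fast to simulate."""
    return (
        ConfounderModel("b1", "bernoulli-logistic", intercept=-1.0),
        ConfounderModel("z1", "gaussian-linear", intercept=0.0, coefs=(0.4,)),
        ConfounderModel("z2", "gaussian-linear", intercept=0.0, coefs=(0.0, 0.3)),
        ConfounderModel("z3", "gaussian-linear", intercept=0.0, coefs=(0.2, 0.0, -0.3)),
    )


def tiny_complex_params(multiplier: float = 2.0, beta_x: float = 0.5) -> DGMParams:
    return DGMParams(
        name="tiny-complex", complexity="complex", p=4, n_continuous=3,
        confounder_models=tiny_models(),
        exposure_intercept=-0.8,
        exposure_main=(0.3, -0.2, 0.25, 0.15),
        exposure_ww_pairs=((1, 2), (0, 3)),
        exposure_ww_coefs=(0.15, -0.1),
        exposure_nl_idx=(1,), exposure_sq_coefs=(0.05,), exposure_log_coefs=(-0.1,),
        outcome_intercept=0.1, outcome_effect=beta_x,
        outcome_main=(0.25, 0.3, -0.2, 0.1),
        outcome_ww_pairs=((2, 3),), outcome_ww_coefs=(0.12,),
        outcome_xw_idx=(1, 2), outcome_xw_coefs=(0.2, -0.15),
        outcome_nl_idx=(3,), outcome_sq_coefs=(0.06,), outcome_log_coefs=(-0.08,),
        residual_sd=1.0, interaction_multiplier=multiplier,
    )


def tiny_simple_params(beta_x: float = 0.5) -> DGMParams:
    """The zero-interaction restriction of the tiny complex mechanism."""
    c = tiny_complex_params(multiplier=1.0, beta_x=beta_x)
    return dataclasses.replace(
        c, name="tiny-simple", complexity="simple",
        exposure_ww_coefs=(0.0, 0.0), exposure_sq_coefs=(0.0,),
        exposure_log_coefs=(0.0,),
        outcome_ww_coefs=(0.0,), outcome_xw_coefs=(0.0, 0.0),
        outcome_sq_coefs=(0.0,), outcome_log_coefs=(0.0,),
    )


@pytest.fixture
def tiny_simple() -> DGMParams:
    return tiny_simple_params()


@pytest.fixture
def tiny_complex() -> DGMParams:
    return tiny_complex_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    assert FIXTURE_DIR.exists(), "packaged fixtures missing; run `causalcf make-fixtures`"
    return FIXTURE_DIR
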