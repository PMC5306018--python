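import warnings

import numpy as np
import pytest

from occ2abund.config import PipelineConfig
from occ2abund.synthetic import (EffortModel, LandscapeConfig,
                                 gen_covariate_stack, gen_virtual_species)
from occ2abund import pipeline

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_landscape():
    """A small but non-trivial landscape shared by read-only tests."""
    config = LandscapeConfig(grid_size=16, n_covariates=4, n_species=3, seed=7)
    stack = gen_covariate_stack(config)
    truth = gen_virtual_species(stack, config)
    return config, stack, truth


def recovery_config() -> PipelineConfig:
    """Study conditions for the parameter-recovery simulation: an 80x80-km
    landscape, 5 virtual species driven strongly by 3 continuous covariates,
    thorough surveying with high detection, and abundance samples with
    moderate observation noise."""
    return PipelineConfig(
        landscape=LandscapeConfig(
            grid_size=80, n_covariates=3, n_species=5, seed=11,
            autocorrelation_range=6.0, n_drivers=3,
            beta_range=(2.0, 3.0), prevalence_range=(0.3, 0.5)),
        effort=EffortModel(min_surveys=2, extra_surveys_mean=1.0,
                           detection_prob=0.9, undersurveyed_fraction=0.1),
        seed=11, repeats=5,
        hyperparameters={"rf": {"n_estimators": 200},
                         "gbm": {"n_estimators": 80}},
        n_patch_source=3000, n_plot_source=3000, noise_sd=2.0,
        rf_params={"n_estimators": 300})


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full two-stage run on the recovery landscape (shared; expensive)."""
    config = recovery_config()
    workdir = tmp_path_factory.mktemp("recovery")
    pipeline.run_all(config, workdir)
    stack = gen_covariate_stack(config.landscape)
    truth = gen_virtual_species(stack, config.landscape)
    return config, workdir, truth
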