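"""Shared fixtures: synthetic inputs at the standard study-like conditions."""

from __future__ import annotations

import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from tapscore import CohortSpec, RunConfig, TapParams, gen_landmark_series
from tapscore.pipeline import cohort_feature_table, shuffled_label_control
from tapscore.severity_model import lopo_cv

#: seed of the standard synthetic cohort used for model-recovery checks
STANDARD_SEED = 1

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*force_row_wise.*")


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=STANDARD_SEED)


@pytest.fixture(scope="session")
def standard_cohort(run_config):
    """100-participant cohort at the default severity regimes (heavy)."""
    spec = CohortSpec(n_participants=100, seed=STANDARD_SEED)
    table, ratings, truth = cohort_feature_table(spec, run_config)
    return {"table": table, "ratings": ratings, "truth": truth, "spec": spec}


@pytest.fixture(scope="session")
def lopo_results(standard_cohort, run_config):
    """LOPO evaluation of the standard cohort plus its shuffled-label control."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = lopo_cv(standard_cohort["table"], seed=STANDARD_SEED)
        control = shuffled_label_control(standard_cohort["table"], run_config)
    return {"cv": cv, "control": control}


@pytest.fixture(scope="session")
def small_cohort(run_config):
    """12-participant cohort for cheap end-to-end tests."""
    spec = CohortSpec(n_participants=12, seed=3)
    table, ratings, truth = cohort_feature_table(spec, run_config)
    return {"table": table, "ratings": ratings, "truth": truth, "spec": spec}


@pytest.fixture()
def clean_video():
    """One zero-noise hand-video at 60 fps with planted events, plus truth."""
    params = TapParams(
        seed=11,
        n_taps=10,
        frame_rate=60.0,
        freeze_events=((2, 0.030), (5, 0.040)),
        interruption_events=((4, 0.015),),
    )
    series, truth = gen_landmark_series(params, video_id="clean", participant_id="pX")
    return params, series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
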