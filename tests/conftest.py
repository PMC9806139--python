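import numpy as np
import pytest

import ratgait as rg


@pytest.fixture(scope="session")
def baseline() -> rg.GaitModelParams:
    return rg.GaitModelParams()


@pytest.fixture(scope="session")
def noise_free_trial() -> rg.TrialRecording:
    """Sham trial with all noise SDs zero: 10 cycles, 60 fps, defaults."""
    tp = rg.make_preset("sham", "pre").noise_free()
    return rg.simulate_trial(tp, 10, seed=0)


@pytest.fixture(scope="session")
def noisy_trial() -> rg.TrialRecording:
    tp = rg.make_preset("L5L6", "d1")
    return rg.simulate_trial(tp, 8, seed=11, group_label="L5L6", day="d1")


@pytest.fixture(scope="session")
def sham_noisy_trial() -> rg.TrialRecording:
    """Symmetric (sham) gait with the default noise model."""
    return rg.simulate_trial(rg.make_preset("sham", "pre"), 8, seed=21)


@pytest.fixture(scope="session")
def small_cohort() -> list[rg.TrialRecording]:
    """Two-group, two-day miniature cohort for pipeline-level tests."""
    design = rg.CohortDesign(
        group_sizes={"sham": 3, "L5L6": 3}, days=("pre", "d1"), trials_per_session=2
    )
    return rg.simulate_cohort(design, seed=2)
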