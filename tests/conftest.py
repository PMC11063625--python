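import numpy as np
import pytest

from emomem.core import TrialRecord
from emomem.synth import (
    BehaviorRates,
    CohortConfig,
    TaskConfig,
    UnitProfile,
    assign_behavior,
    build_task_design,
    simulate_unit,
)


def make_trials(phase: str, outcomes: list[tuple[str, str]]) -> list[TrialRecord]:
    """Trials with prescribed (emotion, outcome) pairs, bypassing labeling."""
    trials = []
    for i, (emotion, outcome) in enumerate(outcomes):
        if phase == "encoding":
            old_new, response = "n/a", "indoor"
        else:
            old_new = "new" if outcome.endswith(("CR", "FA")) else "old"
            response = "N"
        trials.append(
            TrialRecord(
                trial_id=i, phase=phase, emotion=emotion, old_new=old_new,
                response=response, stimulus_id=f"s{i:03d}", outcome=outcome,
            )
        )
    return trials


@pytest.fixture(scope="session")
def labeled_design():
    """One labeled encoding+recognition session pair (default sizes)."""
    design = build_task_design(11, TaskConfig())
    return assign_behavior(design, BehaviorRates(), 11)


@pytest.fixture(scope="session")
def small_encoding_trials():
    """Small balanced encoding design: 40 trials, 2x2 cells of 10."""
    outcomes = (
        [("emotional", "eR")] * 10 + [("emotional", "eF")] * 10
        + [("neutral", "nR")] * 10 + [("neutral", "nF")] * 10
    )
    return make_trials("encoding", outcomes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def null_unit(trials, seed, baseline=5.0, unit_id="u0", **profile_kw):
    """Unit with no condition effects."""
    profile = UnitProfile(baseline_rate=baseline, **profile_kw)
    return simulate_unit(profile, trials, seed, unit_id=unit_id)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 patients x 12 units, encoding only; planted defaults."""
    from emomem.synth import simulate_cohort

    cfg = CohortConfig(n_patients=2, units_per_region=4, phases=("encoding",))
    return simulate_cohort(cfg, seed=202)
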