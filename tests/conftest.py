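"""Shared fixtures: a noise-free miniature dataset and one full-scale study run.

The full-scale run uses the default study design (19 participants, two
sessions, 4x4 target grid, 10 trials per condition) at a fixed seed and is
computed once per session; several tests assert different properties of the
same run.
"""

from hypothesis import HealthCheck, settings

import pytest

from fittslab import (
    component_slopes,
    condition_summaries,
    make_fixtures,
    participant_profiles,
    reduce_frame,
    simulate_study,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: Seed of the shared full-scale study run.
STUDY_SEED = 2026


@pytest.fixture(scope="session")
def tiny_run():
    """Noise-free 2-participant, 2x2-grid dataset plus its reduction."""
    traj, truth = make_fixtures("tiny", seed=7)
    measures = reduce_frame(traj)
    return {"trajectories": traj, "truth": truth, "measures": measures}


@pytest.fixture(scope="session")
def study_run():
    """Full default-design study at the fixed seed, reduced end to end."""
    traj, truth = simulate_study(seed=STUDY_SEED)
    measures = reduce_frame(traj)
    summaries = condition_summaries(measures)
    profiles = participant_profiles(measures)
    slopes = component_slopes(summaries, "nominal")
    return {
        "trajectories": traj,
        "truth": truth,
        "measures": measures,
        "summaries": summaries,
        "profiles": profiles,
        "slopes": slopes,
    }
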