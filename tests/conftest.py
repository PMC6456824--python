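import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sleepmood.panel import SubjectPanel
from sleepmood.synthetic import SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_panel(subject_id="S001", days=None, sleep=None, mood=None, stress=None,
               energy=None, focus=None, group="control", phq9=4, gad7=3):
    """Hand-built subject panel with sensible defaults for unused columns."""
    days = list(days if days is not None else range(1, (len(sleep or mood or [5] * 5)) + 1))
    n = len(days)

    def col(vals, default):
        if vals is None:
            return [default] * n
        return list(vals)

    mood = col(mood, 5.0)
    rec = pd.DataFrame({
        "day_index": days,
        "day_of_week": [((d - 1) % 7) + 1 for d in days],
        "day_type": ["normal"] * n,
        "sleep_quality": col(sleep, 4.0),
        "mood": mood,
        "stress": col(stress, 4.0),
        "energy": col(energy, 4.0),
        "focus": col(focus, 4.0),
        "activity_minutes": [30.0] * n,
        "mean_temp": [12.0] * n,
        "clear_sky_minutes": [200.0] * n,
    })
    for c in ("mood", "stress", "energy", "focus"):
        for j in (1, 2, 3):
            rec[f"{c}_{j}"] = rec[c]
    return SubjectPanel(subject_id, group, phq9, gad7, rec)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_subjects_per_group=3, n_days=24, seed=11, missing_prob=0.05)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def midsize_cohort():
    cfg = SimConfig(n_subjects_per_group=8, n_days=42, seed=7, missing_prob=0.1)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
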