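import numpy as np
import pytest

from circafly.dam_io import ActivitySeries


@pytest.fixture
def rhythmic_series() -> ActivitySeries:
    """One strongly consolidated 21-day fly (24 h period, kappa 4)."""
    from circafly.synthetic import BehaviorSimConfig, simulate_fly

    cfg = BehaviorSimConfig(n_flies=1, kappa=4.0, period_hours=24.0, seed=123)
    series, _ = simulate_fly(cfg, 0)
    return series


@pytest.fixture
def arrhythmic_series() -> ActivitySeries:
    """A 21-day fly with a uniform activity profile (kappa 0)."""
    from circafly.synthetic import BehaviorSimConfig, simulate_fly

    cfg = BehaviorSimConfig(n_flies=1, kappa=0.0, seed=321)
    series, _ = simulate_fly(cfg, 0)
    return series


def make_series(counts, fly_id="f1", genotype="g1", bin_minutes=20.0, start_age_days=3.0):
    return ActivitySeries(
        fly_id=fly_id,
        genotype=genotype,
        run_id="run1",
        counts=np.asarray(counts),
        start_age_days=start_age_days,
        bin_minutes=bin_minutes,
    )
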