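import numpy as np
import pandas as pd
import pytest

from gestwin import synth
from gestwin.config import BatchLayout, EffectSpec, PollutantSpec, SimulationConfig


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort config used across the suite."""
    kwargs = dict(n_participants=40, n_stations=6, n_clock_cpgs=30,
                  n_background_cpgs=120, n_panel_cpgs=150, n_x_probes=30,
                  n_twin_pairs=1, n_sex_discordant=1, n_low_intensity=1,
                  seed=7)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort() -> synth.SyntheticCohort:
    return synth.simulate_cohort(small_config())


@pytest.fixture(scope="session")
def clean_cohort() -> synth.SyntheticCohort:
    """No planted QC failures, no batch effects, no planted exposure effect."""
    cfg = small_config(
        n_twin_pairs=0, n_sex_discordant=0, n_low_intensity=0,
        batch_layout=BatchLayout(n_plates=2, plate_shift=0.0, plate_scale=1.0),
        effect=EffectSpec(gamma=0.0), detection_fail_rate=0.0, seed=11)
    return synth.simulate_cohort(cfg)


def station_grid(dists_km: list[float], base=(-75.0, 40.0)) -> pd.DataFrame:
    """Stations due north of ``base`` at the given great-circle distances."""
    deg_per_km = 1.0 / 111.19492664455873  # meridian arc on sphere R=6371.0088
    return pd.DataFrame({
        "station_id": [f"S{i:03d}" for i in range(len(dists_km))],
        "longitude": base[0],
        "latitude": [base[1] + d * deg_per_km for d in dists_km],
    })
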