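"""Simulation configuration for synthetic pregnancy-cohort generation.

The configuration fixes every knob of the generator: the monitoring-station
network and pollutant fields, the pregnancy calendar, the methylation array
layout (clock, background, deconvolution-panel and sex-probe CpGs), batch
structure, and the planted exposure effect on biological gestational age.
A config plus a seed fully determines all outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: Number of complete 7-day preconception weeks on the unified week axis.
#: Unified week w is preconception for w in 1..13; week 14 is pregnancy week 1.
PRECONCEPTION_WEEKS = 13

#: Length of the distributed-lag axis: preconception weeks 1-13 plus
#: pregnancy weeks 1-35 (pregnancy weeks 36-39 are excluded structurally,
#: so that preterm and term pregnancies share a complete axis).
N_LAG_WEEKS = 48


@dataclass
class PollutantSpec:
    """Generative field for one pollutant.

    Weekly value at location (lon, lat) and calendar week w:

        baseline + gradient * ((lon - lon0) + (lat - lat0))
        + amplitude * sin(2*pi*w/52 + phase) + AR(1) noise,

    floored at zero. ``noise_sd`` is the marginal SD of the total stochastic
    anomaly, split between a region-wide component (shared by all locations,
    part of the latent "true" exposure) and a station-local component
    (measurement/siting error, absent from the truth).
    """

    name: str
    baseline: float
    amplitude: float = 0.0
    noise_sd: float = 0.0
    gradient: float = 0.0
    phase: float = 0.0
    unit: str = ""


@dataclass
class BatchLayout:
    """Plate structure of the synthetic array run.

    ``plate_shift`` is the SD (logit scale) of per-(plate, probe) location
    shifts; ``plate_scale`` is the multiplicative spread of per-plate noise
    scale factors (log-normal around 1).
    """

    n_plates: int = 2
    plate_shift: float = 0.15
    plate_scale: float = 1.2


@dataclass
class EffectSpec:
    """Planted exposure effect on biological gestational age.

    ``gamma`` is the biological-GA shift in weeks per 10-unit increase of the
    mean exposure over unified weeks ``window_start_week..window_end_week``
    (inclusive, weeks within 1..48). The default window, unified weeks 34-44,
    is pregnancy weeks 21-31.
    """

    pollutant: str = "O3"
    window_start_week: int = 34
    window_end_week: int = 44
    gamma: float = -1.0


def _default_pollutants() -> list[PollutantSpec]:
    # Baselines match the magnitude class of urban US monitoring data
    # (NO2/O3 in ppb, PM2.5/PM10 in ug/m3).
    return [
        PollutantSpec("NO2", baseline=13.0, amplitude=4.0, noise_sd=2.0,
                      gradient=2.0, phase=3.1, unit="ppb"),
        PollutantSpec("O3", baseline=26.0, amplitude=8.0, noise_sd=3.0,
                      gradient=-2.0, phase=0.0, unit="ppb"),
        PollutantSpec("PM25", baseline=10.0, amplitude=2.5, noise_sd=1.5,
                      gradient=1.0, phase=0.5, unit="ug/m3"),
        PollutantSpec("PM10", baseline=17.5, amplitude=4.0, noise_sd=2.5,
                      gradient=1.5, phase=0.5, unit="ug/m3"),
    ]


@dataclass
class SimulationConfig:
    n_participants: int = 150
    n_stations: int = 8
    #: (lon_min, lon_max, lat_min, lat_max), decimal degrees.
    region: tuple[float, float, float, float] = (-75.6, -74.6, 39.5, 40.5)
    pollutants: list[PollutantSpec] = field(default_factory=_default_pollutants)

    n_clock_cpgs: int = 120
    n_background_cpgs: int = 1000
    n_panel_cpgs: int = 600
    n_x_probes: int = 80

    #: Beta-scale noise SD for methylation values. Noise is applied on the
    #: logit scale with SD 4*beta_noise_sd (delta method at beta = 0.5).
    beta_noise_sd: float = 0.02
    #: SD (weeks) of individual biological-GA noise around the planted model.
    bio_ga_noise_sd: float = 1.0
    #: "logit": clock CpG betas are logistic in biological GA (realistic,
    #: bounded); "linear": betas are exactly linear in biological GA, in which
    #: case an exact linear clock exists and is recorded in the truth record.
    clock_link: str = "logit"

    batch_layout: BatchLayout = field(default_factory=BatchLayout)
    effect: EffectSpec = field(default_factory=EffectSpec)

    detection_fail_rate: float = 0.005
    n_low_intensity: int = 2
    n_sex_discordant: int = 2
    n_twin_pairs: int = 2

    ga_mean: float = 39.2
    ga_sd: float = 1.4
    #: If None, gestational age at birth is a plain truncated normal on
    #: [28, 42] weeks; otherwise the probability mass below 37 weeks is forced
    #: to this value by a two-component truncation.
    preterm_fraction: Optional[float] = None

    #: First Monday of the station series and number of weekly observations;
    #: conception dates are drawn uniformly over calendar year 2009, so the
    #: default series covers 13 preconception weeks before the earliest
    #: conception through 42 pregnancy weeks after the latest.
    week0: dt.date = dt.date(2008, 9, 29)
    n_weeks: int = 120
    conception_year: int = 2009

    #: AR(1) coefficient of weekly pollutant anomalies.
    ar_coef: float = 0.5

    seed: int = 0
    #: Seed of the shared "biology": clock CpG coefficients, background and
    #: X-probe profiles, and the cell-type reference panel. Kept separate
    #: from the cohort seed so a clock trained on one synthetic cohort
    #: transfers to another (same CpG-GA relationships), as an externally
    #: trained clock does across real cohorts.
    biology_seed: int = 1000

    def __post_init__(self) -> None:
        lon0, lon1, lat0, lat1 = self.region
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError(f"empty region box: {self.region}")
        eff = self.effect
        if not (1 <= eff.window_start_week <= eff.window_end_week <= N_LAG_WEEKS):
            raise ValueError(
                f"effect window [{eff.window_start_week}, {eff.window_end_week}] "
                f"must lie within [1, {N_LAG_WEEKS}]")
        for name, val in [("detection_fail_rate", self.detection_fail_rate),
                          ("beta_noise_sd", self.beta_noise_sd)]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.preterm_fraction is not None and not 0.0 <= self.preterm_fraction <= 1.0:
            raise ValueError("preterm_fraction must be in [0, 1]")
        if self.clock_link not in ("logit", "linear"):
            raise ValueError(f"clock_link must be 'logit' or 'linear', got {self.clock_link!r}")
        if self.n_weeks < 60:
            raise ValueError("n_weeks must be >= 60 to cover a pregnancy calendar")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")

    def pollutant(self, name: str) -> PollutantSpec:
        for p in self.pollutants:
            if p.name == name:
                return p
        raise KeyError(f"pollutant {name!r} not in config "
                       f"({[p.name for p in self.pollutants]})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["week0"] = self.week0.isoformat()
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pollutants" in raw:
            raw["pollutants"] = [PollutantSpec(**p) for p in raw["pollutants"]]
        if "batch_layout" in raw:
            raw["batch_layout"] = BatchLayout(**raw["batch_layout"])
        if "effect" in raw:
            raw["effect"] = EffectSpec(**raw["effect"])
        if "region" in raw:
            raw["region"] = tuple(raw["region"])
        if "week0" in raw and isinstance(raw["week0"], str):
            raw["week0"] = dt.date.fromisoformat(raw["week0"])
        return cls(**raw)
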