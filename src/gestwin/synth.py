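"""Synthetic cohort generator: stations, exposures, pregnancies, methylation.

Every downstream stage of the pipeline (exposure assignment, methylation QC,
cell deconvolution, clock fitting, period-average and distributed-lag models)
is testable against the ground truth this module records while generating:
the latent weekly exposure at each residence, each newborn's biological and
chronologic gestational age, the true cell proportions, the generating clock
coefficients, and the planted exposure effect (a biological-GA shift confined
to a configurable window of the unified 48-week preconception+pregnancy axis).

Reproducibility contract: one RNG stream per component (stations,
participants, methylation), derived from the master seed by fixed offsets,
so e.g. changing ``n_participants`` never perturbs the station series.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import (N_LAG_WEEKS, PRECONCEPTION_WEEKS, PollutantSpec,
                     SimulationConfig)

_STREAM_STATIONS = 1
_STREAM_PARTICIPANTS = 2
_STREAM_METHYLATION = 3
_STREAM_BIOLOGY = 5

CELL_TYPES = ["syncytiotrophoblast", "trophoblasts", "hofbauer",
              "endothelial", "stromal", "nrbc"]

#: Mean placental cell composition used for Dirichlet mixing (fractions).
_CELL_MEANS = np.array([0.645, 0.133, 0.028, 0.074, 0.110, 0.043])
_CELL_MEANS = _CELL_MEANS / _CELL_MEANS.sum()
_CELL_CONCENTRATION = 65.0

#: Categorical covariate dictionaries (first level = reference downstream)
#: with sampling probabilities recorded in the truth record.
COVARIATE_LEVELS: dict[str, tuple[list[str], list[float]]] = {
    "race": (["White", "Asian", "Black", "Other"], [0.64, 0.15, 0.11, 0.10]),
    "ethnicity": (["NonHispanic", "Hispanic"], [0.82, 0.18]),
    "education": (["HighSchoolOrSomeCollege", "Bachelors", "MastersOrHigher"],
                  [0.41, 0.27, 0.32]),
    "income": (["lt30k", "30to50k", "50to75k", "75to100k", "ge100k"],
               [0.11, 0.18, 0.18, 0.20, 0.33]),
    "bmi_cat": (["UnderweightOrNormal", "Overweight", "Obese"],
                [0.40, 0.32, 0.28]),
    "child_sex": (["M", "F"], [0.56, 0.44]),
    "study_site": (["SiteA", "SiteB", "SiteC", "SiteD"],
                   [0.27, 0.25, 0.29, 0.19]),
}


# ---------------------------------------------------------------------------
# Pollutant field

@dataclass
class FieldModel:
    """Generative pollutant field: deterministic surface plus a shared
    region-wide AR(1) weekly anomaly per pollutant.

    The latent "true" exposure at a residence is the field evaluated at the
    residence coordinates (deterministic part + regional anomaly); station
    observations add a station-local AR(1) noise term on top, so
    interpolation error against the truth is realistically nonzero.
    """

    config: SimulationConfig
    regional_anomaly: dict[str, np.ndarray]  # pollutant -> (n_weeks,)
    week_starts: list[dt.date]

    def deterministic(self, pol: PollutantSpec, lon: float, lat: float,
                      week_idx: np.ndarray) -> np.ndarray:
        lon0, _, lat0, _ = self.config.region
        spatial = pol.gradient * ((lon - lon0) + (lat - lat0))
        seasonal = pol.amplitude * np.sin(
            2.0 * np.pi * np.asarray(week_idx, dtype=float) / 52.0 + pol.phase)
        return pol.baseline + spatial + seasonal

    def true_value(self, pollutant: str, lon: float, lat: float,
                   week_idx: np.ndarray) -> np.ndarray:
        """Latent exposure at (lon, lat) for calendar week indices."""
        pol = self.config.pollutant(pollutant)
        det = self.deterministic(pol, lon, lat, week_idx)
        anom = self.regional_anomaly[pollutant][np.asarray(week_idx)]
        return np.maximum(det + anom, 0.0)


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


@dataclass
class StationData:
    stations: pd.DataFrame          # station_id, longitude, latitude
    weekly: pd.DataFrame            # station_id, pollutant, week_start_date, value
    field: FieldModel


def simulate_stations(config: SimulationConfig) -> StationData:
    """Place monitoring stations in the region and generate weekly series.

    Station weekly value = deterministic field + regional AR(1) anomaly
    (shared with the latent truth) + station-local AR(1) noise, floored at 0.
    The total anomaly SD equals the pollutant's ``noise_sd`` (split 0.6/0.8
    in quadrature between regional and local components).
    """
    rng = np.random.default_rng([config.seed, _STREAM_STATIONS])
    lon0, lon1, lat0, lat1 = config.region
    n = config.n_stations
    stations = pd.DataFrame({
        "station_id": [f"S{i:03d}" for i in range(n)],
        "longitude": rng.uniform(lon0, lon1, n),
        "latitude": rng.uniform(lat0, lat1, n),
    })
    week_idx = np.arange(config.n_weeks)
    week_starts = [config.week0 + dt.timedelta(weeks=int(w)) for w in week_idx]

    regional = {}
    rows = []
    for pol in config.pollutants:
        regional[pol.name] = _ar1(rng, config.n_weeks, 0.6 * pol.noise_sd,
                                  config.ar_coef)
        for _, st in stations.iterrows():
            det = (pol.baseline
                   + pol.gradient * ((st.longitude - lon0) + (st.latitude - lat0))
                   + pol.amplitude * np.sin(2 * np.pi * week_idx / 52.0 + pol.phase))
            local = _ar1(rng, config.n_weeks, 0.8 * pol.noise_sd, config.ar_coef)
            values = np.maximum(det + regional[pol.name] + local, 0.0)
            rows.append(pd.DataFrame({
                "station_id": st.station_id,
                "pollutant": pol.name,
                "week_start_date": week_starts,
                "value": values,
            }))
    weekly = pd.concat(rows, ignore_index=True)
    fieldm = FieldModel(config, regional, week_starts)
    return StationData(stations, weekly, fieldm)


# ---------------------------------------------------------------------------
# Participants

def _draw_ga(rng: np.random.Generator, config: SimulationConfig,
             n: int) -> np.ndarray:
    lo, hi = 28.0, 42.0
    a = (lo - config.ga_mean) / config.ga_sd
    b = (hi - config.ga_mean) / config.ga_sd
    if config.preterm_fraction is None:
        return truncnorm.rvs(a, b, loc=config.ga_mean, scale=config.ga_sd,
                             size=n, random_state=rng)
    # Two-component truncation forcing P(GA < 37) = preterm_fraction.
    p = config.preterm_fraction
    c = (37.0 - config.ga_mean) / config.ga_sd
    is_pre = rng.random(n) < p
    ga = np.empty(n)
    n_pre = int(is_pre.sum())
    if n_pre:
        ga[is_pre] = truncnorm.rvs(a, c, loc=config.ga_mean, scale=config.ga_sd,
                                   size=n_pre, random_state=rng)
    if n - n_pre:
        ga[~is_pre] = truncnorm.rvs(c, b, loc=config.ga_mean, scale=config.ga_sd,
                                    size=n - n_pre, random_state=rng)
    return ga


def simulate_participants(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the pregnancy cohort: residences, calendars, covariates.

    Gestational age at birth is truncated normal on [28, 42] weeks;
    conception dates are uniform over one calendar year so birth seasons are
    balanced. Categorical covariates are drawn from the fixed probability
    dictionaries in ``COVARIATE_LEVELS``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PARTICIPANTS])
    lon0, lon1, lat0, lat1 = config.region
    n = config.n_participants

    year_start = dt.date(config.conception_year, 1, 1)
    offsets = rng.integers(0, 365, size=n)
    conception = [year_start + dt.timedelta(days=int(o)) for o in offsets]
    ga = _draw_ga(rng, config, n)

    df = pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "longitude": rng.uniform(lon0, lon1, n),
        "latitude": rng.uniform(lat0, lat1, n),
        "conception_date": conception,
        "ga_weeks": ga,
        "maternal_age": np.clip(rng.normal(34.1, 4.3, n), 18.0, 48.0),
    })
    for col, (levels, probs) in COVARIATE_LEVELS.items():
        df[col] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))
    birth = [c + dt.timedelta(days=int(round(g * 7)))
             for c, g in zip(conception, ga)]
    df["birth_season"] = ["warm" if 4 <= b.month <= 9 else "cold" for b in birth]
    return df


# ---------------------------------------------------------------------------
# Truth exposures

def true_weekly_exposures(config: SimulationConfig, participants: pd.DataFrame,
                          fieldm: FieldModel,
                          pollutant: str) -> pd.DataFrame:
    """Latent weekly exposure per participant on the unified week axis.

    Unified week w (1-based) of a participant covers the 7 days starting
    ``conception - 91 days + 7*(w-1)``; its value is the field evaluated at
    the residence for the calendar week containing the window midpoint.
    Returns a participants x 48 DataFrame (unified weeks 1..48).
    """
    weeks = np.arange(1, N_LAG_WEEKS + 1)
    out = np.empty((len(participants), N_LAG_WEEKS))
    week0 = config.week0
    for i, row in enumerate(participants.itertuples()):
        conc = row.conception_date
        if isinstance(conc, str):
            conc = dt.date.fromisoformat(conc)
        mid = [conc + dt.timedelta(days=-91 + 7 * (int(w) - 1) + 3) for w in weeks]
        cal_idx = np.array([(m - week0).days // 7 for m in mid])
        if cal_idx.min() < 0 or cal_idx.max() >= config.n_weeks:
            raise ValueError("station series does not cover the pregnancy "
                             f"calendar of {row.participant_id}")
        out[i] = fieldm.true_value(pollutant, row.longitude, row.latitude, cal_idx)
    return pd.DataFrame(out, index=participants["participant_id"].to_numpy(),
                        columns=weeks)


# ---------------------------------------------------------------------------
# Methylation

@dataclass
class MethylationData:
    beta: pd.DataFrame              # CpG x sample
    detection_p: pd.DataFrame       # CpG x sample
    intensity: pd.DataFrame         # sample_id, median_log2_intensity
    samplesheet: pd.DataFrame       # sample_id, reported_sex, plate, position, twin_pair
    reference_panel: pd.DataFrame   # panel CpG x cell type


@dataclass
class TruthRecord:
    """Ground truth recorded during generation, for downstream testing."""

    weekly_exposures: dict[str, pd.DataFrame]   # pollutant -> participants x 48
    cga: pd.Series                              # chronologic GA, weeks
    bio_ga: pd.Series                           # biological GA, weeks
    cell_proportions: pd.DataFrame              # sample x cell type
    clock_intercepts: np.ndarray                # a_j, link scale
    clock_slopes: np.ndarray                    # b_j per week, link scale
    clock_cpgs: list[str]
    gamma: float
    window: tuple[int, int]
    linear_clock: "dict | None"                 # exact clock if link == linear
    covariate_probs: dict = field(default_factory=lambda: {
        k: dict(zip(v[0], v[1])) for k, v in COVARIATE_LEVELS.items()})

    def windowed_mean(self, pollutant: str) -> pd.Series:
        w0, w1 = self.window
        ex = self.weekly_exposures[pollutant]
        return ex.loc[:, w0:w1].mean(axis=1)


def simulate_methylation(config: SimulationConfig, participants: pd.DataFrame,
                         truth_exposures: dict[str, pd.DataFrame]
                         ) -> tuple[MethylationData, TruthRecord]:
    """Generate the methylation array data driven by biological GA.

    Biological GA = chronologic GA + gamma * (mean windowed exposure / 10)
    + individual noise. Clock CpGs drift with biological GA on the link
    scale; background CpGs carry no GA signal; a designated panel-CpG block
    is a cell-proportion-weighted mixture of cell-specific reference
    profiles; X-probe beta values separate the sexes for sex prediction.
    Plate shifts/scales act on the logit scale; detection-p failures are
    i.i.d. at ``detection_fail_rate``; the intensity sheet plants
    ``n_low_intensity`` low-intensity samples.
    """
    if config.effect.pollutant not in truth_exposures:
        raise ValueError(f"effect pollutant {config.effect.pollutant!r} has no "
                         "simulated exposure series")
    rng = np.random.default_rng([config.seed, _STREAM_METHYLATION])
    # probe-level "biology" is shared across cohorts (see biology_seed)
    rng_bio = np.random.default_rng([config.biology_seed, _STREAM_BIOLOGY])
    n = len(participants)
    ids = participants["participant_id"].to_numpy()
    cga = participants["ga_weeks"].to_numpy(float)

    eff = config.effect
    wexp = truth_exposures[eff.pollutant].loc[ids, eff.window_start_week:eff.window_end_week]
    windowed = wexp.mean(axis=1).to_numpy()
    bio_ga = (cga + eff.gamma * windowed / 10.0
              + rng.normal(0.0, config.bio_ga_noise_sd, n))

    logit_sd = 4.0 * config.beta_noise_sd

    # plate assignment
    plates = rng.permuted(np.arange(n) % config.batch_layout.n_plates)
    plate_scale = np.exp(rng.normal(
        0.0, math.log(max(config.batch_layout.plate_scale, 1.0 + 1e-12)),
        config.batch_layout.n_plates))

    blocks = []
    cpg_names: list[str] = []

    # clock CpGs
    nc = config.n_clock_cpgs
    if config.clock_link == "linear":
        b = rng_bio.uniform(0.005, 0.02, nc) * rng_bio.choice([-1.0, 1.0], nc)
        a = 0.5 - b * 39.0 + rng_bio.normal(0.0, 0.05, nc)
        clock_clean = np.clip(a[:, None] + b[:, None] * bio_ga[None, :], 0.0, 1.0)
        denom = float(np.sum(b * b))
        linear_clock = {
            "weights": (b / denom).tolist(),
            "intercept": float(-np.sum(a * b) / denom),
        }
        clock_logit = logit(np.clip(clock_clean, 1e-6, 1 - 1e-6))
    else:
        b = rng_bio.uniform(0.08, 0.25, nc) * rng_bio.choice([-1.0, 1.0], nc)
        a = rng_bio.uniform(-1.0, 1.0, nc) - b * 39.2
        clock_logit = a[:, None] + b[:, None] * bio_ga[None, :]
        linear_clock = None
    blocks.append(clock_logit)
    clock_cpgs = [f"cg_clock_{j:05d}" for j in range(nc)]
    cpg_names += clock_cpgs

    # background CpGs
    nb = config.n_background_cpgs
    bg_a = rng_bio.uniform(-2.5, 2.5, nb)
    blocks.append(np.tile(bg_a[:, None], (1, n)))
    cpg_names += [f"cg_bg_{j:05d}" for j in range(nb)]

    # X probes: intermediate methylation in females (X inactivation),
    # low in males.
    nx = config.n_x_probes
    sex_f = (participants["child_sex"].to_numpy() == "F").astype(float)
    x_a = rng_bio.normal(-1.8, 0.3, nx)
    x_shift = rng_bio.normal(1.8, 0.2, nx)
    blocks.append(x_a[:, None] + x_shift[:, None] * sex_f[None, :])
    cpg_names += [f"cg_x_{j:05d}" for j in range(nx)]

    # deconvolution panel CpGs: mixtures of cell-specific profiles
    npnl = config.n_panel_cpgs
    panel = rng_bio.uniform(0.05, 0.95, (npnl, len(CELL_TYPES)))
    props = rng.dirichlet(_CELL_CONCENTRATION * _CELL_MEANS, size=n)
    mixed = panel @ props.T
    blocks.append(logit(np.clip(mixed, 1e-6, 1 - 1e-6)))
    panel_cpgs = [f"cg_panel_{j:05d}" for j in range(npnl)]
    cpg_names += panel_cpgs

    m = np.vstack(blocks)
    n_cpg = m.shape[0]

    # batch: per-(plate, probe) location shift and per-plate noise scale
    shifts = rng.normal(0.0, config.batch_layout.plate_shift,
                        (n_cpg, config.batch_layout.n_plates))
    m = m + shifts[:, plates]
    if logit_sd > 0:
        m = m + rng.normal(0.0, logit_sd, (n_cpg, n)) * plate_scale[plates][None, :]
    beta = expit(m)

    beta_df = pd.DataFrame(beta, index=cpg_names, columns=ids)

    # detection p-values
    detp = rng.uniform(0.0, 0.005, (n_cpg, n))
    fails = rng.random((n_cpg, n)) < config.detection_fail_rate
    detp[fails] = rng.uniform(0.011, 1.0, int(fails.sum()))
    detp_df = pd.DataFrame(detp, index=cpg_names, columns=ids)

    # intensity sheet
    intensity = np.clip(rng.normal(12.5, 0.4, n), 11.2, None)
    low_idx = rng.choice(n, size=min(config.n_low_intensity, n), replace=False)
    intensity[low_idx] = rng.uniform(10.2, 10.9, len(low_idx))
    intensity_df = pd.DataFrame({"sample_id": ids,
                                 "median_log2_intensity": intensity})

    # samplesheet: reported sex (with planted discordance), plate, twins
    reported = participants["child_sex"].to_numpy().copy()
    eligible = np.setdiff1d(np.arange(n), low_idx)
    n_disc = min(config.n_sex_discordant, len(eligible))
    disc_idx = rng.choice(eligible, size=n_disc, replace=False)
    flip = {"M": "F", "F": "M"}
    for i in disc_idx:
        reported[i] = flip[reported[i]]
    twin_pair = np.array([""] * n, dtype=object)
    remaining = np.setdiff1d(eligible, disc_idx)
    n_pairs = min(config.n_twin_pairs, len(remaining) // 2)
    if n_pairs:
        chosen = rng.choice(remaining, size=2 * n_pairs, replace=False)
        for k in range(n_pairs):
            twin_pair[chosen[2 * k]] = f"T{k:02d}"
            twin_pair[chosen[2 * k + 1]] = f"T{k:02d}"
    samplesheet = pd.DataFrame({
        "sample_id": ids,
        "reported_sex": reported,
        "plate": [f"plate{p}" for p in plates],
        "position": [f"R{1 + i % 12:02d}" for i in range(n)],
        "twin_pair": twin_pair,
    })

    panel_df = pd.DataFrame(panel, index=panel_cpgs, columns=CELL_TYPES)
    meth = MethylationData(beta_df, detp_df, intensity_df, samplesheet, panel_df)
    truth = TruthRecord(
        weekly_exposures=truth_exposures,
        cga=pd.Series(cga, index=ids),
        bio_ga=pd.Series(bio_ga, index=ids),
        cell_proportions=pd.DataFrame(props, index=ids, columns=CELL_TYPES),
        clock_intercepts=a, clock_slopes=b, clock_cpgs=clock_cpgs,
        gamma=eff.gamma,
        window=(eff.window_start_week, eff.window_end_week),
        linear_clock=linear_clock,
    )
    return meth, truth


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    stations: StationData
    participants: pd.DataFrame
    methylation: MethylationData
    truth: TruthRecord


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run the full generator: stations, participants, truth, methylation."""
    stations = simulate_stations(config)
    participants = simulate_participants(config)
    truth_exp = {p.name: true_weekly_exposures(config, participants,
                                               stations.field, p.name)
                 for p in config.pollutants}
    meth, truth = simulate_methylation(config, participants, truth_exp)
    return SyntheticCohort(config, stations, participants, meth, truth)


# ---------------------------------------------------------------------------
# Regression-level calibration cohorts
#
# These lightweight generators produce (exposure, covariates, outcome) tables
# directly at the scale the association and distributed-lag models consume.
# They plant the same effect structure as the full generator (gamma weeks of
# GA-residual shift per 10-unit exposure increment) without the methylation
# layer, so large Monte-Carlo calibration studies (type-I error, coverage,
# window recovery) stay cheap.

_COVAR_EFFECTS = {
    "maternal_age": 0.02,
    "child_sex": {"M": 0.0, "F": -0.3},
    "birth_season": {"warm": 0.0, "cold": 0.1},
}


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    df = pd.DataFrame({"maternal_age": np.clip(rng.normal(34.1, 4.3, n), 18, 48)})
    for col, (levels, probs) in COVARIATE_LEVELS.items():
        df[col] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))
    df["birth_season"] = rng.choice(["warm", "cold"], size=n, p=[0.47, 0.53])
    return df


def _covariate_signal(cov: pd.DataFrame) -> np.ndarray:
    sig = _COVAR_EFFECTS["maternal_age"] * (cov["maternal_age"].to_numpy() - 34.1)
    sig = sig + cov["child_sex"].map(_COVAR_EFFECTS["child_sex"]).to_numpy()
    sig = sig + cov["birth_season"].map(_COVAR_EFFECTS["birth_season"]).to_numpy()
    return sig


def simulate_outcome_cohort(n: int, gamma: float, seed: int, *,
                            exposure_mean: float = 25.0,
                            exposure_sd: float = 4.0,
                            noise_sd: float = 1.0) -> pd.DataFrame:
    """One period-average analysis cohort with a planted per-10-unit effect.

    Outcome (a GA-acceleration residual, weeks) =
    gamma * exposure / 10 + covariate signal + N(0, noise_sd).
    """
    rng = np.random.default_rng([seed, 11])
    cov = _draw_covariates(rng, n)
    exposure = rng.normal(exposure_mean, exposure_sd, n)
    outcome = (gamma * exposure / 10.0 + _covariate_signal(cov)
               + rng.normal(0.0, noise_sd, n))
    cov.insert(0, "participant_id", [f"P{i:04d}" for i in range(n)])
    cov["exposure"] = exposure
    cov["outcome"] = outcome
    return cov


def simulate_two_period_cohort(n: int, gamma_pregnancy: float, seed: int, *,
                               corr: float = -0.8,
                               exposure_mean: float = 25.0,
                               exposure_sd: float = 4.0,
                               noise_sd: float = 1.0) -> pd.DataFrame:
    """Preconception + pregnancy averages with controllable correlation.

    The planted effect acts only through the pregnancy average; a strong
    negative correlation between the two period averages creates
    omitted-variable bias in the single-period model, the phenomenon the
    mutually adjusted model is designed to resolve.
    """
    rng = np.random.default_rng([seed, 12])
    cov = _draw_covariates(rng, n)
    z = rng.normal(0.0, 1.0, (n, 2))
    pre = exposure_mean + exposure_sd * z[:, 0]
    preg = exposure_mean + exposure_sd * (corr * z[:, 0]
                                          + math.sqrt(1 - corr ** 2) * z[:, 1])
    outcome = (gamma_pregnancy * preg / 10.0 + _covariate_signal(cov)
               + rng.normal(0.0, noise_sd, n))
    cov.insert(0, "participant_id", [f"P{i:04d}" for i in range(n)])
    cov["exposure_preconception"] = pre
    cov["exposure_pregnancy"] = preg
    cov["outcome"] = outcome
    return cov


def window_lag_profile(gamma: float, window: tuple[int, int],
                       profile: str = "peaked") -> np.ndarray:
    """Per-unit weekly lag coefficients for a window-confined effect.

    ``profile='flat'``: constant inside the window; ``'peaked'``: triangular,
    maximal at the window's central week and tapering to the edges. Either
    way the coefficients sum to gamma/10 per unit, i.e. a sustained 10-unit
    increase across the window shifts the outcome by gamma weeks.
    """
    w0, w1 = window
    width = w1 - w0 + 1
    beta_l = np.zeros(N_LAG_WEEKS)
    if profile == "flat":
        shape = np.ones(width)
    elif profile == "peaked":
        center = (w0 + w1) / 2.0
        shape = 1.0 - np.abs(np.arange(w0, w1 + 1) - center) / (width / 2.0 + 0.5)
    else:
        raise ValueError(f"unknown lag profile {profile!r}")
    beta_l[w0 - 1:w1] = shape / shape.sum() * gamma / 10.0
    return beta_l


def simulate_weekly_cohort(n: int, gamma: float, window: tuple[int, int],
                           seed: int, *,
                           baseline: float = 26.0, amplitude: float = 8.0,
                           noise_sd: float = 3.0, ar_coef: float = 0.5,
                           noise_sd_outcome: float = 1.0,
                           profile: str = "peaked"
                           ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Weekly 48-lag exposure histories with a window-confined effect.

    Each participant's conception week is uniform over the year, so the
    seasonal cycle places different calendar weeks in the lag window across
    participants — the variation the distributed-lag model exploits. Returns
    (X weekly exposures n x 48, covariates, outcome); the planted weekly
    effect follows :func:`window_lag_profile` (default: triangular, peaked
    at the window center), scaled so a sustained 10-unit increase across
    the window shifts the outcome by gamma weeks.
    """
    rng = np.random.default_rng([seed, 13])
    cov = _draw_covariates(rng, n)
    start = rng.integers(0, 52, n)
    lags = np.arange(N_LAG_WEEKS)
    cal = (start[:, None] + lags[None, :])
    x = baseline + amplitude * np.sin(2 * np.pi * cal / 52.0)
    for i in range(n):
        x[i] += _ar1(rng, N_LAG_WEEKS, noise_sd, ar_coef)
    x = np.maximum(x, 0.0)
    beta_l = window_lag_profile(gamma, window, profile)
    outcome = (x @ beta_l + _covariate_signal(cov)
               + rng.normal(0.0, noise_sd_outcome, n))
    return x, cov, outcome
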