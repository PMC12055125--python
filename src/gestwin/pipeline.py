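"""End-to-end orchestration: simulate -> expose -> qc -> deconv -> clock ->
period-average models -> distributed-lag models.

The clock is trained on a separate synthetic training cohort generated with
no planted exposure effect (emulating an externally trained clock) and then
applied to the analysis cohort, so the analysis-cohort residuals are not
contaminated by in-sample clock fitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from . import assoc, clock, deconv, dlm, exposure, methqc, synth
from .config import SimulationConfig


@dataclass
class PipelineResult:
    cohort: synth.SyntheticCohort
    exposures: pd.DataFrame          # long weekly IDW exposures (effect pollutant)
    period_averages: pd.DataFrame
    qc_report: methqc.QCReport
    proportions: pd.DataFrame
    ga_results: pd.DataFrame
    estimates: pd.DataFrame
    dlm_fit: dlm.DLMFit
    windows: dlm.WindowSummary


def train_reference_clock(config: SimulationConfig, seed: int,
                          n_training: int = 200) -> clock.ClockModel:
    """Train a clock on an independent null-effect synthetic cohort."""
    cfg = dataclasses.replace(
        config, n_participants=n_training, seed=seed,
        effect=dataclasses.replace(config.effect, gamma=0.0))
    cohort = synth.simulate_cohort(cfg)
    cga = cohort.participants.set_index("participant_id")["ga_weeks"]
    train_beta = cohort.methylation.beta.loc[cohort.truth.clock_cpgs]
    return clock.train_clock(train_beta, cga, seed=seed)


def run_pipeline(config: SimulationConfig,
                 clock_model: "clock.ClockModel | None" = None,
                 basis_candidates=(("polynomial", 1), ("polynomial", 2),
                                   ("polynomial", 3), ("polynomial", 4)),
                 assoc_periods=("preconception", "pregnancy"),
                 assoc_models=("individual",)) -> PipelineResult:
    """Run every stage on one synthetic cohort for the planted-effect
    pollutant; returns all intermediate products plus the ground truth."""
    cohort = synth.simulate_cohort(config)
    pollutant = config.effect.pollutant

    exposures = exposure.assign_cohort_exposures(
        cohort.participants, cohort.stations.stations, cohort.stations.weekly,
        pollutant)
    period_avgs = exposure.cohort_period_averages(exposures, cohort.participants)

    m = cohort.methylation
    x_probes = [i for i in m.beta.index if str(i).startswith("cg_x_")]
    adjusted, qc_report = methqc.run_qc_pipeline(
        m.beta, m.detection_p, m.intensity, m.samplesheet, x_probes,
        seed=config.seed)

    panel_beta = adjusted.loc[adjusted.index.intersection(m.reference_panel.index)]
    proportions = deconv.estimate_cohort_proportions(panel_beta, m.reference_panel)

    if clock_model is None:
        clock_model = train_reference_clock(config, seed=config.seed + 1)
    ega = clock.predict_ega(adjusted, clock_model)
    cga = cohort.participants.set_index("participant_id")["ga_weeks"]
    ga_results = clock.age_accel_table(ega, cga.loc[ega.index], proportions)

    covariates = cohort.participants.set_index("participant_id")
    spec = assoc.GridSpec(pollutants=[pollutant], periods=list(assoc_periods),
                          models=list(assoc_models))
    estimates = assoc.run_analysis_grid(ga_results, period_avgs, covariates, spec)

    lagmat = exposure.weekly_lag_matrix(exposures, pollutant)
    idx = ga_results.index.intersection(lagmat.index)
    design = assoc.build_covariate_design(covariates.loc[idx])
    fit = dlm.select_basis(ga_results.loc[idx, "intrinsic_gaa"].to_numpy(),
                           lagmat.loc[idx].to_numpy(), design.to_numpy(),
                           list(basis_candidates))
    windows = dlm.extract_windows(fit)
    return PipelineResult(cohort, exposures, period_avgs, qc_report,
                          proportions, ga_results, estimates, fit, windows)
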