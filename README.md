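# gestwin

Critical-window analysis of prenatal ambient air pollution and placental
epigenetic gestational age acceleration.

Environmental epidemiologists studying pregnancy ask not only *whether*
an exposure affects the fetus but *when*: which weeks of preconception and
pregnancy are sensitive. `gestwin` is a tested, reusable implementation of
the full analysis chain for that question when the outcome is placental
epigenetic gestational age at birth:

1. **Exposure assignment** — weekly pollutant concentrations (NO₂, O₃,
   PM₂.₅, PM₁₀) interpolated from monitoring stations to residences by
   inverse-distance-squared weighting (stations within 5 km are exclusive;
   otherwise up to the 4 nearest within 50 km), laid out on a unified week
   axis (13 preconception weeks, then pregnancy weeks), with period
   averages under a strict ≤10% missing-week rule.
2. **Methylation QC** — detection-p probe/sample filters, cross-reactive
   probe removal, low-intensity and sex-discordance exclusions, twin
   dedup, parametric empirical Bayes batch adjustment on the logit scale,
   quantile normalization to a gold-standard array, PC-based outlier
   flagging.
3. **Cell deconvolution** — six placental cell types by constrained
   projection (min ‖b − Rw‖², w ≥ 0, Σw ≤ 1) on a reference panel.
4. **Epigenetic clocks** — EGA = a + Σⱼ wⱼ βⱼ over clock CpGs (loadable
   coefficients or elastic-net training); **intrinsic** GAA/GAD = residual
   of EGA on chronologic GA adjusting for cell proportions, **extrinsic**
   = the univariate residual.
5. **Period-average models** — OLS of GAA/GAD on period-average exposure
   plus covariates, per-10-unit effects with 95% CIs; mutually adjusted
   models across exposure periods.
6. **Distributed-lag models** — weekly effects over the 48-week axis with
   polynomial or natural-cubic-spline lag constraints (θ = Bη), AIC basis
   selection, and critical windows as maximal runs of weeks whose
   pointwise CI excludes zero.

Because cohorts of this kind are rarely public, the package includes a
first-class synthetic-data generator (`gestwin.synth`) that emulates
stations, pregnancies, methylation arrays with planted QC failures and
batch effects, and a configurable exposure effect on biological
gestational age — with a ground-truth record, so every stage is testable
end to end. See `docs/methods.md` for the models and design choices.

## Worked example

```python
from gestwin import pipeline
from gestwin.config import SimulationConfig

# 150 pregnancies; planted effect: -1.0 week of biological GA per
# sustained 10 ppb O3 increase over unified weeks 34-44 (pregnancy 21-31)
res = pipeline.run_pipeline(SimulationConfig(seed=1))
print(res.estimates[["period", "outcome", "beta_per_10",
                     "ci_low", "ci_high", "p_value", "n"]])
```

prints

```
          period    outcome  beta_per_10    ci_low   ci_high   p_value    n
0  preconception  intrinsic     0.510661  0.291663  0.729660  0.000010  142
1      pregnancy  intrinsic    -0.990779 -1.719624 -0.261934  0.008123  142
2  preconception  extrinsic     0.523282  0.296742  0.749823  0.000012  142
3      pregnancy  extrinsic    -1.054755 -1.806261 -0.303250  0.006327  142
```

The pregnancy-period estimates recover the planted deceleration (about
−1 week of gestational age acceleration per 10 ppb, CIs excluding 0). The
*positive* preconception estimates are a real artefact of seasonality:
preconception and mid-pregnancy O₃ are negatively correlated, so a
single-period model inherits an omitted-variable bias — exactly the
phenomenon the mutually adjusted model (`assoc.fit_mutually_adjusted`)
resolves, re-centering the preconception CI on zero.

The same stages are scriptable from the shell:

```bash
gestwin simulate --out sim/
gestwin expose --stations sim/stations.csv --weekly sim/station_weekly.csv \
    --participants sim/participants.csv --pollutant O3 --out exposures.csv
gestwin qc --beta sim/beta.tsv --detp sim/detection_p.tsv \
    --samplesheet sim/samplesheet.csv --intensity sim/intensity.csv --out qc/
gestwin deconv --beta qc/beta_adjusted.tsv --panel sim/reference_panel.tsv \
    --out proportions.csv
gestwin clock --beta qc/beta_adjusted.tsv --model clock_coefs.csv \
    --participants sim/participants.csv --proportions proportions.csv \
    --out ga_results.csv
gestwin assoc --ga ga_results.csv --periods exposures_period_averages.csv \
    --covariates sim/participants.csv --pollutants O3 --out estimates.csv
gestwin dlm --ga ga_results.csv --weekly exposures.csv \
    --covariates sim/participants.csv --pollutant O3 --out dlm_O3.json
```

User-supplied data in the same tabular shapes (station table + long-format
weekly series, participant table, beta/detection-p TSV matrices, intensity
sheet, reference panel, clock coefficient CSV) can be substituted for any
of the simulated files.

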