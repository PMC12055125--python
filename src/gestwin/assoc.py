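"""Period-average association models for gestational age acceleration.

Multivariable linear regression of intrinsic/extrinsic GAA on
period-average pollutant exposure, adjusting for the fixed covariate roster
(maternal age, race, ethnicity, education, income, pre-pregnancy BMI class,
child sex, birth season, study site). Effects are reported per 10-unit
increment of the pollutant (10 ppb or 10 ug/m3) with normal-theory 95% CIs
and two-sided p-values, on complete cases only. Mutually adjusted models
enter all period averages of one pollutant as simultaneous regressors, the
standard device for separating correlated exposure periods.

No multiple-testing adjustment is applied across the analysis grid; outputs
carry raw two-sided p-values (significance convention p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import COVARIATE_LEVELS

#: Covariate roster and fixed reference levels (first level of each
#: dictionary entry; maternal_age is continuous).
DEFAULT_COVARIATE_COLS = ("maternal_age", "race", "ethnicity", "education",
                          "income", "bmi_cat", "child_sex", "birth_season",
                          "study_site")

_CATEGORY_LEVELS = {**{k: v[0] for k, v in COVARIATE_LEVELS.items()},
                    "birth_season": ["warm", "cold"]}


def build_covariate_design(covariates: pd.DataFrame,
                           columns=DEFAULT_COVARIATE_COLS) -> pd.DataFrame:
    """Dummy-code the covariate table with fixed reference levels.

    Returns a numeric design (no intercept column) indexed like the input;
    unknown category values raise.
    """
    parts = []
    for col in columns:
        if col not in covariates.columns:
            raise KeyError(f"covariate column {col!r} missing")
        if col in _CATEGORY_LEVELS:
            levels = _CATEGORY_LEVELS[col]
            bad = set(covariates[col].dropna()) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} categories: {sorted(bad)}")
            cat = pd.Categorical(covariates[col], categories=levels)
            dum = pd.get_dummies(pd.Series(cat, index=covariates.index),
                                 prefix=col, dtype=float, drop_first=True)
            # preserve NaN as missing
            dum[covariates[col].isna()] = np.nan
            parts.append(dum)
        else:
            parts.append(covariates[[col]].astype(float))
    return pd.concat(parts, axis=1)


@dataclass
class AssocEstimate:
    pollutant: str
    period: str
    outcome: str
    model: str                      # "individual" | "mutual"
    beta_per_10: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    n: int = 0
    error: Optional[str] = None


def _fit_ols(y: np.ndarray, x: pd.DataFrame):
    model = sm.OLS(y, sm.add_constant(x.to_numpy(dtype=float), has_constant="add"))
    return model.fit()


def fit_individual(outcome: pd.Series, exposure: pd.Series,
                   covariates: pd.DataFrame,
                   covariate_cols=DEFAULT_COVARIATE_COLS,
                   pollutant: str = "", period: str = "",
                   outcome_name: str = "") -> AssocEstimate:
    """Single-period model: outcome ~ exposure + covariates (complete cases).

    The exposure coefficient is rescaled to a per-10-unit increment
    post-fit (identical to pre-dividing the regressor by 10).
    """
    design = build_covariate_design(covariates, covariate_cols)
    df = pd.concat([outcome.rename("_y"), exposure.rename("_x"), design],
                   axis=1, join="inner").dropna()
    n = len(df)
    n_params = design.shape[1] + 2
    if n <= n_params + 5:
        raise ValueError(f"too few complete cases (n={n}) for {n_params} parameters")
    if np.ptp(df["_x"].to_numpy()) == 0:
        raise ValueError("constant exposure")
    x = df.drop(columns=["_y"])
    res = _fit_ols(df["_y"].to_numpy(dtype=float), x)
    i = 1  # exposure is the first column after the constant
    ci = res.conf_int(alpha=0.05)
    return AssocEstimate(
        pollutant=pollutant, period=period, outcome=outcome_name,
        model="individual",
        beta_per_10=float(res.params[i] * 10.0),
        ci_low=float(ci[i, 0] * 10.0), ci_high=float(ci[i, 1] * 10.0),
        p_value=float(res.pvalues[i]), n=n)


def fit_mutually_adjusted(outcome: pd.Series, exposures: pd.DataFrame,
                          covariates: pd.DataFrame,
                          covariate_cols=DEFAULT_COVARIATE_COLS,
                          pollutant: str = "",
                          outcome_name: str = "") -> list[AssocEstimate]:
    """One model with all period averages of a pollutant as simultaneous
    regressors; returns one per-10-unit estimate per period."""
    periods = list(exposures.columns)
    if len(periods) >= 2:
        corr = exposures.dropna().corr().to_numpy()
        off = corr[~np.eye(len(periods), dtype=bool)]
        if np.any(np.abs(off) > 0.99):
            raise ValueError("period averages nearly collinear (|r| > 0.99): "
                             "not identifiable")
    design = build_covariate_design(covariates, covariate_cols)
    df = pd.concat([outcome.rename("_y"), exposures, design],
                   axis=1, join="inner").dropna()
    n = len(df)
    n_params = design.shape[1] + 1 + len(periods)
    if n <= n_params + 5:
        raise ValueError(f"too few complete cases (n={n}) for {n_params} parameters")
    res = _fit_ols(df["_y"].to_numpy(dtype=float), df.drop(columns=["_y"]))
    ci = res.conf_int(alpha=0.05)
    out = []
    for j, period in enumerate(periods):
        i = 1 + j
        out.append(AssocEstimate(
            pollutant=pollutant, period=period, outcome=outcome_name,
            model="mutual",
            beta_per_10=float(res.params[i] * 10.0),
            ci_low=float(ci[i, 0] * 10.0), ci_high=float(ci[i, 1] * 10.0),
            p_value=float(res.pvalues[i]), n=n))
    return out


@dataclass
class GridSpec:
    pollutants: list[str]
    periods: list[str]
    outcomes: list[str] = field(default_factory=lambda: ["intrinsic", "extrinsic"])
    models: list[str] = field(default_factory=lambda: ["individual"])
    full_term_only: bool = False


_OUTCOME_COLS = {"intrinsic": "intrinsic_gaa", "extrinsic": "extrinsic_gaa"}


def run_analysis_grid(ga_results: pd.DataFrame, period_averages: pd.DataFrame,
                      covariates: pd.DataFrame, spec: GridSpec,
                      covariate_cols=DEFAULT_COVARIATE_COLS) -> pd.DataFrame:
    """Fit the pollutant x period x outcome x model grid; one row per cell.

    ``ga_results`` is indexed by sample_id with intrinsic_gaa/extrinsic_gaa
    columns; ``period_averages`` is the long table from the exposure module;
    ``covariates`` is indexed by participant_id. Cells that cannot be fit
    are recorded with their failure reason rather than raised.
    """
    ga = ga_results
    if spec.full_term_only:
        ga = ga[ga["cga_weeks"] >= 37.0]
    wide = period_averages.pivot_table(index="participant_id",
                                       columns=["pollutant", "period"],
                                       values="mean", aggfunc="first")
    rows = []
    for pol in spec.pollutants:
        for outcome in spec.outcomes:
            y = ga[_OUTCOME_COLS[outcome]]
            for model in spec.models:
                if model == "individual":
                    for period in spec.periods:
                        try:
                            exp = wide[(pol, period)]
                            est = fit_individual(y, exp, covariates,
                                                 covariate_cols, pol, period,
                                                 outcome)
                        except (KeyError, ValueError) as e:
                            est = AssocEstimate(pol, period, outcome,
                                                "individual", error=str(e))
                        rows.append(vars(est))
                elif model == "mutual":
                    try:
                        exp = wide[pol][spec.periods]
                        ests = fit_mutually_adjusted(y, exp, covariates,
                                                     covariate_cols, pol,
                                                     outcome_name=outcome)
                    except (KeyError, ValueError) as e:
                        ests = [AssocEstimate(pol, p, outcome, "mutual",
                                              error=str(e))
                                for p in spec.periods]
                    rows.extend(vars(e) for e in ests)
                else:
                    raise ValueError(f"unknown model type {model!r}")
    return pd.DataFrame(rows)
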