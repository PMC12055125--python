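"""Epigenetic gestational age: linear clocks and age-acceleration residuals.

A clock predicts gestational age as an intercept plus a weighted sum of
beta values at its CpG sites. Clocks can be trained here by elastic-net
regression of chronologic GA on methylation (10-fold cross-validated
penalty), or loaded from a coefficient file. Age acceleration/deceleration
is the residual of epigenetic on chronologic GA: extrinsic from the
univariate regression, intrinsic additionally adjusting for estimated cell
type proportions (one compartment dropped to break the simplex
collinearity). Positive residual = acceleration, negative = deceleration;
both residual vectors sum to zero across the cohort by OLS construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

INTERCEPT_ROW = "__intercept__"


@dataclass
class ClockModel:
    intercept: float                 # weeks
    weights: pd.Series               # weeks per unit beta, indexed by CpG id

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise ValueError("clock must have at least one CpG coefficient")
        if self.weights.index.duplicated().any():
            raise ValueError("duplicate CpG ids in clock coefficients")

    @property
    def cpgs(self) -> list[str]:
        return list(self.weights.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cpg": self.cpgs, "weight": self.weights.to_numpy()})
        return pd.concat([df, pd.DataFrame({"cpg": [INTERCEPT_ROW],
                                            "weight": [self.intercept]})],
                         ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClockModel":
        s = df.set_index("cpg")["weight"]
        if INTERCEPT_ROW not in s.index:
            raise ValueError(f"coefficient file lacks the {INTERCEPT_ROW} row")
        intercept = float(s[INTERCEPT_ROW])
        return cls(intercept, s.drop(INTERCEPT_ROW).astype(float))


def predict_ega(beta: pd.DataFrame, model: ClockModel) -> pd.Series:
    """Epigenetic GA per sample: intercept + sum_j w_j * beta_j.

    Every clock CpG must be present; missing sites raise (no imputation).
    """
    missing = [c for c in model.cpgs if c not in beta.index]
    if missing:
        raise ValueError(f"{len(missing)} clock CpGs absent from beta matrix: "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    sub = beta.loc[model.cpgs].to_numpy(dtype=float)
    ega = model.intercept + model.weights.to_numpy() @ sub
    return pd.Series(ega, index=beta.columns, name="ega_weeks")


def train_clock(beta: pd.DataFrame, ga_weeks: pd.Series,
                alpha_grid=None, l1_ratio: float = 0.5,
                seed: int = 0, cv_folds: int = 10) -> ClockModel:
    """Train a gestational-age clock by cross-validated elastic net.

    Regresses chronologic GA on beta values (samples as rows), choosing the
    penalty by ``cv_folds``-fold CV over ``alpha_grid`` (a default
    log-spaced grid when None). Returns only nonzero-coefficient CpGs.
    """
    samples = [s for s in beta.columns if s in ga_weeks.index]
    if len(samples) < 50:
        raise ValueError(f"need >= 50 training samples, got {len(samples)}")
    y = ga_weeks.loc[samples].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant gestational age vector")
    x = beta[samples].to_numpy(dtype=float).T
    if alpha_grid is None:
        alpha_grid = np.logspace(-3.5, -1, 8)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(alphas=np.asarray(alpha_grid, dtype=float),
                        l1_ratio=l1_ratio, cv=cv, max_iter=20000, tol=1e-3)
    enet.fit(x, y)
    nz = np.flatnonzero(enet.coef_)
    if nz.size == 0:
        # full-shrinkage limit: intercept-only clock anchored at one site
        w = pd.Series([0.0], index=[beta.index[0]])
        return ClockModel(float(enet.intercept_), w)
    w = pd.Series(enet.coef_[nz], index=beta.index[nz])
    return ClockModel(float(enet.intercept_), w)


# ---------------------------------------------------------------------------
# Age acceleration residuals

def _ols_residuals(y: np.ndarray, x: np.ndarray, colnames) -> np.ndarray:
    # exact (saturated) fits are legal and return zero residuals
    if y.shape[0] < x.shape[1]:
        raise ValueError(f"need >= {x.shape[1]} samples for "
                         f"{x.shape[1]} regressors, got {y.shape[0]}")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"collinear design over columns {list(colnames)}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def compute_extrinsic(ega: pd.Series, cga: pd.Series) -> pd.Series:
    """Extrinsic GAA/GAD: residual of EGA on chronologic GA (with intercept)."""
    idx = ega.index.intersection(cga.index)
    y = ega.loc[idx].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(idx)), cga.loc[idx].to_numpy(dtype=float)])
    r = _ols_residuals(y, x, ["intercept", "cga"])
    return pd.Series(r, index=idx, name="extrinsic_gaa")


def compute_intrinsic(ega: pd.Series, cga: pd.Series,
                      cell_proportions: pd.DataFrame,
                      drop_cell_type: str = "syncytiotrophoblast") -> pd.Series:
    """Intrinsic GAA/GAD: residual of EGA on chronologic GA adjusting for
    cell proportions.

    One compartment (the largest, syncytiotrophoblast, by default) is
    dropped so renormalized proportions do not make the design singular.
    Complete cases only.
    """
    props = cell_proportions.drop(columns=[drop_cell_type], errors="ignore")
    props = props.drop(columns=["sum"], errors="ignore")
    idx = ega.index.intersection(cga.index).intersection(props.dropna().index)
    y = ega.loc[idx].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(idx)),
                         cga.loc[idx].to_numpy(dtype=float),
                         props.loc[idx].to_numpy(dtype=float)])
    r = _ols_residuals(y, x, ["intercept", "cga", *props.columns])
    return pd.Series(r, index=idx, name="intrinsic_gaa")


def age_accel_table(ega: pd.Series, cga: pd.Series,
                    cell_proportions: pd.DataFrame,
                    drop_cell_type: str = "syncytiotrophoblast") -> pd.DataFrame:
    """Per-sample epigenetic/chronologic GA and both residual measures."""
    intrinsic = compute_intrinsic(ega, cga, cell_proportions, drop_cell_type)
    extrinsic = compute_extrinsic(ega, cga)
    idx = intrinsic.index
    return pd.DataFrame({
        "sample_id": idx,
        "ega_weeks": ega.loc[idx].to_numpy(),
        "cga_weeks": cga.loc[idx].to_numpy(),
        "intrinsic_gaa": intrinsic.to_numpy(),
        "extrinsic_gaa": extrinsic.loc[idx].to_numpy(),
    }).set_index("sample_id")
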