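"""Reference-based placental cell-type deconvolution by constrained projection.

Each sample's beta vector over the reference-panel CpGs is projected onto
the reference profiles of the six placental cell types
(syncytiotrophoblast, trophoblasts, Hofbauer, endothelial, stromal,
nucleated red blood cells) by solving the quadratic program

    minimize  || b - R w ||^2   subject to  w >= 0,  sum(w) <= 1.

Weights are reported unnormalized (their sum is typically near but not
exactly 1); ``renormalize=True`` rescales to the unit simplex for use as
regression covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

MIN_PANEL_OVERLAP = 0.80


def estimate_proportions(sample_beta: pd.Series, panel: pd.DataFrame,
                         renormalize: bool = False) -> pd.Series:
    """Estimate cell-type weights for one sample.

    ``sample_beta`` is indexed by CpG id; CpGs missing from the sample are
    dropped pairwise, requiring >= 80% panel coverage. Raises if the panel
    is rank deficient after dropping.
    """
    if panel.isna().any().any():
        raise ValueError("reference panel contains missing entries")
    if panel.shape[0] < 2 * panel.shape[1]:
        raise ValueError("reference panel needs >= 2x more CpGs than cell types")
    common = panel.index.intersection(sample_beta.dropna().index)
    if len(common) < MIN_PANEL_OVERLAP * panel.shape[0]:
        raise ValueError(
            f"only {len(common)}/{panel.shape[0]} panel CpGs present in sample "
            f"(need >= {MIN_PANEL_OVERLAP:.0%})")
    r = panel.loc[common].to_numpy(dtype=float)
    b = sample_beta.loc[common].to_numpy(dtype=float)
    if np.linalg.matrix_rank(r) < r.shape[1]:
        raise ValueError("reference panel rank deficient after CpG dropping")

    k = r.shape[1]
    rtr = r.T @ r
    rtb = r.T @ b

    def objective(w):
        return 0.5 * w @ rtr @ w - rtb @ w

    def grad(w):
        return rtr @ w - rtb

    res = minimize(objective, np.full(k, 1.0 / k), jac=grad, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k,
                   constraints=[{"type": "ineq",
                                 "fun": lambda w: 1.0 - w.sum(),
                                 "jac": lambda w: -np.ones(k)}],
                   options={"maxiter": 500, "ftol": 1e-14})
    w = np.clip(res.x, 0.0, None)
    if renormalize and w.sum() > 0:
        w = w / w.sum()
    return pd.Series(w, index=panel.columns, name=sample_beta.name)


def estimate_cohort_proportions(beta: pd.DataFrame, panel: pd.DataFrame,
                                renormalize: bool = False) -> pd.DataFrame:
    """Cell proportions for every sample (rows) in a CpG x sample matrix."""
    rows = {}
    for sid in beta.columns:
        rows[sid] = estimate_proportions(beta[sid], panel, renormalize=renormalize)
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    out["sum"] = out[list(panel.columns)].sum(axis=1)
    return out
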