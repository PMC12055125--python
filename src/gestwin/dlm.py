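"""Weekly distributed-lag models over the unified 48-week exposure axis.

The outcome (a GAA/GAD residual) is regressed on the full 48-week exposure
history — 13 preconception weeks plus pregnancy weeks 1-35 — with the
weekly-coefficient curve constrained to a low-dimensional lag basis
(polynomial in the centered/scaled lag index, or natural cubic spline).
Pregnancy weeks 36-39 are excluded structurally: the axis ends at unified
week 48, so preterm and term pregnancies share a complete lag matrix.

Fitting one constrained model for all lags accounts concurrently for
current and past exposure; the basis order is selected by AIC. Critical
windows are maximal runs of consecutive weeks whose pointwise CIs exclude
zero. Pointwise (not simultaneous) intervals are reported, matching the
usual presentation of weekly DLM effect curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import N_LAG_WEEKS, PRECONCEPTION_WEEKS


# ---------------------------------------------------------------------------
# Lag bases

@dataclass
class LagBasis:
    kind: str                # "polynomial" | "natural_cubic_spline"
    order: int               # polynomial degree p (q = p+1) or spline df (q = df)
    matrix: np.ndarray       # n_lags x q, full column rank

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


def _natural_spline_basis(z: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Classic ns() construction: columns 1, x, and K-2 truncated-power
    combinations that are linear beyond the boundary knots."""
    k = len(knots)

    def d(j: int) -> np.ndarray:
        return (np.maximum(z - knots[j], 0.0) ** 3
                - np.maximum(z - knots[-1], 0.0) ** 3) / (knots[-1] - knots[j])

    cols = [np.ones_like(z), z]
    d_last = d(k - 2)
    for j in range(k - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


def build_lag_basis(kind: str, order: int,
                    n_lags: int = N_LAG_WEEKS) -> LagBasis:
    """Polynomial (degree 0-6) or natural cubic spline (df 2-8) lag basis.

    The lag index 1..n_lags is centered and scaled to unit SD before
    powering (numerical conditioning); spline boundary knots sit at lags 1
    and n_lags with internal knots at equally spaced quantiles.
    """
    lag = np.arange(1, n_lags + 1, dtype=float)
    z = (lag - lag.mean()) / lag.std()
    if kind == "polynomial":
        if not 0 <= order <= 6:
            raise ValueError(f"polynomial degree must be in 0..6, got {order}")
        mat = np.column_stack([z ** p for p in range(order + 1)])
    elif kind == "natural_cubic_spline":
        if not 2 <= order <= 8:
            raise ValueError(f"spline df must be in 2..8, got {order}")
        if order == 2:
            mat = np.column_stack([np.ones_like(z), z])
        else:
            qs = np.linspace(0.0, 1.0, order)[1:-1]
            internal = np.quantile(lag, qs)
            knots = np.concatenate([[lag[0]], internal, [lag[-1]]])
            zknots = (knots - lag.mean()) / lag.std()
            mat = _natural_spline_basis(z, zknots)
    else:
        raise ValueError(f"unknown basis kind {kind!r}")
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("lag basis is rank deficient")
    return LagBasis(kind, order, mat)


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class DLMFit:
    basis: LagBasis
    eta: np.ndarray              # q basis-space coefficients (per unit)
    cov_eta: np.ndarray          # q x q
    theta: np.ndarray            # 48 weekly effects per 10-unit increment
    se_theta: np.ndarray         # per 10-unit
    ci_low: np.ndarray
    ci_high: np.ndarray
    aic: float
    n: int
    n_dropped: int
    df_resid: int
    alpha: float = 0.05
    selection_log: list = field(default_factory=list)

    def ci(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return self.theta - tcrit * self.se_theta, self.theta + tcrit * self.se_theta


def fit_dlm(outcome, weekly_exposure, covariate_design, basis: LagBasis,
            alpha: float = 0.05) -> DLMFit:
    """OLS fit of the basis-constrained distributed lag model.

    ``weekly_exposure`` is n x 48 (unified weeks 1..48); participants with
    any missing week or covariate are dropped (count recorded). The design
    is [intercept | covariates | X B]; weekly effects theta = B eta exactly,
    reported per 10-unit increment, with pointwise t CIs and RSS-based AIC
    = n log(RSS/n) + 2 (p + 1).
    """
    x = np.asarray(weekly_exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape[1] != basis.matrix.shape[0]:
        raise ValueError(f"exposure matrix has {x.shape[1]} weeks; basis expects "
                         f"{basis.matrix.shape[0]}")
    if covariate_design is None:
        c = np.empty((len(y), 0))
    else:
        c = np.asarray(covariate_design, dtype=float)
    keep = (~np.isnan(x).any(axis=1)) & ~np.isnan(y) & (~np.isnan(c).any(axis=1))
    n_dropped = int((~keep).sum())
    x, y, c = x[keep], y[keep], c[keep]
    n = len(y)

    b = basis.matrix
    design = np.hstack([np.ones((n, 1)), c, x @ b])
    p = design.shape[1]
    if n < p + 10:
        raise ValueError(f"need n >= {p + 10} complete participants, got {n}")
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient DLM design")
    resid = y - design @ coef
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(design.T @ design)
    q = basis.q
    eta = coef[-q:]
    cov_eta = sigma2 * xtx_inv[-q:, -q:]

    theta = (b @ eta) * 10.0
    var_theta = np.einsum("ij,jk,ik->i", b, cov_eta, b)
    se = np.sqrt(np.maximum(var_theta, 0.0)) * 10.0
    tcrit = stats.t.ppf(1 - alpha / 2, df_resid)
    aic = n * math.log(rss / n) + 2.0 * (p + 1)
    return DLMFit(basis, eta, cov_eta, theta, se,
                  theta - tcrit * se, theta + tcrit * se,
                  aic, n, n_dropped, df_resid, alpha)


def select_basis(outcome, weekly_exposure, covariate_design,
                 candidates: list[tuple[str, int]],
                 alpha: float = 0.05) -> DLMFit:
    """Fit every candidate (kind, order) basis and return the minimum-AIC
    fit; ties broken toward the smaller order, then first listed. All AICs
    (and failures) are recorded in the returned fit's ``selection_log``."""
    if len(candidates) < 2:
        if len(candidates) == 1:
            kind, order = candidates[0]
            fit = fit_dlm(outcome, weekly_exposure, covariate_design,
                          build_lag_basis(kind, order), alpha)
            fit.selection_log.append((kind, order, fit.aic))
            return fit
        raise ValueError("need at least one candidate basis")
    log, fits, errors = [], [], []
    for kind, order in candidates:
        try:
            fit = fit_dlm(outcome, weekly_exposure, covariate_design,
                          build_lag_basis(kind, order), alpha)
            log.append((kind, order, fit.aic))
            fits.append((fit.aic, order, len(fits), fit))
        except ValueError as e:
            log.append((kind, order, None))
            errors.append(f"{kind}({order}): {e}")
    if not fits:
        raise ValueError("all candidate bases failed: " + "; ".join(errors))
    fits.sort(key=lambda t: (t[0], t[1], t[2]))
    best = fits[0][3]
    best.selection_log = log
    return best


# ---------------------------------------------------------------------------
# Window extraction

@dataclass
class WindowRun:
    start_week: int              # unified axis, 1-based
    end_week: int
    sign: int                    # +1 acceleration, -1 deceleration
    peak_week: int               # argmax |theta| within the run (unified)

    @property
    def pregnancy_weeks(self) -> "tuple[int, int] | None":
        """(start, end) as pregnancy weeks when the run lies past
        preconception; unified weeks 14-48 map to pregnancy weeks 1-35."""
        if self.end_week <= PRECONCEPTION_WEEKS:
            return None
        s = max(self.start_week - PRECONCEPTION_WEEKS, 1)
        return (s, self.end_week - PRECONCEPTION_WEEKS)


@dataclass
class WindowSummary:
    runs: list[WindowRun]
    alpha: float


def extract_windows(fit: DLMFit, alpha: float = 0.05) -> WindowSummary:
    """Maximal consecutive-week runs whose pointwise CI excludes zero."""
    lo, hi = fit.ci(alpha)
    sig = np.where(lo > 0.0, 1, np.where(hi < 0.0, -1, 0))
    runs: list[WindowRun] = []
    start = None
    for i in range(len(sig) + 1):
        cur = sig[i] if i < len(sig) else 0
        if start is not None and (cur != sig[start]):
            seg = slice(start, i)
            peak = start + int(np.argmax(np.abs(fit.theta[seg])))
            runs.append(WindowRun(start + 1, i, int(sig[start]), peak + 1))
            start = None
        if cur != 0 and start is None:
            start = i
    return WindowSummary(runs, alpha)


def full_term_restrict(participants: pd.DataFrame,
                       ga_threshold: float = 37.0) -> pd.DataFrame:
    """Sensitivity subset: keep full-term births (GA >= threshold weeks)."""
    out = participants[participants["ga_weeks"] >= ga_threshold]
    if len(out) == 0:
        raise ValueError("no participants left after full-term restriction")
    return out
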