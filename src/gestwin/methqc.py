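"""Methylation array quality control and batch adjustment.

Pipeline order (fixed and logged): probe filters -> sample filters -> twin
dedup -> empirical Bayes batch adjustment -> gold-standard quantile
normalization -> PC outlier flagging. Probe/sample detection filters use the
strict >0.01 / >10% thresholds; the low-intensity cut is median log2
intensity < 11; sex concordance compares reported sex with a prediction
from X-probe methylation (two-means clustering; X inactivation raises
intermediate methylation in females, so the lower-mean cluster is male).

Batch adjustment is the parametric empirical Bayes location/scale model
(ComBat): per-feature batch means and variances are shrunk toward pooled
estimates under a normal / inverse-gamma prior and removed, operating on the
logit (M-value-like) scale where the Gaussian model is reasonable. After
adjustment each feature is recentred to its original logit-scale grand mean,
so adjustment never moves the overall methylation level of a probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

LOGIT_EPS = 1e-6
DETECTION_P_THRESH = 0.01
DETECTION_FRAC_THRESH = 0.10
INTENSITY_THRESH = 11.0

PROBE_REASONS = ("detection", "cross_reactive")
SAMPLE_REASONS = ("detection", "low_intensity", "sex_discordant",
                  "missing_sex", "twin_dedup", "pc_outlier")


@dataclass
class QCReport:
    dropped_probes: list[tuple[str, str]] = field(default_factory=list)
    dropped_samples: list[tuple[str, str]] = field(default_factory=list)
    n_probes_retained: int = 0
    n_samples_retained: int = 0
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_probes": [{"id": i, "reason": r} for i, r in self.dropped_probes],
            "dropped_samples": [{"id": i, "reason": r} for i, r in self.dropped_samples],
            "n_probes_retained": self.n_probes_retained,
            "n_samples_retained": self.n_samples_retained,
            "log": self.log,
        }


# ---------------------------------------------------------------------------
# Probe / sample filters

def filter_probes(detection_p: pd.DataFrame, cross_reactive_ids=(),
                  p_thresh: float = DETECTION_P_THRESH,
                  frac_thresh: float = DETECTION_FRAC_THRESH
                  ) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop probes failing detection in strictly more than ``frac_thresh``
    of samples (p > ``p_thresh``), and probes on the cross-reactive list."""
    if detection_p.size == 0:
        raise ValueError("empty detection p-value matrix")
    fail_frac = (detection_p.to_numpy() > p_thresh).mean(axis=1)
    xr = set(cross_reactive_ids)
    retained, dropped = [], []
    for pid, frac in zip(detection_p.index, fail_frac):
        if frac > frac_thresh:
            dropped.append((pid, "detection"))
        elif pid in xr:
            dropped.append((pid, "cross_reactive"))
        else:
            retained.append(pid)
    return retained, dropped


def predict_sex(beta: pd.DataFrame, x_probe_ids) -> pd.Series:
    """Predict sample sex from X-probe methylation by 1-D two-means.

    The per-sample mean beta over X probes is split by the exact 1-D
    two-means partition (minimum within-cluster sum of squares over sorted
    split points); the lower-mean cluster is labelled male.
    """
    x_ids = [i for i in x_probe_ids if i in beta.index]
    if not x_ids:
        raise ValueError("no X probes present in beta matrix")
    m = beta.loc[x_ids].mean(axis=0).to_numpy(dtype=float)
    order = np.argsort(m, kind="mergesort")
    s = m[order]
    n = len(s)
    if n < 2 or s[0] == s[-1]:
        return pd.Series(["M"] * n, index=beta.columns)
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    best_cost, best_k = np.inf, 1
    for k in range(1, n):  # split: first k vs rest
        ss1 = csq[k - 1] - csum[k - 1] ** 2 / k
        ss2 = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        if ss1 + ss2 < best_cost:
            best_cost, best_k = ss1 + ss2, k
    labels = np.empty(n, dtype=object)
    labels[order[:best_k]] = "M"
    labels[order[best_k:]] = "F"
    return pd.Series(labels, index=beta.columns)


def filter_samples(detection_p: pd.DataFrame, intensity_sheet: pd.DataFrame,
                   reported_sex: pd.Series, beta: pd.DataFrame,
                   x_probe_ids) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop samples with >10% failing probes, low intensity (< 11 median
    log2 RFU), missing reported sex, or sex discordance (reported vs
    X-probe prediction). One primary reason per dropped sample, in that
    priority order."""
    fail_frac = pd.Series((detection_p.to_numpy() > DETECTION_P_THRESH).mean(axis=0),
                          index=detection_p.columns)
    intensity = intensity_sheet.set_index("sample_id")["median_log2_intensity"]
    predicted = predict_sex(beta, x_probe_ids)
    retained, dropped = [], []
    for sid in detection_p.columns:
        if fail_frac[sid] > DETECTION_FRAC_THRESH:
            dropped.append((sid, "detection"))
        elif intensity.get(sid, np.inf) < INTENSITY_THRESH:
            dropped.append((sid, "low_intensity"))
        elif sid not in reported_sex.index or pd.isna(reported_sex[sid]):
            dropped.append((sid, "missing_sex"))
        elif predicted[sid] != reported_sex[sid]:
            dropped.append((sid, "sex_discordant"))
        else:
            retained.append(sid)
    return retained, dropped


def dedup_twins(sample_ids: list[str], twin_pair: pd.Series,
                seed: int = 0) -> tuple[list[str], list[tuple[str, str]]]:
    """Randomly keep one sample per twin pair (seeded RNG)."""
    rng = np.random.default_rng([seed, 41])
    pairs: dict[str, list[str]] = {}
    for sid in sample_ids:
        tp = twin_pair.get(sid, "")
        if isinstance(tp, str) and tp:
            pairs.setdefault(tp, []).append(sid)
    drop = set()
    for tp in sorted(pairs):
        members = sorted(pairs[tp])
        if len(members) > 1:
            keep = members[int(rng.integers(len(members)))]
            drop.update(m for m in members if m != keep)
    retained = [s for s in sample_ids if s not in drop]
    return retained, [(s, "twin_dedup") for s in sorted(drop)]


# ---------------------------------------------------------------------------
# Empirical Bayes batch adjustment

def _to_logit(beta: np.ndarray) -> np.ndarray:
    return logit(np.clip(beta, LOGIT_EPS, 1.0 - LOGIT_EPS))


def eb_batch_adjust(beta: pd.DataFrame, batch_labels: pd.Series,
                    covariates: "pd.DataFrame | None" = None,
                    max_iter: int = 100, tol: float = 1e-6) -> pd.DataFrame:
    """Remove batch effects by parametric empirical Bayes on the logit scale.

    Per feature, batch location and scale effects are estimated after
    regressing out covariates, shrunk toward pooled estimates (normal prior
    on locations, inverse-gamma on scales, hyperparameters by method of
    moments) via the standard iterative conditional solution, and removed.
    Covariate effects (e.g. sex) are restored untouched. A single batch is
    a no-op; a batch with one sample is an error.
    """
    samples = list(beta.columns)
    batches = pd.Series(batch_labels).reindex(samples)
    if batches.isna().any():
        raise ValueError("batch label missing for some samples")
    levels = sorted(batches.unique())
    if len(levels) == 1:
        return beta.copy()
    counts = batches.value_counts()
    for lev in levels:
        if counts[lev] < 2:
            raise ValueError(f"batch {lev!r} has fewer than 2 samples")

    x = _to_logit(beta.to_numpy(dtype=float))  # G x n
    n = x.shape[1]
    onehot = np.stack([(batches == lev).to_numpy(dtype=float) for lev in levels],
                      axis=1)  # n x K
    if covariates is not None and covariates.shape[1] > 0:
        c = covariates.reindex(samples).to_numpy(dtype=float)
        design = np.hstack([onehot, c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariates confounded with batch (rank-deficient design)")
    else:
        c = None
        design = onehot

    grand0 = x.mean(axis=1)
    bhat, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # p x G
    k = len(levels)
    nk = counts.loc[levels].to_numpy(dtype=float)
    alpha = (nk / n) @ bhat[:k]                          # G
    stand_mean = alpha[:, None] + (c @ bhat[k:]).T if c is not None else \
        np.tile(alpha[:, None], (1, n))
    resid = x - (design @ bhat).T
    var_pooled = np.mean(resid.T ** 2, axis=0)           # G (includes batch effects)
    # pooled variance from the full fit residuals (batch effects removed)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    z = (x - stand_mean) / sd[:, None]

    adjusted = z.copy()
    for ki, lev in enumerate(levels):
        idx = (batches == lev).to_numpy()
        zb = z[:, idx]
        nb = zb.shape[1]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gbar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        dm, dv = delta_hat.mean(), delta_hat.var(ddof=1)
        if dv <= 0 or t2 <= 0:
            gamma_star, delta_star = gamma_hat, np.maximum(delta_hat, 1e-12)
        else:
            a_prior = (2 * dv + dm ** 2) / dv
            b_prior = (dm * dv + dm ** 3) / dv
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                g_new = (nb * t2 * gamma_hat + delta_star * gbar) / \
                        (nb * t2 + delta_star)
                ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * ss + b_prior) / (nb / 2.0 + a_prior - 1.0)
                change = max(np.max(np.abs(g_new - gamma_star)),
                             np.max(np.abs(d_new - delta_star)))
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
        adjusted[:, idx] = (zb - gamma_star[:, None]) / \
            np.sqrt(np.maximum(delta_star, 1e-12))[:, None]

    out = adjusted * sd[:, None] + stand_mean
    # recentre to the original per-feature grand mean on the logit scale
    out = out - out.mean(axis=1)[:, None] + grand0[:, None]
    return pd.DataFrame(expit(out), index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# Gold-standard quantile normalization

def make_gold_standard(beta: pd.DataFrame) -> np.ndarray:
    """Reference distribution: sorted values of the mean array across
    samples (a synthetic 'gold-standard' array)."""
    return np.sort(beta.mean(axis=1).to_numpy(dtype=float))


def normalize_to_gold_standard(beta: pd.DataFrame,
                               reference: np.ndarray) -> pd.DataFrame:
    """Rescale each sample's value distribution to the reference.

    Each value is mapped through its empirical quantile (average rank over
    the sample's non-missing values, plotting positions rank/(n-1)) to the
    reference quantile function (linear interpolation between the sorted
    reference values). Rank-preserving and monotone; missing values pass
    through. A sample already distributed exactly as the reference is a
    fixed point.
    """
    reference = np.sort(np.asarray(reference, dtype=float))
    if reference.size < 10:
        raise ValueError("reference distribution must have >= 10 values")
    ref_p = np.linspace(0.0, 1.0, reference.size)
    out = beta.to_numpy(dtype=float).copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        ok = ~np.isnan(col)
        nv = int(ok.sum())
        if nv == 0:
            continue
        if nv == 1:
            p = np.array([0.5])
        else:
            p = (rankdata(col[ok], method="average") - 1.0) / (nv - 1.0)
        out[ok, j] = np.interp(p, ref_p, reference)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# PC outlier flagging

def pc_outlier_flag(beta: pd.DataFrame, sex_labels: pd.Series,
                    n_pcs: int = 2, k: float = 3.0) -> list[str]:
    """Flag samples whose first-``n_pcs`` PC scores deviate from their sex
    subgroup by more than ``k`` robust SDs (1.4826 x MAD) in any PC.

    An automated surrogate for visual inspection of PC scatterplots by sex.
    """
    x = beta.to_numpy(dtype=float).T  # samples x features
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise ValueError("degenerate (constant) beta matrix")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    scores = pd.DataFrame(scores, index=beta.columns)
    sex = pd.Series(sex_labels).reindex(beta.columns)
    flagged: set[str] = set()
    for _, grp in scores.groupby(sex):
        for pc in range(n_pcs):
            v = grp[pc]
            med = v.median()
            mad = (v - med).abs().median()
            rsd = 1.4826 * mad
            if rsd == 0.0 or not math.isfinite(k):
                continue
            for sid, val in v.items():
                if abs(val - med) > k * rsd:
                    flagged.add(sid)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# Pipeline

def run_qc_pipeline(beta: pd.DataFrame, detection_p: pd.DataFrame,
                    intensity_sheet: pd.DataFrame, samplesheet: pd.DataFrame,
                    x_probe_ids, cross_reactive_ids=(), seed: int = 0,
                    covariate_cols: tuple[str, ...] = ("reported_sex",),
                    pc_k: float = 3.0) -> tuple[pd.DataFrame, QCReport]:
    """Full QC chain in the fixed order; returns adjusted beta + report."""
    report = QCReport()
    probes, pdrop = filter_probes(detection_p, cross_reactive_ids)
    report.dropped_probes += pdrop
    report.log.append(f"probe filter: {len(probes)} retained, {len(pdrop)} dropped")
    beta = beta.loc[probes]
    detection_p = detection_p.loc[probes]

    sheet = samplesheet.set_index("sample_id")
    samples, sdrop = filter_samples(detection_p, intensity_sheet,
                                    sheet["reported_sex"], beta, x_probe_ids)
    report.dropped_samples += sdrop
    report.log.append(f"sample filter: {len(samples)} retained, {len(sdrop)} dropped")

    samples, tdrop = dedup_twins(samples, sheet.get("twin_pair", pd.Series(dtype=object)),
                                 seed=seed)
    report.dropped_samples += tdrop
    report.log.append(f"twin dedup: {len(tdrop)} dropped")
    beta = beta[samples]

    cov = pd.get_dummies(sheet.loc[samples, list(covariate_cols)],
                         drop_first=True, dtype=float)
    adjusted = eb_batch_adjust(beta, sheet.loc[samples, "plate"], cov)
    report.log.append("empirical Bayes batch adjustment (plate, logit scale)")

    normalized = normalize_to_gold_standard(adjusted, make_gold_standard(adjusted))
    report.log.append("gold-standard quantile normalization")

    flagged = pc_outlier_flag(normalized, sheet.loc[samples, "reported_sex"], k=pc_k)
    report.dropped_samples += [(s, "pc_outlier") for s in flagged]
    normalized = normalized.drop(columns=flagged)
    report.log.append(f"PC outlier flag: {len(flagged)} dropped")

    report.n_probes_retained = normalized.shape[0]
    report.n_samples_retained = normalized.shape[1]
    return normalized, report
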