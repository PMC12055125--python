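"""Probe/sample filters, empirical Bayes batch adjustment, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from gestwin import methqc

from conftest import small_config
from gestwin import synth


def _detp(fail_counts, n_samples=100):
    """Detection-p matrix where probe i fails in fail_counts[i] samples."""
    rows = []
    for c in fail_counts:
        row = np.full(n_samples, 0.001)
        row[:c] = 0.5
        rows.append(row)
    return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(fail_counts))],
                        columns=[f"s{i}" for i in range(n_samples)])


# ---------------------------------------------------------------------------
# probe filter

def test_probe_detection_threshold_is_strict():
    detp = _detp([11, 10, 0])
    retained, dropped = methqc.filter_probes(detp)
    assert dict(dropped) == {"p0": "detection"}
    assert retained == ["p1", "p2"]


def test_cross_reactive_probe_dropped_despite_perfect_detection():
    detp = _detp([0, 0])
    retained, dropped = methqc.filter_probes(detp, cross_reactive_ids=["p1"])
    assert ("p1", "cross_reactive") in dropped
    assert retained == ["p0"]


def test_all_clean_probes_retained():
    detp = _detp([0, 0, 0])
    retained, dropped = methqc.filter_probes(detp)
    assert dropped == [] and len(retained) == 3


def test_empty_matrix_rejected():
    with pytest.raises(ValueError, match="empty"):
        methqc.filter_probes(pd.DataFrame())


# ---------------------------------------------------------------------------
# sample filter

def _sample_world(n=20, intensities=None):
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(n)]
    sex = pd.Series(["M" if i % 2 else "F" for i in range(n)], index=samples)
    x_probes = [f"x{j}" for j in range(20)]
    other = [f"p{j}" for j in range(30)]
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (50, n)),
                        index=x_probes + other, columns=samples)
    for i, s in enumerate(samples):  # females intermediate, males low
        beta.loc[x_probes, s] = rng.normal(0.45 if sex[s] == "F" else 0.15,
                                           0.03, 20).clip(0, 1)
    detp = pd.DataFrame(0.001, index=beta.index, columns=samples)
    if intensities is None:
        intensities = np.full(n, 12.5)
    sheet = pd.DataFrame({"sample_id": samples,
                          "median_log2_intensity": intensities})
    return beta, detp, sheet, sex


def test_low_intensity_cut_is_strict_at_11():
    beta, detp, sheet, sex = _sample_world()
    sheet.loc[0, "median_log2_intensity"] = 10.9
    sheet.loc[1, "median_log2_intensity"] = 11.0
    retained, dropped = methqc.filter_samples(detp, sheet, sex, beta,
                                              [f"x{j}" for j in range(20)])
    assert ("s0", "low_intensity") in dropped
    assert "s1" in retained


def test_sex_discordant_sample_dropped():
    beta, detp, sheet, sex = _sample_world()
    sex_reported = sex.copy()
    sex_reported["s2"] = "M"  # true profile female
    retained, dropped = methqc.filter_samples(detp, sheet, sex_reported, beta,
                                              [f"x{j}" for j in range(20)])
    assert ("s2", "sex_discordant") in dropped
    assert len(retained) == len(sex) - 1


def test_missing_reported_sex_dropped_with_reason():
    beta, detp, sheet, sex = _sample_world()
    sex = sex.copy()
    sex["s3"] = np.nan
    _, dropped = methqc.filter_samples(detp, sheet, sex, beta,
                                       [f"x{j}" for j in range(20)])
    assert ("s3", "missing_sex") in dropped


def test_high_detection_failure_sample_dropped():
    beta, detp, sheet, sex = _sample_world()
    detp = detp.copy()
    detp.iloc[: int(0.15 * len(detp)), 4] = 0.5  # 15% failing probes
    _, dropped = methqc.filter_samples(detp, sheet, sex, beta,
                                       [f"x{j}" for j in range(20)])
    assert ("s4", "detection") in dropped


def test_twin_dedup_keeps_exactly_one_reproducibly():
    ids = ["a", "b", "c", "d"]
    pairs = pd.Series({"a": "T1", "b": "T1", "c": "", "d": ""})
    kept1, dropped1 = methqc.dedup_twins(ids, pairs, seed=3)
    kept2, dropped2 = methqc.dedup_twins(ids, pairs, seed=3)
    assert kept1 == kept2 and dropped1 == dropped2
    assert len(kept1) == 3
    assert sum(s in kept1 for s in ("a", "b")) == 1


def test_filters_are_idempotent():
    beta, detp, sheet, sex = _sample_world()
    sheet.loc[0, "median_log2_intensity"] = 10.5
    x = [f"x{j}" for j in range(20)]
    retained, _ = methqc.filter_samples(detp, sheet, sex, beta, x)
    beta2, detp2 = beta[retained], detp[retained]
    retained2, dropped2 = methqc.filter_samples(detp2, sheet, sex, beta2, x)
    assert retained2 == retained and dropped2 == []
    probes, _ = methqc.filter_probes(detp2)
    probes2, pdrop2 = methqc.filter_probes(detp2.loc[probes])
    assert probes2 == probes and pdrop2 == []


# ---------------------------------------------------------------------------
# empirical Bayes batch adjustment

def _batched_beta(n_probes=500, n_per_batch=40, shift=0.05, sex_effect=0.0,
                  n_effect_probes=None, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_batch
    base = rng.uniform(0.3, 0.6, n_probes)
    beta = np.tile(base[:, None], (1, n)) + rng.normal(0, noise, (n_probes, n))
    batch = np.repeat(["A", "B"], n_per_batch)
    beta[:, batch == "B"] += shift
    # sex balanced within each batch -> orthogonal to batch
    sex = np.tile(["M", "F"], n // 2)
    if sex_effect:
        k = n_effect_probes or n_probes
        beta[:k, sex == "F"] += sex_effect
    samples = [f"s{i}" for i in range(n)]
    return (pd.DataFrame(beta.clip(0.01, 0.99),
                         index=[f"p{i}" for i in range(n_probes)],
                         columns=samples),
            pd.Series(batch, index=samples), pd.Series(sex, index=samples))


def test_single_batch_is_identity():
    beta, batch, _ = _batched_beta(n_probes=50, shift=0.0)
    out = methqc.eb_batch_adjust(beta, pd.Series("A", index=beta.columns))
    assert np.allclose(logit(out.to_numpy()), logit(beta.to_numpy()), atol=1e-8)


def test_planted_batch_shift_removed():
    beta, batch, _ = _batched_beta(shift=0.05)
    before = (beta.loc[:, batch == "B"].mean(axis=1)
              - beta.loc[:, batch == "A"].mean(axis=1)).abs().mean()
    out = methqc.eb_batch_adjust(beta, batch)
    after = (out.loc[:, batch == "B"].mean(axis=1)
             - out.loc[:, batch == "A"].mean(axis=1)).abs().mean()
    assert after <= 0.10 * before


def test_orthogonal_sex_effect_preserved():
    beta, batch, sex = _batched_beta(shift=0.05, sex_effect=0.08,
                                     n_effect_probes=200)
    cov = pd.get_dummies(sex, drop_first=True, dtype=float)
    out = methqc.eb_batch_adjust(beta, batch, cov)
    planted = (beta.iloc[:200].loc[:, sex == "F"].mean(axis=1)
               - beta.iloc[:200].loc[:, sex == "M"].mean(axis=1)).mean()
    recovered = (out.iloc[:200].loc[:, sex == "F"].mean(axis=1)
                 - out.iloc[:200].loc[:, sex == "M"].mean(axis=1)).mean()
    assert recovered == pytest.approx(planted, rel=0.05)


def test_grand_mean_preserved_on_logit_scale():
    beta, batch, _ = _batched_beta(shift=0.05)
    out = methqc.eb_batch_adjust(beta, batch)
    assert np.allclose(logit(out.to_numpy()).mean(axis=1),
                       logit(np.clip(beta.to_numpy(), 1e-6, 1 - 1e-6)).mean(axis=1),
                       atol=1e-6)


def test_singleton_batch_rejected_by_name():
    beta, batch, _ = _batched_beta(n_probes=20, n_per_batch=5)
    batch = batch.copy()
    batch.iloc[-1] = "LONE"
    with pytest.raises(ValueError, match="LONE"):
        methqc.eb_batch_adjust(beta, batch)


# ---------------------------------------------------------------------------
# gold-standard normalization

def test_reference_distribution_is_fixed_point():
    rng = np.random.default_rng(1)
    ref = np.sort(rng.uniform(0, 1, 200))
    beta = pd.DataFrame({"s0": ref.copy()}, index=[f"p{i}" for i in range(200)])
    out = methqc.normalize_to_gold_standard(beta, ref)
    assert np.allclose(out["s0"].to_numpy(), ref, atol=1e-12)


def test_output_sorted_values_are_reference_quantiles():
    rng = np.random.default_rng(2)
    ref = np.sort(rng.beta(0.5, 0.5, 500))
    beta = pd.DataFrame({"s0": rng.uniform(0, 1, 120)},
                        index=[f"p{i}" for i in range(120)])
    out = methqc.normalize_to_gold_standard(beta, ref)
    n = 120
    expected = np.interp(np.arange(n) / (n - 1), np.linspace(0, 1, 500), ref)
    assert np.allclose(np.sort(out["s0"].to_numpy()), expected, atol=1e-12)


def test_monotone_distortion_gives_identical_output():
    # two samples with identical ranks but different scales map identically
    rng = np.random.default_rng(3)
    ref = np.sort(rng.uniform(0, 1, 300))
    v = rng.uniform(0.1, 0.9, 80)
    beta = pd.DataFrame({"s0": v, "s1": v ** 2},
                        index=[f"p{i}" for i in range(80)])
    out = methqc.normalize_to_gold_standard(beta, ref)
    assert np.allclose(out["s0"].to_numpy(), out["s1"].to_numpy(), atol=1e-12)


def test_short_reference_rejected():
    with pytest.raises(ValueError, match="reference"):
        methqc.normalize_to_gold_standard(pd.DataFrame({"s": [0.5]}),
                                          np.array([0.1, 0.9]))


# ---------------------------------------------------------------------------
# PC outlier flag

def _pc_world(n=100, seed=4):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    sex = pd.Series(rng.choice(["M", "F"], n, p=[0.5, 0.5]), index=samples)
    beta = pd.DataFrame(rng.normal(0.5, 0.05, (400, n)).clip(0, 1),
                        index=[f"p{i}" for i in range(400)], columns=samples)
    return beta, sex


def test_homogeneous_cohort_rarely_flags():
    # at k=3 the two-sided normal tail gives ~0.0027 per sample per PC,
    # so ~0.5 expected false flags over 100 samples x 2 PCs
    beta, sex = _pc_world()
    assert len(methqc.pc_outlier_flag(beta, sex, k=3.0)) <= 1


def test_planted_outlier_flagged():
    beta, sex = _pc_world()
    beta.iloc[:80, 7] += 0.3  # 20% of probes shifted
    flagged = methqc.pc_outlier_flag(beta, sex, k=3.0)
    assert beta.columns[7] in flagged


def test_infinite_k_disables_flagging():
    beta, sex = _pc_world()
    beta.iloc[:80, 7] += 0.3
    assert methqc.pc_outlier_flag(beta, sex, k=np.inf) == []


def test_constant_matrix_rejected():
    beta = pd.DataFrame(0.5, index=["p0", "p1"], columns=["s0", "s1", "s2",
                                                          "s3", "s4"])
    with pytest.raises(ValueError, match="degenerate"):
        methqc.pc_outlier_flag(beta, pd.Series("F", index=beta.columns))


# ---------------------------------------------------------------------------
# pipeline order

def test_pipeline_runs_and_drops_planted_failures(small_cohort):
    m = small_cohort.methylation
    xp = [i for i in m.beta.index if i.startswith("cg_x_")]
    adjusted, report = methqc.run_qc_pipeline(m.beta, m.detection_p,
                                              m.intensity, m.samplesheet, xp,
                                              seed=1)
    reasons = [r for _, r in report.dropped_samples]
    assert reasons.count("low_intensity") == 1
    assert reasons.count("sex_discordant") == 1
    assert reasons.count("twin_dedup") == 1
    assert report.n_samples_retained == adjusted.shape[1]
    assert [s.split(":")[0] for s in report.log][:3] == [
        "probe filter", "sample filter", "twin dedup"]
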