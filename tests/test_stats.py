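"""Evaluation layer: amplitudes, TOST, 2x2 ANOVA, robustness report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from erpconsensus.sim import TimeWindow, make_montage
from erpconsensus.stats import (
    mean_amplitude,
    replicate_runs,
    rm_anova_2x2,
    tost,
    tw_accuracy,
)


# ----------------------------------------------------------- mean amplitude

def test_mean_amplitude_examples():
    montage = make_montage(4, 0)
    times = np.arange(10, dtype=float)
    X = np.full((10, 4), 2.5)
    win = TimeWindow(2.0, 7.0)
    assert mean_amplitude(X, win, montage.labels[:2], montage, times) == 2.5
    X2 = np.zeros((10, 4))
    X2[:, 0] = 1.0
    X2[:, 1] = 3.0
    assert mean_amplitude(X2, win, montage.labels[:2], montage, times) == 2.0
    ramp = np.arange(10, dtype=float)[:, None] * np.ones((1, 4))
    assert mean_amplitude(ramp, TimeWindow(0.0, 9.0), [montage.labels[0]], montage, times) == 4.5


# --------------------------------------------------------------------- TOST

def test_tost_tiny_differences_declare_equivalence(rng):
    diffs = 0.2 * rng.standard_normal(20)
    res = tost(diffs, delta=5.0)
    assert res.p1 < 1e-6 and res.p2 < 1e-6
    assert res.equivalent
    assert res.ci_low < res.mean_diff < res.ci_high


def test_tost_mean_at_margin_gives_half():
    diffs = np.array([4.0, 6.0, 5.0, 5.0, 4.5, 5.5])  # mean exactly delta
    res = tost(diffs, delta=5.0)
    assert res.p2 == pytest.approx(0.5)


def test_tost_matches_reference_t_distribution():
    """p values equal direct t CDF evaluation on a fixed sample."""
    rng = np.random.default_rng(42)
    diffs = 2.2 + 1.8 * rng.standard_normal(20)
    res = tost(diffs, delta=5.0)
    mean, s = diffs.mean(), diffs.std(ddof=1)
    se = s / np.sqrt(20)
    assert res.p1 == pytest.approx(sps.t.sf((mean + 5) / se, 19))
    assert res.p2 == pytest.approx(sps.t.cdf((mean - 5) / se, 19))
    # 90 % CI
    tcrit = sps.t.ppf(0.95, 19)
    assert res.ci_low == pytest.approx(mean - tcrit * se)
    assert res.ci_high == pytest.approx(mean + tcrit * se)


def test_tost_zero_variance_conventions():
    inside = tost(np.zeros(5), delta=5.0)
    assert inside.p1 == inside.p2 == 0.0
    outside = tost(np.full(5, 9.0), delta=5.0)
    assert outside.p1 == outside.p2 == 1.0


# -------------------------------------------------------------------- ANOVA

def test_anova_identical_columns_no_effect():
    A = np.tile(np.arange(8, dtype=float)[:, None], (1, 2))
    res = rm_anova_2x2(A)
    assert res.effects["task"]["F"] == 0.0
    assert res.effects["task"]["p"] == 1.0


def test_within_anova_equals_squared_paired_t(rng):
    A = rng.standard_normal((15, 2)) + [0.0, 0.8]
    res = rm_anova_2x2(A)
    t_stat, p_t = sps.ttest_rel(A[:, 1], A[:, 0])
    assert res.effects["task"]["F"] == pytest.approx(t_stat**2)
    assert res.effects["task"]["p"] == pytest.approx(p_t)


def test_mixed_anova_matches_independent_oracle(rng):
    """Balanced mixed 2x2 F values match pingouin's implementation."""
    pingouin = pytest.importorskip("pingouin")
    n = 12
    groups = np.array(["g1"] * n + ["g2"] * n)
    A = rng.standard_normal((2 * n, 2))
    A[groups == "g2"] += 0.7          # group effect
    A[:, 1] += 0.5                    # task effect
    A[groups == "g2", 1] += 0.6       # interaction
    res = rm_anova_2x2(A, groups=groups)

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(2 * n), 2),
        "group": np.repeat(groups, 2),
        "task": ["t1", "t2"] * (2 * n),
        "y": A.ravel(),
    })
    oracle = pingouin.mixed_anova(long, dv="y", within="task", between="group",
                                  subject="subject")
    f_by_source = dict(zip(oracle["Source"], oracle["F"]))
    assert res.effects["group"]["F"] == pytest.approx(f_by_source["group"], rel=1e-6)
    assert res.effects["task"]["F"] == pytest.approx(f_by_source["task"], rel=1e-6)
    assert res.effects["group_x_task"]["F"] == pytest.approx(
        f_by_source["Interaction"], rel=1e-6
    )


def test_mixed_anova_rejects_unbalanced_groups(rng):
    A = rng.standard_normal((5, 2))
    with pytest.raises(ValueError):
        rm_anova_2x2(A, groups=np.array(["a", "a", "a", "b", "b"]))


# ---------------------------------------------------------------- accuracy

def test_tw_accuracy_exact_and_shifted():
    truth = TimeWindow(100.0, 160.0)
    step = 1000.0 / 429.0
    shifted = TimeWindow(100.0 + 2 * step, 160.0 + 2 * step)
    acc = tw_accuracy({"S1": truth, "S2": shifted, "S3": None}, truth)
    assert acc.loc["S1"].tolist() == [0.0, 0.0, 0.0]
    assert acc.loc["S2", "start_ms"] == pytest.approx(4.662, abs=1e-3)
    assert acc.loc["S2", "duration_ms"] == pytest.approx(0.0, abs=1e-9)
    assert acc.loc["S3"].isna().all()


def test_tw_accuracy_per_subject_truth():
    t1, t2 = TimeWindow(100.0, 150.0), TimeWindow(110.0, 160.0)
    est = {"S1": t1, "S2": TimeWindow(112.0, 161.0)}
    acc = tw_accuracy(est, {"S1": t1, "S2": t2})
    assert acc.loc["S1", "start_ms"] == 0.0
    assert acc.loc["S2", "start_ms"] == pytest.approx(2.0)


# --------------------------------------------------------------- robustness

def test_replicate_runs_deterministic_pipeline_has_zero_sd():
    report = replicate_runs(lambda seed: {"task": 0.01}, n_runs=5, seed=0)
    assert report.sd_p["task"] == 0.0
    assert report.mean_p["task"] == pytest.approx(0.01)
    assert len(report.seeds) == 5


def test_replicate_runs_records_per_run_values():
    report = replicate_runs(lambda seed: {"task": (seed % 7) / 10}, n_runs=8, seed=1)
    assert report.p_values.shape == (8, 1)
    assert report.sd_p["task"] > 0
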