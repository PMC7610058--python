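"""Evaluation layer: amplitude measurement, TOST, 2×2 ANOVA, robustness.

TOST (two one-sided tests) declares a mean difference equivalent to zero
when both composite nulls H0₁: μ ≤ −δ and H0₂: μ ≥ δ are rejected, i.e.
when the difference demonstrably lies inside the equivalence margin ±δ.
The repeated-measures ANOVA covers the two designs the evaluation needs: a
within-only two-level task factor, and a mixed 2×2 with a between-subject
group factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sim import Montage, TimeWindow

logger = logging.getLogger(__name__)

__all__ = [
    "mean_amplitude",
    "TostResult",
    "tost",
    "AnovaResult",
    "rm_anova_2x2",
    "tw_accuracy",
    "RobustnessReport",
    "replicate_runs",
]


def mean_amplitude(
    condition_matrix: np.ndarray,
    window: TimeWindow,
    electrodes,
    montage: Montage,
    times_ms: np.ndarray,
) -> float:
    """Mean voltage (µV) over a window's samples at the named electrodes."""
    X = np.asarray(condition_matrix, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    cols = [montage.index(e) for e in electrodes]
    rows = np.where((times_ms >= window.start_ms - 1e-9) & (times_ms <= window.end_ms + 1e-9))[0]
    if rows.size == 0:
        raise ValueError("window contains no samples of the epoch")
    return float(X[np.ix_(rows, cols)].mean())


@dataclass
class TostResult:
    """Two one-sided equivalence tests on a sample of differences."""

    p1: float  # H0₁: μ ≤ −δ
    p2: float  # H0₂: μ ≥ +δ
    mean_diff: float
    ci_low: float  # 90 % CI of the mean difference
    ci_high: float
    n: int
    delta: float
    alpha: float = 0.05

    @property
    def equivalent(self) -> bool:
        return max(self.p1, self.p2) < self.alpha

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "mean_diff": self.mean_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "delta": self.delta,
            "equivalent": self.equivalent,
        }


def tost(diffs, delta: float = 5.0, alpha: float = 0.05) -> TostResult:
    """Schuirmann TOST via two one-sample t tests on the differences.

    ``t₁ = (mean + δ)/(s/√n)`` against the upper tail and
    ``t₂ = (mean − δ)/(s/√n)`` against the lower tail, df = n − 1; the
    companion 90 % CI of the mean difference is returned (equivalence holds
    when it lies inside ±δ, mirroring max(p1, p2) < α at α = 0.05).
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 differences")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    mean = float(diffs.mean())
    s = float(diffs.std(ddof=1))
    df = n - 1
    if s == 0:
        if abs(mean) < delta:
            logger.info("zero-variance differences inside the margin; p values set to 0")
            p1 = p2 = 0.0
        else:
            p1 = p2 = 1.0
        return TostResult(p1, p2, mean, mean, mean, n, delta, alpha)
    se = s / np.sqrt(n)
    t1 = (mean + delta) / se
    t2 = (mean - delta) / se
    p1 = float(sps.t.sf(t1, df))
    p2 = float(sps.t.cdf(t2, df))
    tcrit = float(sps.t.ppf(1 - alpha, df))  # 90 % CI at alpha = 0.05
    return TostResult(
        p1=p1,
        p2=p2,
        mean_diff=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        n=n,
        delta=delta,
        alpha=alpha,
    )


@dataclass
class AnovaResult:
    """F tests for a 2-level repeated-measures or mixed 2×2 design."""

    design: str  # "within" or "mixed"
    effects: dict[str, dict[str, float]]  # effect -> {F, df1, df2, p}

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]


def rm_anova_2x2(amplitudes, groups=None) -> AnovaResult:
    """Repeated-measures ANOVA on a subjects × 2-task table.

    Without ``groups``: within-subject task effect only (its F equals the
    squared paired t).  With ``groups`` (two labels, equal group sizes):
    mixed 2×2 with group (between), task (within) and their interaction via
    the standard partitioned sums of squares for a balanced design.
    """
    A = np.asarray(
        amplitudes.values if isinstance(amplitudes, pd.DataFrame) else amplitudes, dtype=float
    )
    if A.ndim != 2 or A.shape[1] != 2:
        raise ValueError("amplitudes must be (n_subjects, 2): two task levels")
    if np.isnan(A).any():
        keep = ~np.isnan(A).any(axis=1)
        logger.info("dropping %d subjects with missing amplitudes", int((~keep).sum()))
        A = A[keep]
        if groups is not None:
            groups = np.asarray(groups)[keep]
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    grand = A.mean()

    if groups is None:
        subj_means = A.mean(axis=1)
        task_means = A.mean(axis=0)
        ss_task = n * float(np.sum((task_means - grand) ** 2))
        resid = A - subj_means[:, None] - task_means[None, :] + grand
        ss_err = float(np.sum(resid**2))
        df1, df2 = 1, n - 1
        F = np.inf if ss_err == 0 and ss_task > 0 else (
            0.0 if ss_task == 0 else (ss_task / df1) / (ss_err / df2)
        )
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        return AnovaResult(
            design="within", effects={"task": {"F": float(F), "df1": df1, "df2": df2, "p": p}}
        )

    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("mixed design needs exactly two groups")
    n_per = [int(np.sum(groups == g)) for g in levels]
    if n_per[0] != n_per[1]:
        raise ValueError("mixed 2x2 requires equal group sizes (balanced design)")
    ng = n_per[0]
    N = n

    subj_means = A.mean(axis=1)
    group_means = np.array([A[groups == g].mean() for g in levels])
    task_means = A.mean(axis=0)
    cell_means = np.array([[A[groups == g][:, t].mean() for t in range(2)] for g in levels])

    ss_between_subj = 2 * float(np.sum((subj_means - grand) ** 2))
    ss_group = 2 * ng * float(np.sum((group_means - grand) ** 2))
    ss_subj_within = ss_between_subj - ss_group
    ss_task = N * float(np.sum((task_means - grand) ** 2))
    ss_cells = ng * float(np.sum((cell_means - grand) ** 2))
    ss_inter = ss_cells - ss_group - ss_task
    ss_within_total = float(np.sum((A - subj_means[:, None]) ** 2))
    ss_err_within = ss_within_total - ss_task - ss_inter

    df_between_err = N - 2
    df_within_err = N - 2

    def ftest(ss_effect, ss_error, df_err):
        if ss_error <= 1e-300:
            F = np.inf if ss_effect > 0 else 0.0
        else:
            F = (ss_effect / 1) / (ss_error / df_err)
        F = max(F, 0.0)
        p = float(sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        return {"F": float(F), "df1": 1, "df2": df_err, "p": p}

    return AnovaResult(
        design="mixed",
        effects={
            "group": ftest(ss_group, ss_subj_within, df_between_err),
            "task": ftest(ss_task, ss_err_within, df_within_err),
            "group_x_task": ftest(ss_inter, ss_err_within, df_within_err),
        },
    )


def tw_accuracy(estimated, truth) -> pd.DataFrame:
    """Signed per-subject differences (ms) between estimated and true windows.

    ``estimated`` maps subject id → :class:`TimeWindow` or ``None`` (missing
    windows are recorded as NaN and logged); ``truth`` is either one
    :class:`TimeWindow` shared by all subjects or a per-subject mapping
    (e.g. each subject's own jitter-shifted true window).  Columns are the
    start, end and duration differences, inputs to :func:`tost`.
    """
    rows = {}
    for sid, win in estimated.items():
        ref = truth.get(sid) if isinstance(truth, dict) else truth
        if win is None or ref is None:
            logger.info("subject %s has no detected window; recorded as missing", sid)
            rows[sid] = (np.nan, np.nan, np.nan)
        else:
            rows[sid] = (
                win.start_ms - ref.start_ms,
                win.end_ms - ref.end_ms,
                win.duration_ms - ref.duration_ms,
            )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["start_ms", "end_ms", "duration_ms"]
    )


@dataclass
class RobustnessReport:
    """Mean and SD of per-effect p values over repeated pipeline runs."""

    n_runs: int
    seeds: list[int]
    p_values: pd.DataFrame  # runs × effects
    mean_p: dict[str, float]
    sd_p: dict[str, float]


def replicate_runs(run_fn, n_runs: int = 50, seed: int = 0) -> RobustnessReport:
    """Re-run a pipeline with derived seeds and summarize p-value stability.

    ``run_fn(seed) -> {effect: p}`` executes one full pipeline run; the
    report carries the per-run p values, their mean and standard deviation
    per effect, and the seeds used (so any run can be reproduced).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_runs)
    ]
    records = []
    for s in seeds:
        records.append(run_fn(s))
    table = pd.DataFrame.from_records(records)
    return RobustnessReport(
        n_runs=n_runs,
        seeds=seeds,
        p_values=table,
        mean_p={c: float(table[c].mean()) for c in table.columns},
        sd_p={c: float(table[c].std(ddof=1)) if n_runs > 1 else 0.0 for c in table.columns},
    )
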