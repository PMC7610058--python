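"""End-to-end orchestration: simulate/read → select → consensus → windows → stats.

One call runs the whole method: benchmark-based method selection,
stabilized two-level (subject → group) consensus clustering, per-condition
time-window detection for each target component, and the evaluation layer
(per-subject window accuracy, TOST equivalence, repeated-measures ANOVA on
mean amplitudes).  Every stage derives its randomness from the single
master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusterers import METHOD_NAMES, MethodParams, Partition, run_base
from .ensemble import (
    GroupFit,
    SelectionReport,
    _sub_seed,
    fit_group,
    select_methods,
)
from .sim import NoWindowError, StudySet, TimeWindow, measurement_electrodes
from .stats import (
    AnovaResult,
    RobustnessReport,
    TostResult,
    mean_amplitude,
    replicate_runs,
    rm_anova_2x2,
    tost,
    tw_accuracy,
)
from .timewin import WindowResult, detect_window, smooth_labels

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentTarget",
    "PipelineConfig",
    "EvalReport",
    "run_pipeline",
    "replicate_pipeline",
    "default_targets",
]


@dataclass(frozen=True)
class ComponentTarget:
    """An ERP of interest: its experimental interval and measurement sites."""

    name: str
    interval_ms: tuple[float, float]
    electrodes: tuple[str, ...]


@dataclass
class PipelineConfig:
    """Parameters of the full pipeline; defaults follow the stock study."""

    k: int = 7
    candidates: tuple[str, ...] = METHOD_NAMES
    benchmark: str = "modified_kmeans"
    sim_threshold: float = 0.8
    majority: float = 0.5
    Mr: int = 20
    tau: float = 0.90
    eps: float = 0.03
    innsim_min: float = 0.90
    min_dur_ms: float = 60.0
    min_overlap: float = 1.0 / 3.0
    delta_ms: float = 5.0
    alpha: float = 0.05
    restarts: int = 5
    min_segment: int = 3  # samples; temporal smoothing of partitions (0 = off)
    seed: int = 0
    targets: dict[str, ComponentTarget] = field(default_factory=dict)

    def method_params(self, name: str) -> MethodParams:
        return MethodParams(method=name, restarts=self.restarts)


def default_targets(spec) -> dict[str, ComponentTarget]:
    """N2 and P3 targets for the stock study: definition interval + sites."""
    targets = {}
    for comps in spec.conditions.values():
        for c in comps:
            if c.name in ("N2", "P3") and c.name not in targets:
                targets[c.name] = ComponentTarget(
                    name=c.name,
                    interval_ms=c.support,
                    electrodes=tuple(measurement_electrodes(spec, c.name, n=2)),
                )
    return targets


@dataclass
class EvalReport:
    """Bundle of everything one pipeline run produced."""

    config: PipelineConfig
    selection: SelectionReport
    fit: GroupFit
    group_windows: dict[str, dict[str, WindowResult | None]]  # cond -> comp -> result
    subject_windows: dict[str, dict[str, dict[str, TimeWindow | None]]]
    # comp -> cond -> subject id -> window
    accuracy: dict[str, dict[str, pd.DataFrame]]  # comp -> cond -> per-subject diffs
    tost_results: dict[str, dict[str, dict[str, TostResult]]]
    # comp -> cond -> property -> TOST
    amplitudes: dict[str, pd.DataFrame]  # comp -> subjects x conditions (µV)
    anova: dict[str, AnovaResult | None]  # comp -> ANOVA on mean amplitudes

    def tost_table(self) -> pd.DataFrame:
        """Flat table of the TOST results (component, condition, property)."""
        rows = []
        for comp, by_cond in self.tost_results.items():
            for cond, by_prop in by_cond.items():
                for prop, res in by_prop.items():
                    rows.append(
                        {
                            "component": comp,
                            "condition": cond,
                            "criterion": prop,
                            **res.to_dict(),
                        }
                    )
        return pd.DataFrame(rows)

    def windows_table(self) -> pd.DataFrame:
        rows = []
        for cond, by_comp in self.group_windows.items():
            for comp, res in by_comp.items():
                if res is None:
                    continue
                rows.append(res.to_dict())
        return pd.DataFrame(rows)


def _detect_or_none(partition, X, target, cond, study, config, level, who):
    try:
        return detect_window(
            partition,
            X,
            target.interval_ms,
            condition=cond,
            study=study,
            innsim_min=config.innsim_min,
            min_dur_ms=config.min_dur_ms,
            min_overlap=config.min_overlap,
            component=target.name,
        )
    except NoWindowError as exc:
        logger.info("%s-level window for %s/%s (%s) not found: %s", level, target.name, cond, who, exc)
        return None


def _condition_slices(study) -> list[slice]:
    return [study.condition_slice(c) for c in study.condition_order]


def _smoothed(partition, X, study, config):
    return smooth_labels(
        partition, X, min_segment=config.min_segment, slices=_condition_slices(study)
    )


def _group_windows(fit, study, config) -> dict[str, dict[str, WindowResult | None]]:
    ga = study.grand_average_concatenated()
    part = _smoothed(fit.group_partition, ga, study, config)
    return {
        cond: {
            name: _detect_or_none(
                part, ga, tgt, cond, study, config, "group", "grand average"
            )
            for name, tgt in config.targets.items()
        }
        for cond in study.condition_order
    }


def _subject_windows(fit, study, config):
    smoothed = [
        _smoothed(fit.subject_partitions[i], study.concatenated(i), study, config)
        for i in range(study.n_subjects)
    ]
    out: dict[str, dict[str, dict[str, TimeWindow | None]]] = {}
    for name, tgt in config.targets.items():
        out[name] = {}
        for cond in study.condition_order:
            per_subj: dict[str, TimeWindow | None] = {}
            for i, subj in enumerate(study.subjects):
                res = _detect_or_none(
                    smoothed[i],
                    study.concatenated(i),
                    tgt,
                    cond,
                    study,
                    config,
                    "subject",
                    subj.subject_id,
                )
                per_subj[subj.subject_id] = res.window if res else None
            out[name][cond] = per_subj
    return out


def _amplitude_table(study, windows_by_cond, target) -> pd.DataFrame | None:
    """Subjects × conditions mean amplitude in the group windows."""
    cols = {}
    for cond in study.condition_order:
        res = windows_by_cond[cond].get(target.name)
        if res is None:
            return None
        cols[cond] = [
            mean_amplitude(
                subj.conditions[cond],
                res.window,
                target.electrodes,
                study.montage,
                study.times_ms,
            )
            for subj in study.subjects
        ]
    return pd.DataFrame(cols, index=[s.subject_id for s in study.subjects])


def run_pipeline(study: StudySet, config: PipelineConfig) -> EvalReport:
    """Run selection, two-level consensus, window detection and evaluation."""
    if not config.targets:
        raise ValueError("config.targets is empty: nothing to detect")
    seed = config.seed
    cand = [config.method_params(m) for m in config.candidates]
    selection = select_methods(
        study,
        config.k,
        cand,
        benchmark=config.method_params(config.benchmark),
        sim_threshold=config.sim_threshold,
        majority=config.majority,
        seed=_sub_seed(seed, 1),
        Mr=config.Mr,
        tau=config.tau,
        eps=config.eps,
    )
    methods = [config.method_params(m) for m in selection.selected]
    fit = fit_group(
        study,
        config.k,
        methods,
        seed=_sub_seed(seed, 2),
        r_by_method=selection.r_opt,
    )

    group_windows = _group_windows(fit, study, config)
    subject_windows = _subject_windows(fit, study, config)

    accuracy: dict[str, dict[str, pd.DataFrame]] = {}
    tost_results: dict[str, dict[str, dict[str, TostResult]]] = {}
    for name in config.targets:
        accuracy[name] = {}
        tost_results[name] = {}
        for cond in study.condition_order:
            truth = study.ground_truth.get(cond, {}).get(name)
            if truth is None:
                continue
            # individual-level reference: each subject's own true window
            # (includes that subject's latency jitter) when recorded
            subj_truth = {
                s.subject_id: s.ground_truth.get(cond, {}).get(name, truth)
                for s in study.subjects
            }
            acc = tw_accuracy(subject_windows[name][cond], subj_truth)
            accuracy[name][cond] = acc
            tost_results[name][cond] = {}
            for prop in ("start_ms", "end_ms", "duration_ms"):
                diffs = acc[prop].dropna().to_numpy()
                if diffs.size >= 2:
                    tost_results[name][cond][prop] = tost(
                        diffs, delta=config.delta_ms, alpha=config.alpha
                    )

    amplitudes: dict[str, pd.DataFrame] = {}
    anova: dict[str, AnovaResult | None] = {}
    groups = [s.group for s in study.subjects]
    mixed = len(set(groups)) == 2
    for name, tgt in config.targets.items():
        table = _amplitude_table(study, group_windows, tgt)
        if table is None:
            amplitudes[name] = pd.DataFrame()
            anova[name] = None
            continue
        amplitudes[name] = table
        anova[name] = rm_anova_2x2(table, groups=groups if mixed else None)

    return EvalReport(
        config=config,
        selection=selection,
        fit=fit,
        group_windows=group_windows,
        subject_windows=subject_windows,
        accuracy=accuracy,
        tost_results=tost_results,
        amplitudes=amplitudes,
        anova=anova,
    )


def replicate_pipeline(
    study: StudySet,
    config: PipelineConfig,
    n_runs: int = 50,
    methods: list[str] | None = None,
    stabilize: bool = True,
    seed: int | None = None,
) -> RobustnessReport:
    """Robustness harness: rerun clustering → windows → ANOVA on fixed data.

    The clustering methods and their stabilized repeat counts are fixed once
    (from ``methods`` or a fresh selection), then ``n_runs`` re-executions
    with derived seeds re-cluster the same study; the report summarizes the
    per-effect ANOVA p values across runs.  Deterministic methods are
    computed once per subject and cached — they cannot vary across runs.
    With ``stabilize=False`` and a single stochastic method the harness
    degenerates to the plain repeated single-clusterer baseline.
    """
    seed = config.seed if seed is None else seed
    if methods is None:
        selection = select_methods(
            study,
            config.k,
            [config.method_params(m) for m in config.candidates],
            benchmark=config.method_params(config.benchmark),
            sim_threshold=config.sim_threshold,
            majority=config.majority,
            seed=_sub_seed(seed, 1),
            Mr=config.Mr,
            tau=config.tau,
            eps=config.eps,
        )
        method_params = [config.method_params(m) for m in selection.selected]
        r_by_method = selection.r_opt
    else:
        method_params = [config.method_params(m) for m in methods]
        r_by_method = {m: (config.Mr // 4 if stabilize else 1) for m in methods}
        if stabilize:
            from .ensemble import calibrate_repeats

            r_by_method = calibrate_repeats(
                study, config.k, method_params, Mr=config.Mr, tau=config.tau,
                eps=config.eps, seed=_sub_seed(seed, 1),
            )
    if not stabilize:
        r_by_method = {m.method: 1 for m in method_params}

    det = [m for m in method_params if not m.is_stochastic]
    sto = [m for m in method_params if m.is_stochastic]
    det_cache: list[list[Partition]] = [
        [run_base(m, study.concatenated(i), config.k, seed=0) for m in det]
        for i in range(study.n_subjects)
    ]

    from .ensemble import cspa, group_consensus

    def one_run(run_seed: int) -> dict[str, float]:
        subject_parts = []
        for i in range(study.n_subjects):
            X = study.concatenated(i)
            parts = list(det_cache[i])
            for j, m in enumerate(sto):
                from .ensemble import stabilized_partition

                r = r_by_method.get(m.method, 1)
                s = _sub_seed(run_seed, j, i)
                parts.append(
                    stabilized_partition(m, X, config.k, r, s)
                    if r > 1
                    else run_base(m, X, config.k, seed=s)
                )
            subject_parts.append(parts[0] if len(parts) == 1 else cspa(parts, config.k))
        group_part = group_consensus(subject_parts, config.k)
        fit = GroupFit(
            k=config.k,
            methods=[m.method for m in method_params],
            r_opt=dict(r_by_method),
            subject_partitions=subject_parts,
            group_partition=group_part,
        )
        group_windows = _group_windows(fit, study, config)
        groups = [s.group for s in study.subjects]
        mixed = len(set(groups)) == 2
        out: dict[str, float] = {}
        for name, tgt in config.targets.items():
            table = _amplitude_table(study, group_windows, tgt)
            if table is None:
                for eff in (("group", "task", "group_x_task") if mixed else ("task",)):
                    out[f"{name}:{eff}"] = np.nan
                continue
            res = rm_anova_2x2(table, groups=groups if mixed else None)
            for eff, d in res.effects.items():
                out[f"{name}:{eff}"] = d["p"]
        return out

    return replicate_runs(one_run, n_runs=n_runs, seed=seed)
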