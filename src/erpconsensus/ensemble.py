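"""Consensus clustering machinery.

Implements the Rand index, the co-association matrix, the CSPA-style
consensus function (average-linkage agglomeration of 1 − co-association),
stabilization of stochastic clusterers by consensus-over-repeats,
benchmark-based method selection, and the two-level subject → group
consensus.

Seed discipline: a single master seed is fanned out with
``numpy.random.SeedSequence`` into per-method, per-subject, per-repeat
sub-seeds, so every stage is reproducible and independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, is_valid_linkage, linkage
from scipy.spatial.distance import squareform

from .clusterers import METHOD_NAMES, MethodParams, Partition, canonical_labels, run_base

logger = logging.getLogger(__name__)

__all__ = [
    "rand_index",
    "CoAssocMatrix",
    "coassociation",
    "cspa",
    "StabilizationResult",
    "stabilize_method",
    "stabilized_partition",
    "SelectionReport",
    "select_methods",
    "subject_consensus",
    "group_consensus",
    "GroupFit",
    "fit_group",
    "choose_k",
]


def _sub_seed(master: int, *path: int) -> int:
    """Deterministic sub-seed below 2**31 derived from a master seed."""
    return int(np.random.SeedSequence([int(master), *map(int, path)]).generate_state(1)[0] % (2**31))


def rand_index(l1: np.ndarray | Partition, l2: np.ndarray | Partition) -> float:
    """Fraction of point pairs on which two partitions agree (together/apart).

    ``(N11 + N00) / (n(n−1)/2)`` with N11 the pairs co-clustered in both and
    N00 the pairs separated in both; computed from the contingency table.
    """
    a = l1.labels if isinstance(l1, Partition) else np.asarray(l1)
    b = l2.labels if isinstance(l2, Partition) else np.asarray(l2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 points")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) // 2

    n11 = int(comb2(table).sum())
    same_a = int(comb2(table.sum(axis=1)).sum())
    same_b = int(comb2(table.sum(axis=0)).sum())
    total = comb2(n)
    n00 = total - same_a - same_b + n11
    return float((n11 + n00) / total)


@dataclass(frozen=True)
class CoAssocMatrix:
    """Pairwise fraction-of-partitions-together matrix over time-points."""

    matrix: np.ndarray  # (n, n), symmetric, diag 1, entries in [0, 1]
    n_partitions: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("co-association matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _label_arrays(partitions) -> list[np.ndarray]:
    arrs = [p.labels if isinstance(p, Partition) else np.asarray(p) for p in partitions]
    if not arrs:
        raise ValueError("need at least one partition")
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("partitions have unequal lengths")
    return arrs


def coassociation(partitions) -> CoAssocMatrix:
    """Entry (i, j): fraction of partitions placing i and j in one cluster."""
    arrs = _label_arrays(partitions)
    n = arrs[0].size
    acc = np.zeros((n, n))
    for a in arrs:
        acc += a[:, None] == a[None, :]
    return CoAssocMatrix(matrix=acc / len(arrs), n_partitions=len(arrs))


def cspa(partitions, k: int, min_cluster_size: int | None = None) -> Partition:
    """Consensus partition: average-linkage cut of 1 − co-association.

    Accepts a list of partitions or an already-built :class:`CoAssocMatrix`.
    Deterministic given its inputs and invariant to relabeling of the input
    partitions (only co-membership enters the evidence matrix).

    Average linkage peels extreme outliers off as micro-clusters, so a
    handful of erratic points (e.g. time-points on which the input
    partitions scatter at random) can consume cluster ids and force genuine
    clusters to merge.  When the plain cut at ``k`` yields fewer than ``k``
    clusters of at least ``min_cluster_size`` members, the dendrogram is
    cut deeper until ``k`` substantive clusters exist and the debris points
    are absorbed into the substantive cluster they co-associate with most.
    A unanimous ensemble whose clusters all reach the size floor is
    returned unchanged (idempotence).
    """
    if isinstance(partitions, CoAssocMatrix):
        ca = partitions
    else:
        ca = coassociation(partitions)
    if not 2 <= k <= ca.n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={ca.n}")
    if min_cluster_size is None:
        min_cluster_size = 2 if ca.n < 400 else 3
    D = 1.0 - ca.matrix
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    if not is_valid_linkage(Z, warning=False):
        # co-association distances are heavily tied (a few rational values);
        # scipy's NN-chain can emit an invalid tree then.  Break ties with a
        # minuscule deterministic symmetric perturbation (<< 1/n_partitions,
        # so no non-tied comparison can flip) and rebuild.
        n = D.shape[0]
        idx = np.arange(n)
        pert = 1e-9 * ((idx[:, None] * 31 + idx[None, :] * 31 + idx[:, None] * idx[None, :]) % 97) / 97.0
        pert = 0.5 * (pert + pert.T)
        np.fill_diagonal(pert, 0.0)
        Z = linkage(squareform(D + pert, checks=False), method="average")
        logger.debug("cspa: rebuilt linkage with tie-breaking perturbation")
    labels = fcluster(Z, t=k, criterion="maxclust")

    def substantive(lab):
        ids, counts = np.unique(lab, return_counts=True)
        return set(ids[counts >= min_cluster_size])

    big = substantive(labels)
    if len(big) < k:
        for k_deep in range(k + 1, ca.n + 1):
            deeper = fcluster(Z, t=k_deep, criterion="maxclust")
            if len(substantive(deeper)) >= k:
                labels, big = deeper, substantive(deeper)
                break
        else:
            big = set(np.unique(labels))  # nothing substantive: keep plain cut
        if len(big) > k:  # a deeper cut may split two at once: keep k largest
            ids, counts = np.unique(labels, return_counts=True)
            order = sorted(zip(-counts, ids))
            big = {cid for _, cid in order[:k] if cid in big}
        debris = [i for i in range(ca.n) if labels[i] not in big]
        if debris and len(big) >= 2:
            members = {c: np.where(labels == c)[0] for c in big}
            order = sorted(big)
            for i in debris:
                scores = [ca.matrix[i, members[c]].mean() for c in order]
                labels[i] = order[int(np.argmax(scores))]
            logger.debug("cspa: absorbed %d debris points into %d clusters", len(debris), len(big))
    return Partition(labels=canonical_labels(labels), k=k, method="cspa")


@dataclass
class StabilizationResult:
    """Outcome of the repeat-count stabilization of a stochastic clusterer."""

    method: str
    r_opt: int
    R_series: dict[int, float]  # r -> mutual similarity R_r, r = 2..Mr
    consensus: Partition
    converged: bool


def stabilized_partition(
    method: MethodParams | str, X: np.ndarray, k: int, r: int, seed: int
) -> Partition:
    """Consensus (CSPA) of ``r`` runs of a base method with distinct sub-seeds."""
    params = MethodParams(method=method) if isinstance(method, str) else method
    runs = [run_base(params, X, k, seed=_sub_seed(seed, i)) for i in range(r)]
    if len(runs) == 1:
        return runs[0]
    part = cspa(runs, k)
    return Partition(labels=part.labels, k=k, method=f"{params.method}+cspa{r}", seed=seed)


def stabilize_method(
    method: MethodParams | str,
    X: np.ndarray,
    k: int,
    Mr: int = 20,
    tau: float = 0.90,
    eps: float = 0.03,
    seed: int = 0,
) -> StabilizationResult:
    """Find the repeat count at which consensus-of-repeats stops changing.

    Runs the base method ``Mr`` times with distinct sub-seeds; for
    r = 2..Mr forms the consensus of the first r runs and the mutual
    similarity ``R_r`` (Rand index between consecutive consensus results).
    The chosen ``r_opt`` is the smallest r in 3..Mr−1 with
    ``max(|R_r − R_{r−1}|, |R_r − R_{r+1}|) ≤ eps`` and
    ``min(R_{r−1}, R_r, R_{r+1}) ≥ tau``; if none qualifies, ``r_opt = Mr``
    with ``converged = False``.
    """
    if Mr < 4:
        raise ValueError("Mr must be >= 4")
    params = MethodParams(method=method) if isinstance(method, str) else method
    runs = [run_base(params, X, k, seed=_sub_seed(seed, i)) for i in range(Mr)]
    n = runs[0].n
    acc = np.zeros((n, n))
    consensus_by_r: dict[int, Partition] = {}
    acc += runs[0].labels[:, None] == runs[0].labels[None, :]
    for r in range(2, Mr + 1):
        a = runs[r - 1].labels
        acc += a[:, None] == a[None, :]
        consensus_by_r[r] = cspa(CoAssocMatrix(matrix=acc / r, n_partitions=r), k)
    R = {
        r: rand_index(consensus_by_r[r], consensus_by_r[r - 1]) if r > 2
        else rand_index(consensus_by_r[2], runs[0])
        for r in range(2, Mr + 1)
    }
    r_opt, converged = Mr, False
    for r in range(3, Mr):
        stable = max(abs(R[r] - R[r - 1]), abs(R[r] - R[r + 1])) <= eps
        high = min(R[r - 1], R[r], R[r + 1]) >= tau
        if stable and high:
            r_opt, converged = r, True
            break
    if not converged:
        logger.info("stabilization of %s did not converge; using r = Mr = %d", params.method, Mr)
    return StabilizationResult(
        method=params.method,
        r_opt=r_opt,
        R_series=R,
        consensus=consensus_by_r[r_opt],
        converged=converged,
    )


@dataclass
class SelectionReport:
    """Benchmark-agreement screening of candidate clustering methods."""

    benchmark: str
    sim_threshold: float
    majority: float
    rand_by_method: dict[str, list[float]]  # method -> per-subject Rand index
    counts: dict[str, int]  # subjects with Rand >= threshold
    selected: list[str]  # methods passing the majority rule (benchmark included)
    r_opt: dict[str, int]  # stabilized repeat count per stochastic method


def _resolve_params(methods) -> list[MethodParams]:
    return [MethodParams(method=m) if isinstance(m, str) else m for m in methods]


def calibrate_repeats(
    study,
    k: int,
    methods,
    Mr: int = 20,
    tau: float = 0.90,
    eps: float = 0.03,
    seed: int = 0,
) -> dict[str, int]:
    """Stabilize each stochastic method once on the grand average; r_opt map.

    Deterministic methods are skipped (a single run is already stable) and
    get r = 1.
    """
    ga = study.grand_average_concatenated()
    out: dict[str, int] = {}
    for params in _resolve_params(methods):
        if params.is_stochastic:
            res = stabilize_method(
                params,
                ga,
                k,
                Mr=Mr,
                tau=tau,
                eps=eps,
                seed=_sub_seed(seed, 13, METHOD_NAMES.index(params.method)),
            )
            out[params.method] = res.r_opt
        else:
            out[params.method] = 1
    return out


def _subject_partition(
    params: MethodParams, X: np.ndarray, k: int, r: int, seed: int
) -> Partition:
    if params.is_stochastic and r > 1:
        return stabilized_partition(params, X, k, r, seed)
    return run_base(params, X, k, seed=seed)


def select_methods(
    study,
    k: int,
    candidates,
    benchmark: MethodParams | str = "modified_kmeans",
    sim_threshold: float = 0.8,
    majority: float = 0.5,
    seed: int = 0,
    Mr: int = 20,
    tau: float = 0.90,
    eps: float = 0.03,
) -> SelectionReport:
    """Keep candidates that agree with the benchmark on most subjects.

    Every candidate (stochastic ones stabilized at the repeat count
    calibrated on the grand average) and the benchmark cluster each
    subject's concatenated data; a candidate is selected when its Rand index
    with the benchmark reaches ``sim_threshold`` on at least a ``majority``
    fraction of subjects.  The benchmark itself is always selected.
    """
    cand = _resolve_params(candidates)
    bench = MethodParams(method=benchmark) if isinstance(benchmark, str) else benchmark
    cand = [c for c in cand if c.method != bench.method]
    r_opt = calibrate_repeats(study, k, cand + [bench], Mr=Mr, tau=tau, eps=eps, seed=seed)

    p = study.n_subjects
    rand_by_method: dict[str, list[float]] = {c.method: [] for c in cand}
    for i in range(p):
        X = study.concatenated(i)
        bench_part = _subject_partition(bench, X, k, r_opt[bench.method], _sub_seed(seed, 0, i))
        for j, c in enumerate(cand, start=1):
            part = _subject_partition(c, X, k, r_opt[c.method], _sub_seed(seed, j, i))
            rand_by_method[c.method].append(rand_index(part, bench_part))
    counts = {
        m: int(np.sum(np.asarray(vals) >= sim_threshold)) for m, vals in rand_by_method.items()
    }
    selected = [m for m, cnt in counts.items() if cnt / p >= majority]
    selected.append(bench.method)
    logger.info("method selection counts: %s; selected %s", counts, selected)
    return SelectionReport(
        benchmark=bench.method,
        sim_threshold=sim_threshold,
        majority=majority,
        rand_by_method=rand_by_method,
        counts=counts,
        selected=selected,
        r_opt=r_opt,
    )


def subject_consensus(
    X: np.ndarray,
    methods,
    k: int,
    seed: int = 0,
    r_by_method: dict[str, int] | None = None,
) -> Partition:
    """First-level consensus: CSPA over the selected methods on one subject."""
    params = _resolve_params(methods)
    if not params:
        raise ValueError("need at least one method")
    parts = []
    for j, c in enumerate(params):
        r = (r_by_method or {}).get(c.method, 1)
        parts.append(_subject_partition(c, X, k, r, _sub_seed(seed, j)))
    if len(parts) == 1:
        return parts[0]
    part = cspa(parts, k)
    return Partition(labels=part.labels, k=k, method="subject_consensus", seed=seed)


def group_consensus(subject_partitions, k: int) -> Partition:
    """Second-level consensus: CSPA over the subject-level partitions."""
    parts = _label_arrays(subject_partitions)
    if not parts:
        raise ValueError("need at least one subject partition")
    part = cspa(subject_partitions, k)
    return Partition(labels=part.labels, k=k, method="group_consensus")


@dataclass
class GroupFit:
    """Subject-level and group-level consensus partitions for one study."""

    k: int
    methods: list[str]
    r_opt: dict[str, int]
    subject_partitions: list[Partition]
    group_partition: Partition


def fit_group(
    study,
    k: int,
    methods,
    seed: int = 0,
    r_by_method: dict[str, int] | None = None,
    Mr: int = 20,
    tau: float = 0.90,
    eps: float = 0.03,
) -> GroupFit:
    """Run the two-level consensus on every subject of a study.

    ``r_by_method`` may carry repeat counts already calibrated on the grand
    average; otherwise they are calibrated here.
    """
    params = _resolve_params(methods)
    if r_by_method is None:
        r_by_method = calibrate_repeats(study, k, params, Mr=Mr, tau=tau, eps=eps, seed=seed)
    subject_parts = [
        subject_consensus(
            study.concatenated(i), params, k, seed=_sub_seed(seed, 100, i), r_by_method=r_by_method
        )
        for i in range(study.n_subjects)
    ]
    group_part = group_consensus(subject_parts, k)
    return GroupFit(
        k=k,
        methods=[c.method for c in params],
        r_opt=dict(r_by_method),
        subject_partitions=subject_parts,
        group_partition=group_part,
    )


def choose_k(
    study,
    k_range,
    intervals: dict[str, tuple[float, float]],
    methods,
    seed: int = 0,
    innsim_min: float = 0.90,
    min_dur_ms: float = 60.0,
) -> tuple[int, dict[int, float]]:
    """Scan k and keep the one whose detected windows score best.

    For each k the two-level consensus is fit and windows are detected for
    every (component interval, condition); the quality of a k is the mean of
    ``inner_similarity × overlap_fraction`` over all detected windows
    (undetected windows score 0).  Returns the arg-max k and the full trace.
    """
    from .timewin import detect_window  # local import to avoid cycle at module load

    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    trace: dict[int, float] = {}
    ga = study.grand_average_concatenated()
    for k in k_range:
        fit = fit_group(study, k, methods, seed=_sub_seed(seed, 7, k))
        scores = []
        for cond in study.condition_order:
            for comp, interval in intervals.items():
                try:
                    res = detect_window(
                        fit.group_partition,
                        ga,
                        interval,
                        condition=cond,
                        study=study,
                        innsim_min=innsim_min,
                        min_dur_ms=min_dur_ms,
                    )
                    scores.append(res.inner_similarity * res.overlap_fraction)
                except Exception:
                    scores.append(0.0)
        trace[k] = float(np.mean(scores)) if scores else 0.0
    best = max(trace, key=lambda k: (trace[k], -k))
    return best, trace
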