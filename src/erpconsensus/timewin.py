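"""Measurement time-window determination from a partition.

A cluster of time-points whose topographies are mutually very similar
(inner-similarity above threshold) and whose temporal run overlaps the
experimental measurement interval marks the period in which one ERP
component dominates the scalp field; that run, in milliseconds, is the
measurement window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clusterers import Partition
from .metrics import correlation_matrix
from .sim import NoWindowError, TimeWindow

logger = logging.getLogger(__name__)

__all__ = [
    "contiguous_runs",
    "smooth_labels",
    "inner_similarity",
    "ClusterMapStats",
    "candidate_maps",
    "detect_window",
    "WindowResult",
    "NoWindowError",
]


def contiguous_runs(labels: np.ndarray, cluster_id: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive indices carrying ``cluster_id``.

    Returns ``[first, last]`` sample-index pairs (closed), ordered in time.
    """
    mask = np.asarray(labels) == cluster_id
    if not mask.any():
        return []
    idx = np.where(mask)[0]
    breaks = np.where(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def smooth_labels(
    partition: Partition,
    X: np.ndarray,
    min_segment: int = 3,
    slices: list[slice] | None = None,
) -> Partition:
    """Temporal segment smoothing: absorb sub-threshold label runs.

    Microstate segmentations conventionally reject segments shorter than a
    few samples — isolated label flips at cluster boundaries that would
    otherwise break a contiguous map run in two.  Each run shorter than
    ``min_segment`` samples is reassigned to the neighbouring run's cluster
    whose mean topography its samples correlate with best.  Smoothing is
    applied independently inside each slice (one per condition) so segments
    never bridge a concatenation boundary.  ``min_segment`` is kept well
    below any window-duration threshold; it removes label noise, not maps.
    """
    if min_segment <= 1:
        return partition
    X = np.asarray(X, dtype=float)
    labels = partition.labels.copy()
    slices = slices or [slice(0, labels.size)]
    from .metrics import row_template_correlation

    for sl in slices:
        seg = labels[sl]
        Xs = X[sl]
        for _ in range(min_segment):  # a few passes reach a fixed point
            runs = _all_runs(seg)
            if all((b - a + 1) >= min_segment for a, b, _ in runs) or len(runs) == 1:
                break
            templates = {
                cid: Xs[seg == cid].mean(axis=0) for cid in np.unique(seg)
            }
            new = seg.copy()
            for idx, (a, b, cid) in enumerate(runs):
                if (b - a + 1) >= min_segment:
                    continue
                neighbours = []
                if idx > 0:
                    neighbours.append(runs[idx - 1][2])
                if idx + 1 < len(runs):
                    neighbours.append(runs[idx + 1][2])
                neighbours = [c for c in dict.fromkeys(neighbours) if c != cid]
                if not neighbours:
                    continue
                T = np.vstack([templates[c] for c in neighbours])
                corr = row_template_correlation(Xs[a : b + 1], T)
                for off, row in enumerate(corr):
                    new[a + off] = neighbours[int(np.argmax(row))]
            if np.array_equal(new, seg):
                break
            seg = new
        labels[sl] = seg
    return Partition(labels=labels, k=partition.k, method=partition.method + "+smooth",
                     seed=partition.seed)


def _all_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(first, last, label) for every maximal constant run, in time order."""
    breaks = np.where(np.diff(labels) != 0)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [labels.size - 1]])
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, ends)]


def inner_similarity(X: np.ndarray, indices) -> float:
    """Fisher-z-averaged pairwise spatial correlation of a set of maps.

    All pairwise spatial correlations over the index set are clipped to
    ±(1 − 1e−7), transformed with Fisher z (arctanh), averaged over the
    off-diagonal pairs, and back-transformed with tanh.  Equals the plain
    mean correlation when all pairwise correlations coincide.  A singleton
    set is degenerate and returns 1 with a warning.
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty index set")
    if indices.size == 1:
        logger.warning("inner similarity of a singleton set is degenerate; returning 1")
        return 1.0
    C = correlation_matrix(np.asarray(X, dtype=float)[indices])
    iu = np.triu_indices_from(C, k=1)
    r = np.clip(C[iu], -(1 - 1e-7), 1 - 1e-7)
    return float(np.tanh(np.mean(np.arctanh(r))))


@dataclass
class ClusterMapStats:
    """One candidate cluster map inside the experimental interval."""

    cluster_id: int
    run: tuple[int, int]  # condition-local sample indices, closed
    runs: list[tuple[int, int]]  # all runs of this cluster in the condition
    inner_similarity: float
    overlap_fraction: float
    duration_ms: float
    mean_topography: np.ndarray


def _interval_to_samples(
    interval_ms: tuple[float, float], times_ms: np.ndarray
) -> np.ndarray:
    lo, hi = interval_ms
    idx = np.where((times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9))[0]
    if idx.size == 0:
        raise ValueError(f"experimental interval [{lo}, {hi}] ms contains no samples")
    return idx


def candidate_maps(
    partition: Partition,
    X: np.ndarray,
    experimental_interval_ms: tuple[float, float],
    condition: str,
    study,
) -> list[ClusterMapStats]:
    """Candidate cluster maps: clusters whose runs touch the interval.

    Labels and data are restricted to the condition's slice of the
    concatenation; for each cluster with at least one contiguous run
    intersecting the experimental interval, its longest intersecting run is
    kept, with the inner-similarity over the run's time-points and the
    fraction of the experimental interval the run covers.
    """
    sl = study.condition_slice(condition)
    labels = partition.labels[sl]
    Xc = np.asarray(X, dtype=float)[sl]
    times = study.times_ms
    interval_idx = _interval_to_samples(experimental_interval_ms, times)
    interval_set = set(interval_idx.tolist())
    step_ms = 1000.0 / study.sfreq_hz

    out: list[ClusterMapStats] = []
    for cid in np.unique(labels):
        runs = contiguous_runs(labels, cid)
        hits = [r for r in runs if not interval_set.isdisjoint(range(r[0], r[1] + 1))]
        if not hits:
            continue
        run = max(hits, key=lambda r: (r[1] - r[0], -r[0]))  # longest, then earliest
        run_idx = np.arange(run[0], run[1] + 1)
        overlap = len(interval_set.intersection(run_idx.tolist())) / len(interval_set)
        innsim = inner_similarity(Xc, run_idx)
        out.append(
            ClusterMapStats(
                cluster_id=int(cid),
                run=run,
                runs=runs,
                inner_similarity=innsim,
                overlap_fraction=float(overlap),
                # duration as covered time: number of time-points × sample period
                duration_ms=float((run[1] - run[0] + 1) * step_ms),
                mean_topography=Xc[run_idx].mean(axis=0),
            )
        )
    return out


@dataclass
class WindowResult:
    """A detected measurement window with its provenance."""

    window: TimeWindow
    cluster_id: int
    inner_similarity: float
    overlap_fraction: float
    condition: str
    component: str | None = None
    candidates: list[ClusterMapStats] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "component": self.component,
            "cluster_id": self.cluster_id,
            "inner_similarity": float(self.inner_similarity),
            "overlap_fraction": float(self.overlap_fraction),
            **self.window.to_dict(),
        }


def detect_window(
    partition: Partition,
    X: np.ndarray,
    experimental_interval_ms: tuple[float, float],
    condition: str,
    study,
    innsim_min: float = 0.90,
    min_dur_ms: float = 60.0,
    min_overlap: float = 1.0 / 3.0,
    component: str | None = None,
    score: str = "product",
) -> WindowResult:
    """Select the best-qualifying cluster run as the measurement window.

    Candidates must reach ``innsim_min`` inner-similarity, ``min_dur_ms``
    duration and ``min_overlap`` coverage of the experimental interval
    (qualification considers inner-similarity *and* overlap: without the
    overlap floor, a neighbouring component's cluster whose run barely
    clips the interval can win whenever the target cluster narrowly fails
    a filter, which turns a near-miss into a gross misdetection instead of
    an honest no-window outcome).  Among survivors the maximizer of
    ``inner_similarity × overlap_fraction`` wins (``score="lexicographic"``
    ranks by inner-similarity first, overlap as tiebreak).  The returned
    window is the chosen run converted to ms on the epoch grid — clipped to
    the epoch, not to the experimental interval.
    """
    if not 0 < innsim_min <= 1:
        raise ValueError("innsim_min must be in (0, 1]")
    if min_dur_ms <= 0:
        raise ValueError("min_dur_ms must be > 0")
    if not 0 <= min_overlap <= 1:
        raise ValueError("min_overlap must be in [0, 1]")
    cands = candidate_maps(partition, X, experimental_interval_ms, condition, study)
    if not cands:
        raise NoWindowError(
            f"no cluster run intersects [{experimental_interval_ms[0]}, "
            f"{experimental_interval_ms[1]}] ms in {condition}"
        )
    qualifying = [
        c
        for c in cands
        if c.inner_similarity >= innsim_min
        and c.duration_ms >= min_dur_ms
        and c.overlap_fraction >= min_overlap
    ]
    if not qualifying:
        near = max(cands, key=lambda c: c.inner_similarity * c.overlap_fraction)
        raise NoWindowError(
            f"no candidate passes innsim >= {innsim_min} and duration >= "
            f"{min_dur_ms} ms in {condition}; nearest miss: cluster "
            f"{near.cluster_id} (innsim {near.inner_similarity:.3f}, "
            f"duration {near.duration_ms:.1f} ms, overlap {near.overlap_fraction:.2f})"
        )
    if score == "product":
        key = lambda c: (c.inner_similarity * c.overlap_fraction, -c.cluster_id)
    elif score == "lexicographic":
        key = lambda c: (c.inner_similarity, c.overlap_fraction, -c.cluster_id)
    else:
        raise ValueError(f"unknown score rule {score!r}")
    chosen = max(qualifying, key=key)
    times = study.times_ms
    window = TimeWindow(
        start_ms=float(times[chosen.run[0]]), end_ms=float(times[chosen.run[1]])
    )
    return WindowResult(
        window=window,
        cluster_id=chosen.cluster_id,
        inner_similarity=chosen.inner_similarity,
        overlap_fraction=chosen.overlap_fraction,
        condition=condition,
        component=component,
        candidates=cands,
    )
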