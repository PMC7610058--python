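"""Synthetic multi-subject ERP studies with known ground truth.

Builds multi-subject, multi-condition event-related-potential (ERP)
datasets from parametric components: each component is a fixed scalp
topography multiplied by a smooth raised-cosine time course, summed over
components, jittered in latency per subject, and degraded with white
Gaussian noise calibrated to a target signal-to-noise ratio.  Ground-truth
measurement windows are derived from the clean component waveforms by the
signed-area rule, so window-detection algorithms can be scored against a
known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Montage",
    "ComponentSpec",
    "StudySpec",
    "SubjectRecord",
    "StudySet",
    "TimeWindow",
    "NoWindowError",
    "make_montage",
    "nearest_channels",
    "component_topography",
    "component_waveform",
    "signed_area_window",
    "solve_area_fraction",
    "add_awgn",
    "simulate_study",
    "default_components",
    "default_study_spec",
]


class NoWindowError(RuntimeError):
    """Raised when no time window satisfying the request exists."""


@dataclass(frozen=True)
class TimeWindow:
    """A closed measurement interval in milliseconds."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms > self.end_ms:
            raise ValueError(f"start_ms {self.start_ms} > end_ms {self.end_ms}")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def to_dict(self) -> dict:
        return {
            "start_ms": float(self.start_ms),
            "end_ms": float(self.end_ms),
            "duration_ms": float(self.duration_ms),
        }


@dataclass(frozen=True)
class Montage:
    """Channel labels and 2-D positions on a unit-disc head layout."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (f, 2)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


def make_montage(f: int, seed: int = 0) -> Montage:
    """Place ``f`` uniquely labeled electrodes quasi-uniformly on the unit disc.

    Uses a sunflower (golden-angle) spiral, which is deterministic; ``seed``
    is accepted for interface symmetry with the stochastic generators and
    only rotates the spiral so distinct seeds give distinct (but equally
    uniform) layouts.
    """
    if f < 2:
        raise ValueError("montage needs at least 2 channels")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(f)
    r = np.sqrt((i + 0.5) / f)
    theta = i * golden + (seed % 360) * np.pi / 180.0
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    labels = tuple(f"E{j + 1:02d}" for j in range(f))
    return Montage(labels=labels, positions=pos)


def nearest_channels(montage: Montage, point: tuple[float, float], n: int = 2) -> list[str]:
    """Labels of the ``n`` electrodes closest to ``point`` on the layout."""
    d = np.linalg.norm(montage.positions - np.asarray(point, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")[:n]
    return [montage.labels[j] for j in order]


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: where on the scalp, when in the epoch, how strong.

    ``support`` is the (onset, offset) interval in ms inside which the
    waveform is nonzero; the raised-cosine envelope peaks at
    ``peak_latency_ms`` with amplitude ``peak_amplitude`` (µV).  The
    topography is a sum of spatial Gaussians at ``topo_centers`` with common
    width ``topo_width``, sign ``polarity``.  ``area_fraction`` is the share
    of the polarity-signed area used by :func:`signed_area_window` when this
    component's ground-truth measurement window is derived.
    """

    name: str
    polarity: int
    support: tuple[float, float]
    peak_latency_ms: float
    peak_amplitude: float
    topo_centers: tuple[tuple[float, float], ...]
    topo_width: float = 0.5
    topo_weights: tuple[float, ...] | None = None  # per-center; signs allowed
    area_fraction: float = 0.9
    background: bool = False  # ongoing-rhythm state, not an ERP: no ground truth

    def __post_init__(self) -> None:
        onset, offset = self.support
        if not onset < self.peak_latency_ms < offset:
            raise ValueError(
                f"{self.name}: need onset < peak < offset, got "
                f"{onset} / {self.peak_latency_ms} / {offset}"
            )
        if self.peak_amplitude <= 0:
            raise ValueError(f"{self.name}: peak_amplitude must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError(f"{self.name}: polarity must be +1 or -1")
        if not 0 < self.area_fraction <= 1:
            raise ValueError(f"{self.name}: area_fraction must be in (0, 1]")


def component_topography(montage: Montage, spec: ComponentSpec) -> np.ndarray:
    """Average-referenced scalp map of a component, unit maximum magnitude.

    Weighted sum of spatial Gaussians at the component's centers (signed
    weights allow dipolar fields), multiplied by its polarity,
    mean-subtracted across channels (average reference), then scaled to
    unit maximum absolute value.  Amplitude scaling is applied later, by
    the waveform.
    """
    if spec.topo_width <= 0:
        raise ValueError("topo_width must be > 0")
    weights = spec.topo_weights or (1.0,) * len(spec.topo_centers)
    if len(weights) != len(spec.topo_centers):
        raise ValueError(f"{spec.name}: one weight per topography center required")
    topo = np.zeros(montage.n_channels)
    for (cx, cy), w in zip(spec.topo_centers, weights):
        if cx * cx + cy * cy > 1.0 + 1e-9:
            raise ValueError(f"{spec.name}: topography center ({cx}, {cy}) is off the layout")
        d2 = np.sum((montage.positions - np.array([cx, cy])) ** 2, axis=1)
        topo += w * np.exp(-d2 / (2.0 * spec.topo_width**2))
    topo *= spec.polarity
    topo -= topo.mean()
    peak = np.abs(topo).max()
    if peak == 0:
        raise ValueError(f"{spec.name}: degenerate (constant) topography")
    return topo / peak


def component_waveform(spec: ComponentSpec, sfreq_hz: float, times_ms: np.ndarray) -> np.ndarray:
    """Raised-cosine envelope sampled on the epoch grid (µV, nonnegative).

    Rises as half a raised cosine from onset to peak and falls from peak to
    offset, so asymmetric supports are allowed; exactly zero outside the
    support; value ``peak_amplitude`` at the peak latency (up to the grid).
    """
    onset, offset = spec.support
    if onset < times_ms[0] - 1e-9 or offset > times_ms[-1] + 1e-9:
        raise ValueError(
            f"{spec.name}: support {spec.support} outside epoch "
            f"[{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms"
        )
    return spec.peak_amplitude * _raised_cosine(
        np.asarray(times_ms, dtype=float), onset, spec.peak_latency_ms, offset
    )


def _raised_cosine(t: np.ndarray, onset: float, peak: float, offset: float) -> np.ndarray:
    w = np.zeros_like(t)
    left = (t >= onset) & (t <= peak)
    right = (t > peak) & (t <= offset)
    w[left] = 0.5 * (1.0 + np.cos(np.pi * (t[left] - peak) / (peak - onset)))
    w[right] = 0.5 * (1.0 + np.cos(np.pi * (t[right] - peak) / (offset - peak)))
    return w


def signed_area_window(
    waveform: np.ndarray,
    polarity: int,
    search_interval_ms: tuple[float, float],
    area_fraction: float,
    times_ms: np.ndarray,
) -> TimeWindow:
    """Shortest contiguous interval holding a fraction of the signed area.

    Within ``search_interval_ms`` the waveform is flipped to the component's
    polarity; the returned window is the shortest contiguous run of samples
    whose signed-area sum reaches ``area_fraction`` of the total signed area
    in the search interval (ties broken by larger area, then earlier start).
    Window edges are the first/last sample times in ms (closed interval).
    """
    if not 0 < area_fraction <= 1:
        raise ValueError("area_fraction must be in (0, 1]")
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = search_interval_ms
    idx = np.where((times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9))[0]
    if idx.size == 0:
        raise ValueError("search interval contains no samples")
    s = polarity * np.asarray(waveform, dtype=float)[idx]
    total = s.sum()
    if s.max() <= 0 or total <= 0:
        raise NoWindowError(
            f"no deflection of polarity {polarity:+d} in "
            f"[{lo}, {hi}] ms (max signed value {s.max():.3g})"
        )
    target = area_fraction * total - 1e-12 * abs(total)
    csum = np.concatenate([[0.0], np.cumsum(s)])
    n = s.size
    for length in range(1, n + 1):
        sums = csum[length:] - csum[:-length]
        best = sums.max()
        if best >= target:
            start = int(np.argmax(sums))  # argmax → largest area, earliest start
            return TimeWindow(
                start_ms=float(times_ms[idx[start]]),
                end_ms=float(times_ms[idx[start + length - 1]]),
            )
    raise NoWindowError("signed area target unreachable")  # pragma: no cover


def solve_area_fraction(spec: ComponentSpec, target: TimeWindow) -> float:
    """Area fraction making the clean envelope's signed-area window ``target``.

    Closed form for the piecewise raised-cosine envelope: the integral of
    ``(1 + cos(pi x / h)) / 2`` from the peak out to distance ``a`` on a half
    of width ``h`` is ``(a + h/pi * sin(pi a / h)) / 2``, and each full half
    contributes ``h / 2``.
    """
    onset, offset = spec.support
    peak = spec.peak_latency_ms
    h_left, h_right = peak - onset, offset - peak

    def half_integral(a: float, h: float) -> float:
        a = min(max(a, 0.0), h)
        return 0.5 * (a + h / np.pi * np.sin(np.pi * a / h))

    total = 0.5 * (h_left + h_right)
    inside = half_integral(peak - target.start_ms, h_left) + half_integral(
        target.end_ms - peak, h_right
    )
    return float(inside / total)


# Fractions solved with solve_area_fraction so the clean N2 and P3 templates
# yield the 201–265 ms and 266–357 ms measurement windows.
N2_AREA_FRACTION = 0.8618
P3_AREA_FRACTION = 0.9207


def add_awgn(matrix: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Add white Gaussian noise at a target SNR measured on whole-matrix power.

    Noise variance is ``P_signal * 10**(-snr_db / 10)`` with ``P_signal`` the
    mean square over every entry of ``matrix`` (the dataset as a whole).
    ``snr_db = inf`` returns the input unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.isinf(snr_db):
        return matrix.copy()
    p_signal = float(np.mean(matrix**2))
    sigma = np.sqrt(p_signal * 10.0 ** (-snr_db / 10.0))
    return matrix + rng.standard_normal(matrix.shape) * sigma


@dataclass(frozen=True)
class StudySpec:
    """Full description of a synthetic multi-subject ERP study."""

    n_subjects: int
    conditions: dict[str, tuple[ComponentSpec, ...]]
    montage: Montage
    sfreq_hz: float = 429.0
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 600.0
    snr_db: float = 20.0
    # between-subject variability: each subject's whole response is scaled by
    # 1 + N(0, subject_gain_sd), and every condition after the first
    # additionally by 1 + N(0, task_gain_sd) (subject-specific effect size).
    # Whole-matrix scalings preserve all within-condition amplitude ratios,
    # so component crossovers and true windows are unaffected.
    subject_gain_sd: float = 0.0
    task_gain_sd: float = 0.0
    jitter_max_samples: int = 5
    jitter_mode: str = "shared"  # "shared": one draw per subject moves all
    # jittered components together; "per_component": independent draws
    jitter_components: tuple[str, ...] | None = None  # None -> all components
    seed: int = 0
    group_labels: tuple[str, ...] | None = None  # one per subject

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.sfreq_hz <= 0:
            raise ValueError("sfreq_hz must be > 0")
        if self.jitter_max_samples < 0:
            raise ValueError("jitter_max_samples must be >= 0")
        if self.jitter_mode not in ("shared", "per_component"):
            raise ValueError("jitter_mode must be 'shared' or 'per_component'")
        if self.subject_gain_sd < 0 or self.task_gain_sd < 0:
            raise ValueError("gain SDs must be >= 0")
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must be finite or +inf")
        if self.group_labels is not None and len(self.group_labels) != self.n_subjects:
            raise ValueError("group_labels must have one entry per subject")

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(self.conditions)

    @property
    def times_ms(self) -> np.ndarray:
        """Epoch sample grid: sample i ↦ epoch_start_ms + i / sfreq × 1000.

        The epoch covers ``epoch_end_ms − epoch_start_ms`` of signal, i.e.
        ``round(duration × sfreq / 1000)`` samples starting at the epoch
        start (so a −100…600 ms epoch at 429 Hz has 300 samples).
        """
        n_t = int(round((self.epoch_end_ms - self.epoch_start_ms) * self.sfreq_hz / 1000.0))
        return self.epoch_start_ms + np.arange(n_t) * (1000.0 / self.sfreq_hz)

    @property
    def n_times(self) -> int:
        return self.times_ms.size


@dataclass
class SubjectRecord:
    """One subject's per-condition epochs and their temporal concatenation."""

    subject_id: str
    group: str
    conditions: dict[str, np.ndarray]  # condition -> (n_t, f)
    ground_truth: dict[str, dict[str, "TimeWindow"]] = field(default_factory=dict)
    # condition -> component -> this subject's own (jitter-shifted) true window

    def concatenated(self, order: tuple[str, ...]) -> np.ndarray:
        return np.vstack([self.conditions[c] for c in order])


@dataclass
class StudySet:
    """A group of subjects sharing a montage, epoch grid and condition order."""

    montage: Montage
    sfreq_hz: float
    epoch_start_ms: float
    condition_order: tuple[str, ...]
    subjects: list[SubjectRecord]
    ground_truth: dict[str, dict[str, TimeWindow]] = field(default_factory=dict)
    # ground_truth[condition][component] -> TimeWindow
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {
            subj.conditions[c].shape for subj in self.subjects for c in self.condition_order
        }
        if len(shapes) > 1:
            raise ValueError(f"inconsistent condition matrix shapes: {shapes}")
        (shape,) = shapes or {(0, self.montage.n_channels)}
        if shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        self._n_t = shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_times_per_condition(self) -> int:
        return self._n_t

    @property
    def n_concat(self) -> int:
        return self._n_t * len(self.condition_order)

    @property
    def times_ms(self) -> np.ndarray:
        return self.epoch_start_ms + np.arange(self._n_t) * 1000.0 / self.sfreq_hz

    def concatenated(self, subject_index: int) -> np.ndarray:
        return self.subjects[subject_index].concatenated(self.condition_order)

    def grand_average(self) -> dict[str, np.ndarray]:
        """Per-condition mean across subjects, (n_t, f) each."""
        return {
            c: np.mean([s.conditions[c] for s in self.subjects], axis=0)
            for c in self.condition_order
        }

    def grand_average_concatenated(self) -> np.ndarray:
        ga = self.grand_average()
        return np.vstack([ga[c] for c in self.condition_order])

    def condition_slice(self, condition: str) -> slice:
        i = self.condition_order.index(condition)
        return slice(i * self._n_t, (i + 1) * self._n_t)


def _component_names(spec: StudySpec) -> list[str]:
    names: list[str] = []
    for comps in spec.conditions.values():
        for c in comps:
            if c.name not in names:
                names.append(c.name)
    return names


def _clean_condition(
    spec: StudySpec,
    comps: tuple[ComponentSpec, ...],
    jitter_ms: dict[str, float],
    times: np.ndarray,
) -> np.ndarray:
    """Noise-free (n_t, f) matrix for one condition with latency shifts applied."""
    out = np.zeros((times.size, spec.montage.n_channels))
    for comp in comps:
        shift = jitter_ms.get(comp.name, 0.0)
        onset, offset = comp.support
        onset, offset, peak = onset + shift, offset + shift, comp.peak_latency_ms + shift
        clipped = False
        if onset < times[0]:
            onset, clipped = times[0], True
        if offset > times[-1]:
            offset, clipped = times[-1], True
        if clipped and not comp.background:
            logger.warning(
                "component %s support clipped to epoch after %+.1f ms jitter",
                comp.name,
                shift,
            )
            if not onset < peak < offset:  # jitter pushed the peak outside
                peak = 0.5 * (onset + offset)
        envelope = comp.peak_amplitude * _raised_cosine(times, onset, peak, offset)
        out += np.outer(envelope, component_topography(spec.montage, comp))
    return out


def _ground_truth_windows(spec: StudySpec) -> dict[str, dict[str, TimeWindow]]:
    """Signed-area windows from the clean, jitter-free component envelopes."""
    times = spec.times_ms
    truth: dict[str, dict[str, TimeWindow]] = {}
    for cond, comps in spec.conditions.items():
        truth[cond] = {}
        for comp in comps:
            if comp.background:
                continue
            wave = comp.polarity * component_waveform(comp, spec.sfreq_hz, times)
            truth[cond][comp.name] = signed_area_window(
                wave, comp.polarity, comp.support, comp.area_fraction, times
            )
    return truth


def _subject_truth(
    spec: StudySpec, jitter_ms: dict[str, float], times: np.ndarray
) -> dict[str, dict[str, TimeWindow]]:
    """Signed-area windows on one subject's clean, jitter-shifted envelopes."""
    truth: dict[str, dict[str, TimeWindow]] = {}
    for cond, comps in spec.conditions.items():
        truth[cond] = {}
        for comp in comps:
            if comp.background:
                continue
            shift = jitter_ms.get(comp.name, 0.0)
            onset = max(comp.support[0] + shift, float(times[0]))
            offset = min(comp.support[1] + shift, float(times[-1]))
            peak = comp.peak_latency_ms + shift
            if not onset < peak < offset:
                peak = 0.5 * (onset + offset)
            wave = comp.peak_amplitude * _raised_cosine(times, onset, peak, offset)
            truth[cond][comp.name] = signed_area_window(
                comp.polarity * wave,
                comp.polarity,
                (onset, offset),
                comp.area_fraction,
                times,
            )
    return truth


def simulate_study(spec: StudySpec) -> StudySet:
    """Generate a full synthetic study, reproducible from ``spec.seed``.

    Per subject, the latency of each jittered component is shifted by an
    integer number of samples drawn uniformly from ±``jitter_max_samples``
    (in ``"shared"`` mode one draw moves all jittered components together;
    in ``"per_component"`` mode each gets an independent draw; either way
    the shift is shared across conditions); the clean topography ⊗ waveform
    sum is assembled per condition; Gaussian noise at ``snr_db`` is added
    once to the subject's concatenated dataset.  Study-level ground-truth windows
    come from the clean, jitter-free templates (identical across subjects,
    invariant to noise and jitter); each subject additionally records its
    own true windows on its jitter-shifted clean envelopes, the reference
    for individual-level accuracy.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times_ms
    comp_names = _component_names(spec)
    order = spec.condition_names
    step_ms = 1000.0 / spec.sfreq_hz

    jittered = comp_names if spec.jitter_components is None else list(spec.jitter_components)
    subjects: list[SubjectRecord] = []
    for i in range(spec.n_subjects):
        if spec.jitter_mode == "shared":
            d = int(rng.integers(-spec.jitter_max_samples, spec.jitter_max_samples + 1))
            jitter_ms = {name: d * step_ms for name in jittered}
        else:
            draws = rng.integers(
                -spec.jitter_max_samples, spec.jitter_max_samples + 1, size=len(jittered)
            )
            jitter_ms = {name: float(d) * step_ms for name, d in zip(jittered, draws)}
        subject_gain = max(1.0 + spec.subject_gain_sd * rng.standard_normal(), 0.2)
        task_gain = max(1.0 + spec.task_gain_sd * rng.standard_normal(), 0.2)
        clean = {
            cond: _clean_condition(spec, comps, jitter_ms, times)
            * subject_gain
            * (task_gain if j > 0 else 1.0)
            for j, (cond, comps) in enumerate(spec.conditions.items())
        }
        concat = np.vstack([clean[c] for c in order])
        noisy = add_awgn(concat, spec.snr_db, rng)
        n_t = times.size
        per_cond = {c: noisy[j * n_t : (j + 1) * n_t] for j, c in enumerate(order)}
        group = spec.group_labels[i] if spec.group_labels else "G1"
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:02d}",
                group=group,
                conditions=per_cond,
                ground_truth=_subject_truth(spec, jitter_ms, times),
            )
        )

    return StudySet(
        montage=spec.montage,
        sfreq_hz=spec.sfreq_hz,
        epoch_start_ms=spec.epoch_start_ms,
        condition_order=order,
        subjects=subjects,
        ground_truth=_ground_truth_windows(spec),
        seed=spec.seed,
    )


# --------------------------------------------------------------------------
# Default six-component study emulating a visual-attention design:
# P1/N1/P2/N2/P3/N4, two conditions differing in N2 and P3 strength.

# name -> (polarity, centers, width, per-center weights).  Centers, widths
# and counter-lobes keep the state maps mutually distinct (positive
# correlations well below 1; anticorrelated pairs are separated by polarity
# in the signed methods), which is what lets clustering isolate every
# component.
_TOPO = {
    # occipital positivity with weak bilateral frontal counter-lobes
    "P1": (+1, ((0.0, -0.85), (0.55, 0.5), (-0.55, 0.5)), 0.28, (1.0, -0.2, -0.2)),
    # bilateral temporo-occipital negativity with the classic anterior lobe
    "N1": (-1, ((0.72, -0.28), (-0.72, -0.28), (0.0, 0.5)), 0.26, (1.0, 1.0, 0.3)),
    # frontal positivity spreading toward right-posterior sites
    "P2": (+1, ((0.0, 0.68), (0.3, -0.45)), 0.33, (1.0, 0.35)),
    "N2": (-1, ((0.42, -0.52),), 0.38, None),  # right-posterior negativity
    "P3": (+1, ((0.0, -0.12),), 0.45, None),  # centro-parietal positivity
    "N4": (-1, ((0.0, 0.15), (0.0, 0.85)), 0.40, (1.0, -0.35)),  # central negativity
}

_TIMING = {  # name -> (onset, peak, offset) ms
    "P1": (42.0, 75.0, 108.0),
    "N1": (85.0, 120.0, 155.0),
    "P2": (140.0, 172.0, 221.0),
    "N2": (175.0, 233.0, 292.0),
    "P3": (240.0, 310.0, 385.0),
    "N4": (330.0, 412.0, 540.0),
}

_AREA_FRACTION = {"N2": N2_AREA_FRACTION, "P3": P3_AREA_FRACTION}

# µV peak amplitudes per condition; the task effect lives in N2 and P3.
_AMPLITUDES = {
    "Cond1": {"P1": 4.0, "N1": 5.0, "P2": 5.0, "N2": 5.0, "P3": 6.4, "N4": 5.5},
    "Cond2": {"P1": 4.0, "N1": 5.0, "P2": 5.0, "N2": 6.0, "P3": 7.68, "N4": 6.6},
}


# Ongoing background rhythm: one fixed scalp field present before stimulus
# onset and again once the evoked sequence has ended (event-related
# desynchronization suppresses it in between).  It gives the pre-stimulus
# and late periods a coherent topographic state of their own, as in real
# ERP data, so every epoch sample carries structured signal.  The supports
# deliberately extend beyond the epoch (the rhythm does not start or stop
# with the recording window); the generator clips them to the epoch.
_BACKGROUND = {
    "BG_pre": (-140.0, -60.0, 44.0),
    "BG_post": (535.0, 575.0, 640.0),
}
_BG_TOPO = (((-0.5, 0.45), (0.5, 0.45)), 0.30, (1.0, -1.0))  # frontal dipole
_BG_AMPLITUDE = 2.8


def default_components(condition: str = "Cond1") -> tuple[ComponentSpec, ...]:
    """The six stock ERPs (P1, N1, P2, N2, P3, N4) plus the background state."""
    amps = _AMPLITUDES[condition]
    specs = []
    for name, (onset, peak, offset) in _TIMING.items():
        polarity, centers, width, weights = _TOPO[name]
        specs.append(
            ComponentSpec(
                name=name,
                polarity=polarity,
                support=(onset, offset),
                peak_latency_ms=peak,
                peak_amplitude=amps[name],
                topo_centers=centers,
                topo_width=width,
                topo_weights=weights,
                area_fraction=_AREA_FRACTION.get(name, 0.9),
            )
        )
    centers, width, weights = _BG_TOPO
    for name, (onset, peak, offset) in _BACKGROUND.items():
        specs.append(
            ComponentSpec(
                name=name,
                polarity=1,
                support=(onset, offset),
                peak_latency_ms=peak,
                peak_amplitude=_BG_AMPLITUDE,
                topo_centers=centers,
                topo_width=width,
                topo_weights=weights,
                background=True,
            )
        )
    return tuple(specs)


def default_study_spec(
    n_subjects: int = 20,
    n_channels: int = 65,
    snr_db: float = 20.0,
    jitter_max_samples: int = 5,
    seed: int = 0,
) -> StudySpec:
    """The stock two-condition, 20-subject, 65-channel study at 429 Hz."""
    montage = make_montage(n_channels, seed=0)
    return StudySpec(
        n_subjects=n_subjects,
        conditions={
            "Cond1": default_components("Cond1"),
            "Cond2": default_components("Cond2"),
        },
        montage=montage,
        sfreq_hz=429.0,
        epoch_start_ms=-100.0,
        epoch_end_ms=600.0,
        snr_db=snr_db,
        subject_gain_sd=0.10,
        task_gain_sd=0.12,
        jitter_max_samples=jitter_max_samples,
        # inter-subject latency variability: one per-subject shift of the signal
        jitter_mode="shared",
        jitter_components=None,
        seed=seed,
    )


def measurement_electrodes(spec: StudySpec, component: str, n: int = 2) -> list[str]:
    """Electrodes nearest a component's main topographic center."""
    _, centers, _, _ = _TOPO.get(component, (None, None, None, None))
    if centers is None:
        for comps in spec.conditions.values():
            for c in comps:
                if c.name == component:
                    centers = c.topo_centers
        if centers is None:
            raise KeyError(f"unknown component {component!r}")
    return nearest_channels(spec.montage, centers[0], n=n)
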