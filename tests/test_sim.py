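"""Synthetic-study generator: montage, components, signed area, noise."""

import numpy as np
import pytest

from erpconsensus.sim import (
    ComponentSpec,
    NoWindowError,
    TimeWindow,
    add_awgn,
    component_topography,
    component_waveform,
    default_components,
    default_study_spec,
    make_montage,
    signed_area_window,
    simulate_study,
    solve_area_fraction,
)


# ------------------------------------------------------------------ montage

def test_montage_full_size_unique_positions():
    m = make_montage(65, 0)
    assert m.n_channels == 65
    assert len(set(m.labels)) == 65
    d = np.linalg.norm(m.positions[:, None] - m.positions[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() > 1e-3  # all pairwise positions distinct
    assert np.all(np.linalg.norm(m.positions, axis=1) <= 1.0 + 1e-9)


def test_montage_minimum_and_determinism():
    assert make_montage(2, 0).n_channels == 2
    a, b = make_montage(65, 0), make_montage(65, 0)
    np.testing.assert_array_equal(a.positions, b.positions)
    with pytest.raises(ValueError):
        make_montage(1, 0)


# --------------------------------------------------------------- topography

def _spec(**kw):
    base = dict(
        name="X", polarity=1, support=(100.0, 200.0), peak_latency_ms=150.0,
        peak_amplitude=5.0, topo_centers=((0.0, -0.5),), topo_width=0.4,
    )
    base.update(kw)
    return ComponentSpec(**base)


def test_topography_average_reference_and_normalization():
    m = make_montage(65, 0)
    t = component_topography(m, _spec())
    assert abs(t.mean()) < 1e-12
    assert np.isclose(np.abs(t).max(), 1.0)


def test_topography_polarity_sign_symmetry():
    m = make_montage(65, 0)
    tp = component_topography(m, _spec(polarity=1))
    tn = component_topography(m, _spec(polarity=-1))
    np.testing.assert_allclose(tn, -tp)


def test_topography_dipolar_differs_from_single_lobe():
    m = make_montage(65, 0)
    single = component_topography(m, _spec())
    dipole = component_topography(
        m, _spec(topo_centers=((0.0, -0.5), (0.0, 0.5)), topo_weights=(1.0, -1.0))
    )
    r = np.corrcoef(single, dipole)[0, 1]
    assert r < 1.0 - 1e-6


def test_topography_off_layout_center_rejected():
    m = make_montage(16, 0)
    with pytest.raises(ValueError):
        component_topography(m, _spec(topo_centers=((1.4, 0.0),)))


# ----------------------------------------------------------------- waveform

def test_waveform_support_and_peak():
    spec = default_study_spec(n_subjects=1)
    times = spec.times_ms
    n2 = next(c for c in default_components("Cond1") if c.name == "N2")
    w = component_waveform(n2, spec.sfreq_hz, times)
    inside = (times >= 175.0) & (times <= 292.0)
    assert np.all(w[~inside] == 0.0)
    assert np.any(w[inside] > 0.0)
    # peak sample carries (almost) the full amplitude despite the grid
    assert w.max() == pytest.approx(n2.peak_amplitude, rel=1e-3)


def test_waveform_closed_form_integral():
    # raised cosine of width w and height h integrates to h*w/2
    spec = _spec(support=(0.0, 80.0), peak_latency_ms=40.0, peak_amplitude=2.0)
    times = np.linspace(-10, 100, 20001)
    w = component_waveform(spec, 429.0, times)
    integral = np.trapezoid(w, times)
    assert integral == pytest.approx(2.0 * 80.0 / 2.0, rel=1e-4)


def test_waveform_support_outside_epoch_rejected():
    spec = _spec(support=(-300.0, 100.0), peak_latency_ms=-50.0)
    with pytest.raises(ValueError):
        component_waveform(spec, 429.0, np.linspace(-100, 600, 301))


# -------------------------------------------------------------- signed area

def test_signed_area_rectangle_full_fraction():
    times = np.arange(0.0, 100.0, 1.0)
    wave = np.where((times >= 20) & (times <= 60), -1.0, 0.0)
    win = signed_area_window(wave, -1, (0, 99), 1.0, times)
    assert (win.start_ms, win.end_ms) == (20.0, 60.0)


def test_signed_area_symmetric_about_peak():
    spec = _spec(support=(100.0, 200.0), peak_latency_ms=150.0)
    times = np.arange(0.0, 300.0, 1.0)
    wave = component_waveform(spec, 1000.0, times)
    win = signed_area_window(wave, 1, (100, 200), 0.8, times)
    assert win.start_ms + win.end_ms == pytest.approx(2 * 150.0, abs=1.0)


def test_signed_area_wrong_polarity_raises():
    times = np.arange(0.0, 50.0, 1.0)
    with pytest.raises(NoWindowError):
        signed_area_window(np.ones_like(times), -1, (0, 49), 0.5, times)


def _brute_force_window(wave, polarity, idx, fraction, times):
    s = polarity * wave[idx]
    target = fraction * s.sum() - 1e-12 * abs(s.sum())
    best = None
    n = len(s)
    for i in range(n):
        acc = 0.0
        for j in range(i, n):
            acc += s[j]
            if acc >= target:
                cand = (j - i, -acc, i)
                if best is None or cand < best:
                    best = cand
    length, neg_area, i = best
    return times[idx[i]], times[idx[i + length]]


@pytest.mark.parametrize("trial", range(8))
def test_signed_area_matches_exhaustive_scan(trial):
    """The production window equals an O(n^2) scan over all intervals."""
    rng = np.random.default_rng(100 + trial)
    n = 80
    times = np.arange(n, dtype=float)
    # smooth unimodal positive bump with noise floor, random placement
    center = rng.uniform(20, 60)
    width = rng.uniform(8, 18)
    wave = np.exp(-0.5 * ((times - center) / width) ** 2) + 0.01 * rng.standard_normal(n)
    fraction = rng.uniform(0.3, 0.95)
    idx = np.arange(n)
    win = signed_area_window(wave, 1, (0, n - 1), fraction, times)
    bs, be = _brute_force_window(wave, 1, idx, fraction, times)
    assert (win.start_ms, win.end_ms) == (bs, be)


def test_printed_measurement_windows_from_clean_templates():
    """Clean N2 and P3 templates yield the documented measurement windows."""
    spec = default_study_spec(n_subjects=1)
    times = spec.times_ms
    step = 1000.0 / spec.sfreq_hz
    for name, (lo, hi) in (("N2", (201.0, 265.0)), ("P3", (266.0, 357.0))):
        comp = next(c for c in default_components("Cond1") if c.name == name)
        wave = comp.polarity * component_waveform(comp, spec.sfreq_hz, times)
        win = signed_area_window(wave, comp.polarity, comp.support, comp.area_fraction, times)
        assert abs(win.start_ms - lo) <= step
        assert abs(win.end_ms - hi) <= step


def test_area_fractions_solve_the_printed_windows():
    """The frozen per-component fractions agree with the closed form."""
    for name, target in (("N2", TimeWindow(201.0, 265.0)), ("P3", TimeWindow(266.0, 357.0))):
        comp = next(c for c in default_components("Cond1") if c.name == name)
        solved = solve_area_fraction(comp, target)
        assert comp.area_fraction == pytest.approx(solved, abs=5e-4)


# -------------------------------------------------------------------- noise

def test_awgn_infinite_snr_is_identity(rng):
    x = rng.standard_normal((50, 8))
    np.testing.assert_array_equal(add_awgn(x, np.inf, rng), x)


def test_awgn_variance_calibration(rng):
    x = rng.standard_normal((400, 50))  # unit power
    noisy = add_awgn(x, 20.0, rng)
    resid = noisy - x
    assert np.var(resid) == pytest.approx(0.01 * np.mean(x**2), rel=0.05)


def test_awgn_zero_db_noise_equals_signal_power(rng):
    x = 2.0 * rng.standard_normal((300, 60))
    resid = add_awgn(x, 0.0, rng) - x
    assert np.mean(resid**2) == pytest.approx(np.mean(x**2), rel=0.05)


# ------------------------------------------------------------ whole studies

def test_study_concatenation_is_600_by_65(full_study):
    assert full_study.concatenated(0).shape == (600, 65)
    assert full_study.n_subjects == 20


def test_simulation_is_deterministic():
    spec = default_study_spec(n_subjects=3, n_channels=16, seed=11)
    a, b = simulate_study(spec), simulate_study(spec)
    for sa, sb in zip(a.subjects, b.subjects):
        for cond in a.condition_order:
            np.testing.assert_array_equal(sa.conditions[cond], sb.conditions[cond])


def test_noiseless_zero_jitter_subjects_equal_templates():
    from dataclasses import replace

    spec = replace(
        default_study_spec(n_subjects=3, n_channels=16, snr_db=np.inf,
                           jitter_max_samples=0, seed=2),
        subject_gain_sd=0.0, task_gain_sd=0.0,
    )
    study = simulate_study(spec)
    ref = study.subjects[0]
    for subj in study.subjects[1:]:
        for cond in study.condition_order:
            np.testing.assert_allclose(subj.conditions[cond], ref.conditions[cond])


def test_empirical_snr_within_half_db():
    from dataclasses import replace

    # gains off so the clean and noisy runs consume identical random draws
    def spec(snr):
        return replace(
            default_study_spec(n_subjects=3, seed=4, snr_db=snr, jitter_max_samples=0),
            subject_gain_sd=0.0, task_gain_sd=0.0,
        )

    clean = simulate_study(spec(np.inf))
    noisy = simulate_study(spec(20.0))
    for sc, sn in zip(clean.subjects, noisy.subjects):
        x = np.vstack([sc.conditions[c] for c in clean.condition_order])
        y = np.vstack([sn.conditions[c] for c in noisy.condition_order])
        snr = 10 * np.log10(np.mean(x**2) / np.mean((y - x) ** 2))
        assert abs(snr - 20.0) < 0.5


def test_ground_truth_invariant_to_noise_and_jitter():
    base = simulate_study(default_study_spec(n_subjects=2, seed=5))
    quiet = simulate_study(default_study_spec(n_subjects=2, seed=6, snr_db=np.inf,
                                              jitter_max_samples=0))
    for cond in base.condition_order:
        for comp, tw in base.ground_truth[cond].items():
            other = quiet.ground_truth[cond][comp]
            assert (tw.start_ms, tw.end_ms) == (other.start_ms, other.end_ms)


def test_subject_truth_tracks_latency_shift():
    """Per-subject true windows are the study truth shifted by the jitter."""
    study = simulate_study(default_study_spec(n_subjects=8, seed=9))
    step = 1000.0 / study.sfreq_hz
    for subj in study.subjects:
        for cond in study.condition_order:
            shift = (subj.ground_truth[cond]["N2"].start_ms
                     - study.ground_truth[cond]["N2"].start_ms)
            # integer number of samples, bounded by the configured maximum
            assert abs(shift / step - round(shift / step)) < 1e-6
            assert abs(shift) <= 5 * step + 1e-9
            # whole-signal shift: P3 moves by the same amount
            p3_shift = (subj.ground_truth[cond]["P3"].start_ms
                        - study.ground_truth[cond]["P3"].start_ms)
            assert p3_shift == pytest.approx(shift, abs=1e-9)
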