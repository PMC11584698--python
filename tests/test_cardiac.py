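"""ECG delineation, phase labelling, cycle angles, artifact regression."""

import numpy as np
import pytest

from cardiomotor import (CardiacEvents, cue_angle, delineate, detect_r_peaks,
                         detect_t_offsets, label_cue_phase, preprocess_ecg,
                         regress_cardiac_artifact, SimulationConfig,
                         simulate_ecg)

FS = 250.0


@pytest.fixture(scope="module")
def clean_ecg():
    cfg = SimulationConfig(n_trials_left=10, n_trials_right=10, seed=5)
    ecg, truth = simulate_ecg(cfg)
    return ecg, truth, cfg


# --- preprocessing ---------------------------------------------------------

def test_bandpass_removes_dc(clean_ecg):
    ecg, _, cfg = clean_ecg
    shifted = ecg + 5.0
    out = preprocess_ecg(shifted, cfg.sampling_rate)
    assert abs(out.mean()) < 0.05


def test_bandpass_attenuates_50hz(clean_ecg):
    ecg, _, cfg = clean_ecg
    t = np.arange(ecg.size) / cfg.sampling_rate
    noisy = ecg + np.sin(2 * np.pi * 50.0 * t)
    out = preprocess_ecg(noisy, cfg.sampling_rate)

    def power_at(x, f):
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, 1 / cfg.sampling_rate)
        sel = np.abs(freqs - f) < 0.5
        return np.sum(np.abs(spec[sel]) ** 2)

    assert power_at(out, 50.0) < 0.1 * power_at(noisy, 50.0)


def test_bandpass_idempotent_in_passband(clean_ecg):
    ecg, _, cfg = clean_ecg
    once = preprocess_ecg(ecg, cfg.sampling_rate)
    twice = preprocess_ecg(once, cfg.sampling_rate)

    def band_rms(x):
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, 1 / cfg.sampling_rate)
        sel = (freqs >= 0.5) & (freqs <= 35.0)
        return np.sqrt(np.sum(np.abs(spec[sel]) ** 2))

    spec_diff = np.fft.rfft(twice - once)
    freqs = np.fft.rfftfreq(ecg.size, 1 / cfg.sampling_rate)
    sel = (freqs >= 0.5) & (freqs <= 35.0)
    assert np.sqrt(np.sum(np.abs(spec_diff[sel]) ** 2)) < 0.01 * band_rms(once)


def test_bandpass_rejects_bad_input():
    with pytest.raises(ValueError):
        preprocess_ecg(np.array([1.0, np.nan, 2.0] * 100), FS)
    with pytest.raises(ValueError):
        preprocess_ecg(np.zeros(1000), 60.0)  # rate too low for 40 Hz edge


# --- R peaks ---------------------------------------------------------------

def test_r_peaks_recovered_exactly(clean_ecg):
    ecg, truth, cfg = clean_ecg
    filtered = preprocess_ecg(ecg, cfg.sampling_rate)
    r = detect_r_peaks(filtered, cfg.sampling_rate)
    assert r.shape[0] == truth.r_times.shape[0]  # no extras, no misses
    assert np.max(np.abs(r - truth.r_times)) <= 1.0 / cfg.sampling_rate


def test_r_peaks_polarity_invariant(clean_ecg):
    ecg, _, cfg = clean_ecg
    filtered = preprocess_ecg(ecg, cfg.sampling_rate)
    r_pos = detect_r_peaks(filtered, cfg.sampling_rate)
    r_neg = detect_r_peaks(-filtered, cfg.sampling_rate)
    assert np.array_equal(r_pos, r_neg)


def test_flat_signal_raises():
    with pytest.raises(ValueError):
        detect_r_peaks(np.zeros(5000), FS)


# --- T offsets -------------------------------------------------------------

def test_t_offsets_within_tolerance(clean_ecg):
    ecg, truth, cfg = clean_ecg
    filtered = preprocess_ecg(ecg, cfg.sampling_rate)
    r = detect_r_peaks(filtered, cfg.sampling_rate)
    t_off = detect_t_offsets(filtered, r, cfg.sampling_rate)
    ok = np.isfinite(t_off)
    assert ok.mean() > 0.95
    assert np.max(np.abs(t_off[ok] - truth.t_offsets[ok])) < 0.015


def test_t_offsets_inside_own_beat(clean_ecg):
    ecg, _, cfg = clean_ecg
    events = delineate(ecg, cfg.sampling_rate)
    ok = np.isfinite(events.t_offsets)
    assert np.all(events.t_offsets[ok] > events.r_times[:-1][ok])
    assert np.all(events.t_offsets[ok] < events.r_times[1:][ok])


def test_absent_t_wave_is_flagged_not_fabricated():
    # R-spikes only, no T bump at all
    fs = FS
    t = np.arange(int(10 * fs)) / fs
    r_times = np.arange(0.5, 9.5, 0.9)
    x = np.zeros_like(t)
    for r in r_times:
        x += np.exp(-0.5 * ((t - r) / 0.012) ** 2)
    t_off = detect_t_offsets(x, r_times, fs)
    assert np.all(np.isnan(t_off))


def test_t_offsets_need_two_beats():
    with pytest.raises(ValueError):
        detect_t_offsets(np.zeros(1000), np.array([1.0]), FS)


# --- phase labels and angles ----------------------------------------------

def _events(r_times, t_offsets):
    return CardiacEvents(r_times=np.asarray(r_times, float),
                         t_offsets=np.asarray(t_offsets, float))


def test_phase_label_definitions():
    ev = _events([0.0, 0.9], [0.3])
    labels = label_cue_phase([0.05, 0.35, 0.3, 0.95], ev)
    assert list(labels) == ["systole", "diastole", "diastole", "unlabeled"]


def test_phase_partition_counts(session_and_truth):
    session, events, _ = session_and_truth
    ce = delineate(session.ecg, session.sampling_rate)
    labels = label_cue_phase(events["onset_s"].to_numpy(), ce)
    labelled = labels != "unlabeled"
    n_sys = np.sum(labels == "systole")
    n_dia = np.sum(labels == "diastole")
    assert n_sys + n_dia == labelled.sum()


def test_cue_angle_zero_latency():
    ev = _events([0.0, 0.9, 1.8], [0.3, 1.2])
    (a,) = cue_angle([0.9], ev)
    assert a.theta == pytest.approx(0.0)
    assert a.phase == "systole"


def test_cue_angle_four_beat_average():
    # previous four IBIs 0.8, 0.8, 1.0, 1.0 -> IBI_i = 0.9; C - R = 0.45 -> pi
    r = [0.0, 0.8, 1.6, 2.6, 3.6, 4.6]
    ev = _events(r, [ri + 0.3 for ri in r[:-1]])
    (a,) = cue_angle([3.6 + 0.45], ev)
    assert a.ibi_used == pytest.approx(0.9)
    assert a.theta == pytest.approx(np.pi)


def test_cue_angle_wraps_long_beats():
    # latency 1.0 s with averaged IBI 0.9 -> 2*pi/9 after wrapping
    r = [0.0, 0.9, 1.8, 2.7, 3.6, 4.7]
    ev = _events(r, [ri + 0.3 for ri in r[:-1]])
    (a,) = cue_angle([3.6 + 1.0], ev)
    assert a.theta == pytest.approx(2 * np.pi * (1.0 / 0.9) - 2 * np.pi,
                                    abs=1e-9)


def test_angle_phase_consistency(session_and_truth):
    """theta below the systole arc implies a systole label (noise-free)."""
    session, events, _ = session_and_truth
    ce = delineate(session.ecg, session.sampling_rate)
    for a in cue_angle(events["onset_s"].to_numpy(), ce):
        if a.phase == "unlabeled":
            continue
        if a.cue_time - a.r_time >= a.ibi_used:
            continue  # wrapped angle: consistency holds only pre-wrap
        j = np.searchsorted(ce.r_times, a.cue_time, side="right") - 1
        if not np.isfinite(ce.t_offsets[j]):
            continue
        arc = 2 * np.pi * (ce.t_offsets[j] - ce.r_times[j]) / a.ibi_used
        if a.theta < arc - 0.05:
            assert a.phase == "systole"
        elif a.theta > arc + 0.05:
            assert a.phase == "diastole"


# --- artifact regression ---------------------------------------------------

def test_regression_removes_known_leakage(rng):
    n = 50000
    clean = rng.standard_normal((2, n))
    ecg = rng.standard_normal(n)
    contaminated = clean + 0.4 * ecg
    out = regress_cardiac_artifact(contaminated, ecg)
    for ch in range(2):
        assert abs(np.corrcoef(out[ch], ecg)[0, 1]) < 0.02
        err = np.sqrt(np.mean((out[ch] - clean[ch]) ** 2))
        assert err < 0.05 * np.sqrt(np.mean(clean[ch] ** 2))


def test_regression_is_noop_without_artifact(rng):
    n = 20000
    clean = rng.standard_normal((1, n))
    ecg = rng.standard_normal(n)
    out = regress_cardiac_artifact(clean, ecg)
    change = np.sqrt(np.mean((out - clean) ** 2))
    assert change < 0.01 * np.sqrt(np.mean(clean ** 2))


def test_regression_idempotent(rng):
    n = 20000
    y = rng.standard_normal((1, n)) + 0.4 * np.sin(np.arange(n) / 5)
    ecg = np.sin(np.arange(n) / 5)
    once = regress_cardiac_artifact(y, ecg)
    twice = regress_cardiac_artifact(once, ecg)
    assert np.sqrt(np.mean((twice - once) ** 2)) \
        < 1e-3 * np.sqrt(np.mean(once ** 2))


def test_regression_rejects_flat_ecg(rng):
    with pytest.raises(ValueError):
        regress_cardiac_artifact(rng.standard_normal((1, 100)), np.ones(100))
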