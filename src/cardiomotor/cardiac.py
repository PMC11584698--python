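"""ECG delineation, cardiac-phase labelling of cues, and artifact regression.

Ventricular systole is defined as the interval from the R-peak to the T-wave
offset of the same beat, ventricular diastole as T-wave offset to the next
R-peak.  Cue latencies are also mapped to angles on the cardiac cycle,

    theta_i = 2*pi * (C_i - R_i) / IBI_i   (wrapped to [0, 2*pi)),

where IBI_i is the mean of up to four R-R intervals immediately preceding
the beat containing the cue — the averaging makes the normalization robust
to single-beat delineation glitches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as spsig

MIN_ECG_RATE = 80.0      # Hz needed to represent the 40 Hz upper band edge
REFRACTORY_S = 0.25      # minimum R-R separation enforced by the detector


@dataclass
class CardiacEvents:
    """Delineated R-peaks and T-wave offsets of one recording."""

    r_times: np.ndarray    # s, strictly increasing
    t_offsets: np.ndarray  # s, one per complete beat; NaN where undetected

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, float)
        self.t_offsets = np.asarray(self.t_offsets, float)
        if np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        if self.t_offsets.shape[0] != max(self.r_times.shape[0] - 1, 0):
            raise ValueError("need one t_offset slot per complete beat")

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.r_times)

    def systole_durations(self) -> np.ndarray:
        return self.t_offsets - self.r_times[:-1]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "r_time_s": self.r_times[:-1],
            "t_offset_s": self.t_offsets,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class CueAngle:
    """Cardiac timing of one cue: phase label and cycle angle."""

    index: int
    cue_time: float
    r_time: float
    ibi_used: float
    theta: float             # radians in [0, 2*pi)
    phase: str               # "systole" | "diastole" | "unlabeled"


def preprocess_ecg(ecg: np.ndarray, sampling_rate: float,
                   band: tuple[float, float] = (0.2, 40.0)) -> np.ndarray:
    """Zero-phase FIR band-pass (default 0.2-40 Hz), length preserved.

    A symmetric (linear-phase) FIR applied centred is exactly zero-phase;
    the filter length is capped at a third of the signal so short traces
    remain filterable, at the cost of a wider transition band.
    """
    ecg = np.asarray(ecg, float)
    if not np.all(np.isfinite(ecg)):
        raise ValueError("ECG contains NaN or infinite samples")
    if sampling_rate <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz too low for a {band[1]} Hz edge")
    n = ecg.shape[0]
    ntaps = min(int(8.0 * sampling_rate), n // 3)
    ntaps -= (ntaps + 1) % 2  # force odd (Type-I symmetric)
    if ntaps < 11:
        raise ValueError("signal too short to band-pass filter")
    taps = spsig.firwin(ntaps, band, pass_zero=False, fs=sampling_rate)
    pad = ntaps // 2
    padded = np.pad(ecg, pad, mode="reflect")
    return spsig.fftconvolve(padded, taps, mode="same")[pad:pad + n]


def detect_r_peaks(ecg: np.ndarray, sampling_rate: float,
                   min_beats: int = 5) -> np.ndarray:
    """R-peak times from a preprocessed ECG; 250 ms refractory period.

    Polarity is resolved automatically by comparing the magnitude of the
    largest positive and negative excursions around the median.
    """
    x = np.asarray(ecg, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ECG contains NaN or infinite samples")
    med = np.median(x)
    if np.percentile(np.abs(x - med), 99) - np.percentile(np.abs(x - med), 50) <= 0:
        raise ValueError("flat ECG: no beats found")
    up = np.percentile(x - med, 99.8)
    down = np.percentile(med - x, 99.8)
    if down > up:
        x = 2 * med - x  # inverted-polarity lead
        up = down
    height = med + 0.5 * up
    peaks, _ = spsig.find_peaks(x, height=height,
                                distance=max(int(REFRACTORY_S * sampling_rate), 1))
    if peaks.shape[0] < min_beats:
        raise ValueError(f"fewer than {min_beats} beats found")
    return peaks / sampling_rate


def detect_t_offsets(ecg: np.ndarray, r_times: np.ndarray,
                     sampling_rate: float) -> np.ndarray:
    """T-wave offsets by the tangent rule, one per complete beat.

    Within the search window (R + 150 ms, R + 0.6*IBI) the T peak is the
    largest excursion; the offset is where the tangent at the steepest point
    of the descending limb crosses the local baseline.  Beats without a
    detectable T wave get NaN (flagged, never fabricated).
    """
    x = np.asarray(ecg, float)
    r_times = np.asarray(r_times, float)
    if r_times.shape[0] < 2:
        raise ValueError("need at least two R peaks to delineate T offsets")
    fs = sampling_rate
    # light smoothing stabilizes the derivative on noisy records
    win = max(int(0.02 * fs), 1)
    smooth = spsig.fftconvolve(x, np.ones(win) / win, mode="same")
    deriv = np.gradient(smooth) * fs
    r_amp = np.median(smooth[np.round(r_times * fs).astype(int).clip(0, x.size - 1)])

    offsets = np.full(r_times.shape[0] - 1, np.nan)
    for k in range(r_times.shape[0] - 1):
        ibi = r_times[k + 1] - r_times[k]
        lo = int((r_times[k] + 0.15) * fs)
        hi = int((r_times[k] + 0.6 * ibi) * fs)
        if hi - lo < 4 or hi > x.size:
            continue
        seg = smooth[lo:hi]
        baseline = np.median(smooth[max(0, hi - int(0.05 * fs)):hi])
        t_peak = lo + int(np.argmax(np.abs(seg - baseline)))
        amp = seg[t_peak - lo] - baseline
        if abs(amp) < 0.05 * abs(r_amp - baseline):
            continue  # absent T bump
        limb = deriv[t_peak:hi] * np.sign(amp)
        if limb.size < 2:
            continue
        steep = t_peak + int(np.argmin(limb))
        slope = deriv[steep]
        if slope == 0 or np.sign(slope) == np.sign(amp):
            continue
        t_off = steep / fs + (baseline - smooth[steep]) / slope
        if r_times[k] < t_off < r_times[k + 1]:
            offsets[k] = t_off
    return offsets


def delineate(ecg: np.ndarray, sampling_rate: float) -> CardiacEvents:
    """Preprocess + R-peak + T-offset delineation in one call."""
    filtered = preprocess_ecg(ecg, sampling_rate)
    r_times = detect_r_peaks(filtered, sampling_rate)
    t_offsets = detect_t_offsets(filtered, r_times, sampling_rate)
    return CardiacEvents(r_times=r_times, t_offsets=t_offsets)


def _beat_index(events: CardiacEvents, cue: float) -> int:
    """Index of the beat containing ``cue``, or -1 if uncovered."""
    j = int(np.searchsorted(events.r_times, cue, side="right")) - 1
    if j < 0 or j >= events.r_times.shape[0] - 1:
        return -1
    return j


def label_cue_phase(cue_times: np.ndarray,
                    events: CardiacEvents) -> np.ndarray:
    """Systole/diastole label per cue with half-open boundary convention.

    ``[R, T_off) -> systole``, ``[T_off, next R) -> diastole``; cues outside
    the span of complete beats, or in beats whose T offset is missing, are
    labelled "unlabeled".
    """
    labels = np.empty(len(cue_times), dtype=object)
    for i, cue in enumerate(np.asarray(cue_times, float)):
        j = _beat_index(events, cue)
        if j < 0 or not np.isfinite(events.t_offsets[j]):
            labels[i] = "unlabeled"
        elif cue < events.t_offsets[j]:
            labels[i] = "systole"
        else:
            labels[i] = "diastole"
    return labels


def cue_angle(cue_times: np.ndarray, events: CardiacEvents,
              n_history: int = 4) -> list[CueAngle]:
    """Cardiac-cycle angle per cue, normalized by the recent-history IBI.

    The normalizing IBI is the mean of up to ``n_history`` R-R intervals
    preceding the cue's beat; with fewer preceding intervals the available
    ones are averaged, and for a cue inside the very first complete beat the
    first interval itself is used.  Angles wrap modulo 2*pi.
    """
    ibis = events.ibis
    phases = label_cue_phase(cue_times, events)
    out = []
    for i, cue in enumerate(np.asarray(cue_times, float)):
        j = _beat_index(events, cue)
        if j < 0:
            out.append(CueAngle(i, cue, np.nan, np.nan, np.nan, "unlabeled"))
            continue
        prev = ibis[max(0, j - n_history):j]
        ibi_used = float(prev.mean()) if prev.size else float(ibis[0])
        theta = float((2 * np.pi * (cue - events.r_times[j]) / ibi_used)
                      % (2 * np.pi))
        out.append(CueAngle(i, cue, float(events.r_times[j]), ibi_used,
                            theta, phases[i]))
    return out


def enrich_events(events_df: pd.DataFrame, cardiac: CardiacEvents
                  ) -> pd.DataFrame:
    """Cue table + phase, theta_rad, ibi_used_s columns."""
    angles = cue_angle(events_df["onset_s"].to_numpy(), cardiac)
    out = events_df.copy()
    out["phase"] = [a.phase for a in angles]
    out["theta_rad"] = [a.theta for a in angles]
    out["ibi_used_s"] = [a.ibi_used for a in angles]
    return out


def regress_cardiac_artifact(neural: np.ndarray, ecg: np.ndarray
                             ) -> np.ndarray:
    """Remove the cardiac-field artifact by OLS regression on the ECG.

    Per neural channel, the trace is regressed on the concurrent ECG (plus
    intercept) over all samples pooled (across epochs when epoched input is
    given) and the fitted component is subtracted.  Shapes supported:
    ``(n_ch, n_samples)`` with ``(n_samples,)`` ECG, or
    ``(n_trials, n_ch, n_samples)`` with ``(n_trials, n_samples)`` ECG.
    """
    neural = np.asarray(neural, float)
    ecg = np.asarray(ecg, float)
    if neural.ndim == 2 and ecg.ndim == 1:
        y = neural[None]            # (1, n_ch, n)
        e = ecg[None]               # (1, n)
        squeeze = True
    elif neural.ndim == 3 and ecg.ndim == 2:
        y, e, squeeze = neural, ecg, False
    else:
        raise ValueError("unsupported neural/ECG shapes")
    if y.shape[0] != e.shape[0] or y.shape[-1] != e.shape[-1]:
        raise ValueError("neural and ECG epochs are not time-aligned")
    e_flat = e.reshape(-1)
    var = e_flat.var()
    if var == 0:
        raise ValueError("zero-variance ECG: regression undefined")
    e_c = e_flat - e_flat.mean()
    cleaned = np.empty_like(y)
    for ch in range(y.shape[1]):
        y_flat = y[:, ch, :].reshape(-1)
        slope = (e_c @ (y_flat - y_flat.mean())) / (e_c @ e_c)
        intercept = y_flat.mean() - slope * e_flat.mean()
        resid = y_flat - (intercept + slope * e_flat)
        cleaned[:, ch, :] = resid.reshape(y.shape[0], y.shape[2])
    return cleaned[0] if squeeze else cleaned
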