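"""Synthetic coupled ECG / neural / EMG sessions with exact ground truth.

The generator emulates a cued motor-imagery experiment in which the phase of
the cardiac cycle at cue onset (ventricular systole vs diastole) modulates
the depth of contralateral alpha/beta desynchronization in sensorimotor
regions and the gain of the ipsilateral-dominant EMG burst.  Every event the
downstream analysis must recover — R-peaks, T-wave offsets, cue phases,
cue angles, programmed suppression depths, artifact gain — is returned as
ground truth, so each pipeline stage has an oracle.

Signal model per neural channel (M1/S1 x left/right hemisphere):

    x(t) = a_alpha * e(t) * sin(2*pi*f_alpha*t + phi)
         + a_beta  * e(t) * sin(2*pi*f_beta *t + psi)
         + noise_sd * pink(t) + artifact_gain * ECG(t)

where e(t) is an amplitude envelope equal to 1 at baseline and dropping to
(1 - depth) inside the post-cue desynchronization window; the programmed
depth depends on whether the channel is contralateral to the cued side and
on the cue's true cardiac phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

NEURAL_CHANNELS = ("M1-lh", "M1-rh", "S1-lh", "S1-rh")
EMG_CHANNELS = ("EMG-left", "EMG-right")

# stereotyped beat: Gaussian bumps (amplitude, offset from R in s, width in s);
# the T bump is positioned per beat so its tangent offset lands exactly at the
# programmed end of systole (peak at t_off - 2*sigma_T).
_P_WAVE = (0.12, -0.17, 0.020)
_Q_WAVE = (-0.08, -0.030, 0.008)
_R_WAVE = (1.00, 0.0, 0.012)
_S_WAVE = (-0.12, 0.035, 0.010)
_T_AMP = 0.30
T_SIGMA = 0.040


@dataclass
class SimulationConfig:
    """Parameters of a synthetic session; defaults are the study conditions."""

    sampling_rate: float = 250.0          # Hz
    session_duration: float | None = None  # s; derived from trial count if None
    n_trials_left: int = 100
    n_trials_right: int = 100
    trial_period: float = 8.0             # s between cues (trials last ~8 s)
    cue_jitter: float = 0.25              # s, uniform jitter around the grid
    ibi_mean: float = 0.9                 # s
    ibi_sd: float = 0.05                  # s
    systole_fraction: float = 0.35        # T-offset at this fraction of the beat
    alpha_freq: float = 10.0              # Hz
    beta_freq: float = 20.0               # Hz
    alpha_amp: float = 1.0
    beta_amp: float = 0.7
    erd_depth_contra_diastole: float = 0.5
    erd_depth_contra_systole: float = 0.2
    erd_depth_ipsi: float = 0.2
    erd_window: tuple[float, float] = (0.4, 2.5)  # s post-cue
    emg_burst_gain_ipsi: float = 3.0
    emg_burst_gain_contra: float = 1.0
    emg_phase_gain_diastole: float = 1.5
    emg_burst_window: tuple[float, float] = (0.3, 1.5)  # s post-cue
    emg_noise_sd: float = 0.05
    artifact_gain: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_trials(self) -> int:
        return self.n_trials_left + self.n_trials_right

    @property
    def duration(self) -> float:
        if self.session_duration is not None:
            return float(self.session_duration)
        # lead-in for cardiac history + full post-cue window after the last cue
        return 8.0 + self.n_trials * self.trial_period + 8.0

    def validate(self) -> None:
        positive = {
            "sampling_rate": self.sampling_rate,
            "trial_period": self.trial_period,
            "ibi_mean": self.ibi_mean,
            "alpha_freq": self.alpha_freq,
            "beta_freq": self.beta_freq,
            "noise_sd": self.noise_sd,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not 0.0 < self.systole_fraction < 1.0:
            raise ValueError("systole_fraction must lie in (0, 1)")
        for name in ("erd_depth_contra_diastole", "erd_depth_contra_systole",
                     "erd_depth_ipsi"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {d}")
        if self.ibi_sd < 0:
            raise ValueError("ibi_sd must be non-negative")
        # truncation at +/-3 SD must keep beats from overlapping the QRS/T span
        if self.ibi_mean - 3.0 * self.ibi_sd <= 0.3:
            raise ValueError(
                "ibi_sd too large: beats closer than 0.3 s would overlap")
        if self.session_duration is not None:
            needed = 8.0 + self.n_trials * self.trial_period + 8.0
            if self.session_duration < needed:
                raise ValueError(
                    f"{self.n_trials} cues at {self.trial_period} s spacing do "
                    f"not fit inside session_duration={self.session_duration}")


@dataclass
class GroundTruth:
    """Exact event times and programmed effects of a simulated session."""

    r_times: np.ndarray            # s, all R-peaks
    t_offsets: np.ndarray          # s, one per complete beat (len = n_beats - 1)
    ibis: np.ndarray               # s, R-R intervals
    cue_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    cue_sides: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    cue_phases: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    cue_angles: np.ndarray = field(default_factory=lambda: np.empty(0))
    contra_depths: np.ndarray = field(default_factory=lambda: np.empty(0))
    ipsi_depths: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_gain: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload))


@dataclass
class Session:
    """One recording: 4 region traces, 1 ECG lead, 2 EMG channels, cue table."""

    neural: np.ndarray             # (4, n_samples)
    ecg: np.ndarray                # (n_samples,)
    emg: np.ndarray                # (2, n_samples)
    sampling_rate: float
    events: pd.DataFrame           # onset_s, side, task
    neural_channels: tuple[str, ...] = NEURAL_CHANNELS
    emg_channels: tuple[str, ...] = EMG_CHANNELS

    @property
    def n_samples(self) -> int:
        return self.ecg.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "recording.npz", neural=self.neural, ecg=self.ecg,
                 emg=self.emg, sampling_rate=self.sampling_rate)
        self.events.to_csv(out / "events.tsv", sep="\t", index=False)
        meta = {"neural_channels": list(self.neural_channels),
                "emg_channels": list(self.emg_channels)}
        (out / "recording.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, out_dir: str | Path) -> "Session":
        out = Path(out_dir)
        arrays = np.load(out / "recording.npz")
        events = pd.read_csv(out / "events.tsv", sep="\t")
        meta = json.loads((out / "recording.json").read_text())
        return cls(neural=arrays["neural"], ecg=arrays["ecg"],
                   emg=arrays["emg"],
                   sampling_rate=float(arrays["sampling_rate"]),
                   events=events,
                   neural_channels=tuple(meta["neural_channels"]),
                   emg_channels=tuple(meta["emg_channels"]))


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _add_bump(trace, fs, amp, center, sigma):
    lo = max(0, int((center - 5 * sigma) * fs))
    hi = min(trace.shape[0], int((center + 5 * sigma) * fs) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    trace[lo:hi] += amp * _gauss(t, center, sigma)


def simulate_ecg(config: SimulationConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Stereotyped P-QRS-T train with analytically known events.

    IBIs are Normal(ibi_mean, ibi_sd) truncated at +/-3 SD.  The T-wave
    offset of beat k is placed at ``R_k + systole_fraction * IBI_k``; the
    T bump's peak sits two T-widths earlier so that the tangent rule on the
    descending limb recovers the offset exactly on noise-free data.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    duration = config.duration
    n_samples = int(round(duration * fs))

    max_beats = int(duration / max(config.ibi_mean - 3 * config.ibi_sd, 0.3)) + 2
    if config.ibi_sd > 0:
        ibis = sps.truncnorm.rvs(-3.0, 3.0, loc=config.ibi_mean,
                                 scale=config.ibi_sd, size=max_beats,
                                 random_state=rng)
    else:
        ibis = np.full(max_beats, config.ibi_mean)
    r_times = 1.0 + np.concatenate([[0.0], np.cumsum(ibis)])
    r_times = r_times[r_times < duration - 0.6]
    ibis = np.diff(r_times)
    t_offsets = r_times[:-1] + config.systole_fraction * ibis

    ecg = np.zeros(n_samples)
    for k, r in enumerate(r_times):
        for amp, off, sig in (_P_WAVE, _Q_WAVE, _R_WAVE, _S_WAVE):
            _add_bump(ecg, fs, amp, r + off, sig)
        if k < t_offsets.shape[0]:
            _add_bump(ecg, fs, _T_AMP, t_offsets[k] - 2.0 * T_SIGMA, T_SIGMA)
    truth = GroundTruth(r_times=r_times, t_offsets=t_offsets, ibis=ibis,
                        artifact_gain=config.artifact_gain)
    return ecg, truth


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped (1/f amplitude) Gaussian noise, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return pink / pink.std()


def _true_phase_and_angle(cue: float, truth: GroundTruth
                          ) -> tuple[str, float]:
    r = truth.r_times
    j = int(np.searchsorted(r, cue, side="right")) - 1
    if j < 0 or j >= truth.t_offsets.shape[0]:
        raise ValueError("cue outside the span of complete beats")
    phase = "systole" if cue < truth.t_offsets[j] else "diastole"
    prev = truth.ibis[max(0, j - 4):j]
    ibi_i = prev.mean() if prev.size else truth.ibis[0]
    theta = (2.0 * np.pi * (cue - r[j]) / ibi_i) % (2.0 * np.pi)
    return phase, theta


def _smooth_window(times: np.ndarray, start: float, end: float,
                   ramp: float = 0.1) -> np.ndarray:
    """0->1->0 envelope over [start, end] with raised-cosine ramps."""
    w = np.zeros_like(times)
    core = (times >= start + ramp) & (times <= end - ramp)
    w[core] = 1.0
    up = (times >= start) & (times < start + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (times[up] - start) / ramp))
    down = (times > end - ramp) & (times <= end)
    w[down] = 0.5 * (1 - np.cos(np.pi * (end - times[down]) / ramp))
    return w


def simulate_session(config: SimulationConfig, task: str = "MI"
                     ) -> tuple[Session, pd.DataFrame, GroundTruth]:
    """Full coupled session: ECG + 4 neural regions + 2 EMG channels.

    Reproducible bit-for-bit from ``config.seed``; independent substreams are
    spawned for the cardiac train, cue layout, each noise channel and each
    EMG carrier so stages can be regenerated independently.
    """
    config.validate()
    if config.erd_window[1] > 4.0 or config.erd_window[0] < -1.0:
        raise ValueError("erd_window must lie inside the -1..4 s epoch span")
    seeds = np.random.SeedSequence(config.seed).spawn(10)
    rng_ecg, rng_cue = (np.random.default_rng(s) for s in seeds[:2])
    rngs_neural = [np.random.default_rng(s) for s in seeds[2:6]]
    rngs_emg = [np.random.default_rng(s) for s in seeds[6:8]]
    rng_phase = np.random.default_rng(seeds[8])

    fs = config.sampling_rate
    ecg, truth = simulate_ecg(config, rng_ecg)
    n_samples = ecg.shape[0]
    times = np.arange(n_samples) / fs

    # cue layout: jittered grid, shuffled sides
    n = config.n_trials
    grid = 8.0 + config.trial_period * np.arange(n)
    cues = grid + rng_cue.uniform(-config.cue_jitter, config.cue_jitter, n)
    sides = np.array(["left"] * config.n_trials_left
                     + ["right"] * config.n_trials_right, dtype=object)
    rng_cue.shuffle(sides)

    phases = np.empty(n, dtype=object)
    angles = np.empty(n)
    for i, c in enumerate(cues):
        phases[i], angles[i] = _true_phase_and_angle(c, truth)

    contra_depths = np.where(phases == "diastole",
                             config.erd_depth_contra_diastole,
                             config.erd_depth_contra_systole)
    ipsi_depths = np.full(n, config.erd_depth_ipsi)

    # per-hemisphere desynchronization envelopes (shared by M1 and S1)
    envelopes = {}
    for hemi in ("lh", "rh"):
        env = np.ones(n_samples)
        for i, c in enumerate(cues):
            contra = (sides[i] == "left") == (hemi == "rh")
            depth = contra_depths[i] if contra else ipsi_depths[i]
            if depth == 0.0:
                continue
            w = _smooth_window(times, c + config.erd_window[0],
                               c + config.erd_window[1])
            env *= 1.0 - depth * w
        envelopes[hemi] = env

    neural = np.empty((4, n_samples))
    for ch, name in enumerate(NEURAL_CHANNELS):
        hemi = name.split("-")[1]
        phi, psi = rng_phase.uniform(0, 2 * np.pi, 2)
        osc = (config.alpha_amp * np.sin(2 * np.pi * config.alpha_freq * times + phi)
               + config.beta_amp * np.sin(2 * np.pi * config.beta_freq * times + psi))
        neural[ch] = (envelopes[hemi] * osc
                      + config.noise_sd * _pink_noise(n_samples, rngs_neural[ch])
                      + config.artifact_gain * ecg)

    emg = np.empty((2, n_samples))
    for ch, ch_side in enumerate(("left", "right")):
        gain_env = np.zeros(n_samples)
        for i, c in enumerate(cues):
            gain = (config.emg_burst_gain_ipsi if sides[i] == ch_side
                    else config.emg_burst_gain_contra)
            if phases[i] == "diastole":
                gain *= config.emg_phase_gain_diastole
            gain_env += gain * _smooth_window(
                times, c + config.emg_burst_window[0],
                c + config.emg_burst_window[1])
        carrier = rngs_emg[ch].standard_normal(n_samples)
        emg[ch] = config.emg_noise_sd * carrier * (1.0 + gain_env)

    events = pd.DataFrame({"onset_s": cues, "side": sides,
                           "task": [task] * n})
    truth.cue_times = cues
    truth.cue_sides = sides
    truth.cue_phases = phases
    truth.cue_angles = angles
    truth.contra_depths = contra_depths
    truth.ipsi_depths = ipsi_depths
    session = Session(neural=neural, ecg=ecg, emg=emg, sampling_rate=fs,
                      events=events)
    return session, events, truth
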