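"""Epoching, Morlet time-frequency power, baseline z-scoring, band averaging.

Trials are cut from -1 to 4 s around the cue (half-open on the sampling
grid), decomposed with 5-cycle complex Morlet wavelets at 1 Hz resolution
over 8-30 Hz, z-scored against the -0.5..0 s pre-cue baseline of the same
trial, and averaged into alpha (8-13 Hz) and beta (14-30 Hz) bands.  The
result is expressed in baseline standard deviations, so event-related
desynchronization appears as negative values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

EPOCH_WINDOW = (-1.0, 4.0)       # s relative to cue
BASELINE = (-0.5, 0.0)           # s relative to cue
BANDS = {"alpha": (8, 13), "beta": (14, 30)}
DEFAULT_FREQS = np.arange(8.0, 31.0)   # 1 Hz bins, 8..30 inclusive
EDGE_GUARD = 0.3                 # s trimmed from statistics (wavelet edges)
ANALYSIS_WINDOWS = {"primary": (0.5, 2.0), "full": (0.5, 4.0)}


@dataclass
class EpochSet:
    """Cue-locked trials: (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    sampling_rate: float
    t0_offset: float = EPOCH_WINDOW[0]
    channels: tuple[str, ...] = ()
    events: pd.DataFrame | None = None   # side/phase/... per kept trial

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.data.shape[-1]) / self.sampling_rate

    def __post_init__(self) -> None:
        if self.events is not None and len(self.events) != self.data.shape[0]:
            raise ValueError("trial metadata length must equal trial count")


@dataclass
class BandPowerSet:
    """Baseline-z-scored band power: (n_trials, n_channels, n_bands, n_samples)."""

    z: np.ndarray
    sampling_rate: float
    t0_offset: float = EPOCH_WINDOW[0]
    bands: tuple[str, ...] = tuple(BANDS)
    channels: tuple[str, ...] = ()
    baseline: tuple[float, float] = BASELINE
    events: pd.DataFrame | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.z.shape[-1]) / self.sampling_rate

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        return (t >= window[0]) & (t < window[1])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "bandpower.npz", z=self.z)
        meta = {"sampling_rate": self.sampling_rate,
                "t0_offset": self.t0_offset, "bands": list(self.bands),
                "channels": list(self.channels),
                "baseline": list(self.baseline),
                "band_edges": {b: list(BANDS[b]) for b in self.bands
                               if b in BANDS}}
        (out / "bandpower.json").write_text(json.dumps(meta))
        if self.events is not None:
            self.events.to_csv(out / "bandpower_events.tsv", sep="\t",
                               index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "BandPowerSet":
        out = Path(out_dir)
        z = np.load(out / "bandpower.npz")["z"]
        meta = json.loads((out / "bandpower.json").read_text())
        ev_path = out / "bandpower_events.tsv"
        events = pd.read_csv(ev_path, sep="\t") if ev_path.exists() else None
        return cls(z=z, sampling_rate=meta["sampling_rate"],
                   t0_offset=meta["t0_offset"], bands=tuple(meta["bands"]),
                   channels=tuple(meta["channels"]),
                   baseline=tuple(meta["baseline"]), events=events)


def epoch(data: np.ndarray, sampling_rate: float, cue_times: np.ndarray,
          window: tuple[float, float] = EPOCH_WINDOW,
          channels: tuple[str, ...] = (),
          events: pd.DataFrame | None = None) -> EpochSet:
    """Cut cue-locked trials out of a continuous multichannel recording.

    Cues whose window is not fully covered by the recording are dropped;
    an empty result raises, signalling misaligned events.  The window is
    half-open on the sampling grid: ``n_samples = round((w1 - w0) * fs)``.
    """
    data = np.atleast_2d(np.asarray(data, float))
    cue_times = np.asarray(cue_times, float)
    n_total = data.shape[-1]
    n_samp = int(round((window[1] - window[0]) * sampling_rate))
    starts = np.round((cue_times + window[0]) * sampling_rate).astype(int)
    keep = (starts >= 0) & (starts + n_samp <= n_total)
    if not keep.any():
        raise ValueError("no cue has full window coverage: misaligned events?")
    trials = np.stack([data[:, s:s + n_samp] for s in starts[keep]])
    kept_events = None
    if events is not None:
        kept_events = events.loc[keep].reset_index(drop=True)
    return EpochSet(data=trials, sampling_rate=sampling_rate,
                    t0_offset=window[0], channels=tuple(channels),
                    events=kept_events)


def morlet_power(epochs: EpochSet, freqs: np.ndarray = DEFAULT_FREQS,
                 n_cycles: float = 5.0) -> np.ndarray:
    """Squared-magnitude Morlet decomposition, (trials, ch, freqs, samples)."""
    freqs = np.asarray(freqs, float)
    if freqs.max() >= epochs.sampling_rate / 2:
        raise ValueError("requested frequency at or above Nyquist")
    min_len = n_cycles / freqs.min()
    if epochs.data.shape[-1] / epochs.sampling_rate < min_len:
        raise ValueError(
            f"epochs shorter than {n_cycles} cycles at {freqs.min()} Hz")
    return tfr_array_morlet(epochs.data, sfreq=epochs.sampling_rate,
                            freqs=freqs, n_cycles=n_cycles, output="power")


def baseline_zscore(power: np.ndarray, times: np.ndarray,
                    baseline: tuple[float, float] = BASELINE,
                    mode: str = "per-trial") -> np.ndarray:
    """Z-score power against the pre-cue baseline.

    ``per-trial`` (default) uses each trial's own baseline mean/SD per
    channel and frequency; ``pooled`` uses baseline statistics pooled over
    trials.  Trials with zero baseline SD are flagged by NaN output.
    """
    mask = (times >= baseline[0]) & (times < baseline[1])
    if not mask.any():
        raise ValueError("baseline window outside the epoch")
    base = power[..., mask]
    if mode == "per-trial":
        mu = base.mean(axis=-1, keepdims=True)
        sd = base.std(axis=-1, keepdims=True)
    elif mode == "pooled":
        mu = base.mean(axis=(0, -1), keepdims=True)
        sd = base.std(axis=(0, -1), keepdims=True)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    sd = np.where(sd == 0, np.nan, sd)
    return (power - mu) / sd


def band_average(z_power: np.ndarray, freqs: np.ndarray = DEFAULT_FREQS,
                 bands: dict[str, tuple[float, float]] = BANDS) -> np.ndarray:
    """Unweighted mean over the integer frequency bins of each band."""
    freqs = np.asarray(freqs, float)
    out = []
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"no frequency bins cover band {name}")
        out.append(z_power[..., sel, :].mean(axis=-2))
    return np.stack(out, axis=-2)


def compute_band_power(epochs: EpochSet, freqs: np.ndarray = DEFAULT_FREQS,
                       n_cycles: float = 5.0,
                       baseline: tuple[float, float] = BASELINE,
                       baseline_mode: str = "per-trial",
                       bands: dict[str, tuple[float, float]] = BANDS
                       ) -> BandPowerSet:
    """Epochs -> Morlet power -> baseline z-score -> band means."""
    power = morlet_power(epochs, freqs, n_cycles)
    z = baseline_zscore(power, epochs.times, baseline, baseline_mode)
    zb = band_average(z, freqs, bands)
    return BandPowerSet(z=zb, sampling_rate=epochs.sampling_rate,
                        t0_offset=epochs.t0_offset, bands=tuple(bands),
                        channels=epochs.channels, baseline=baseline,
                        events=epochs.events)


def lateralize(bp: BandPowerSet, sides: np.ndarray,
               regions: tuple[str, ...] = ("M1", "S1")
               ) -> tuple[np.ndarray, np.ndarray]:
    """Reorder hemisphere channels into (ipsi, contra) per trial.

    Returns two arrays of shape (n_trials, n_regions, n_bands, n_samples):
    the trace ipsilateral and contralateral to each trial's cued side.
    Assumes channels named ``<region>-lh`` / ``<region>-rh``.
    """
    names = list(bp.channels)
    sides = np.asarray(sides)
    ipsi = np.empty((bp.z.shape[0], len(regions)) + bp.z.shape[2:])
    contra = np.empty_like(ipsi)
    for r, region in enumerate(regions):
        lh = names.index(f"{region}-lh")
        rh = names.index(f"{region}-rh")
        left_cue = sides == "left"
        ipsi[left_cue, r] = bp.z[left_cue, lh]
        ipsi[~left_cue, r] = bp.z[~left_cue, rh]
        contra[left_cue, r] = bp.z[left_cue, rh]
        contra[~left_cue, r] = bp.z[~left_cue, lh]
    return ipsi, contra
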