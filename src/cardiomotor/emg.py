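"""EMG envelopes: high-pass, full-wave rectification, moving-RMS smoothing.

The 10 Hz filter is applied as a zero-phase high-pass: it suppresses motion
artifact and baseline drift while leaving the surface-EMG band intact (a
10 Hz low-pass would remove the EMG signal itself).  The envelope is the
moving root-mean-square of the rectified trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy.ndimage import uniform_filter1d


@dataclass
class EmgEnvelopeSet:
    """Envelope epochs ordered (ipsi, contra) relative to each cue."""

    envelopes: np.ndarray        # (n_trials, 2, n_samples), >= 0
    sampling_rate: float
    t0_offset: float
    smoothing_window: float      # s
    events: pd.DataFrame | None = None

    @property
    def times(self) -> np.ndarray:
        n = self.envelopes.shape[-1]
        return self.t0_offset + np.arange(n) / self.sampling_rate

    @property
    def ipsi(self) -> np.ndarray:
        return self.envelopes[:, 0]

    @property
    def contra(self) -> np.ndarray:
        return self.envelopes[:, 1]


def preprocess_emg(emg: np.ndarray, sampling_rate: float,
                   highpass: float = 10.0,
                   rms_window: float = 0.1) -> np.ndarray:
    """Rectified, RMS-smoothed envelope of one or more EMG traces.

    Steps: zero-phase 4th-order Butterworth high-pass at ``highpass`` Hz,
    full-wave rectification, moving RMS over ``rms_window`` seconds (hop of
    one sample).  Works on the last axis of any-dimensional input.
    """
    emg = np.asarray(emg, float)
    if not np.all(np.isfinite(emg)):
        raise ValueError("EMG contains NaN or infinite samples")
    sos = spsig.butter(4, highpass, btype="highpass", fs=sampling_rate,
                       output="sos")
    filtered = spsig.sosfiltfilt(sos, emg, axis=-1)
    rect = np.abs(filtered)
    win = max(int(round(rms_window * sampling_rate)), 1)
    return np.sqrt(uniform_filter1d(rect ** 2, size=win, axis=-1,
                                    mode="nearest"))


def split_ipsi_contra(envelope_epochs: np.ndarray, sides: np.ndarray,
                      channel_sides: tuple[str, str] = ("left", "right")
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Map (left, right) channel epochs to (ipsi, contra) per cued side.

    Ipsilateral is the channel on the same side as the cue.  Shapes:
    ``envelope_epochs`` is (n_trials, 2, n_samples); returns two
    (n_trials, n_samples) arrays.
    """
    env = np.asarray(envelope_epochs, float)
    if env.ndim != 3 or env.shape[1] != 2:
        raise ValueError("expected (n_trials, 2 channels, n_samples) epochs")
    sides = np.asarray(sides)
    if sides.shape[0] != env.shape[0]:
        raise ValueError("one cued side per trial required")
    left_idx = channel_sides.index("left")
    right_idx = channel_sides.index("right")
    is_left = sides == "left"
    ipsi = np.where(is_left[:, None], env[:, left_idx], env[:, right_idx])
    contra = np.where(is_left[:, None], env[:, right_idx], env[:, left_idx])
    return ipsi, contra
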