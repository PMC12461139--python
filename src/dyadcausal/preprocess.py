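"""Band-pass filtering and per-channel normalization.

The analysis assumes chromophore concentration time series band-limited to
the hemodynamic range: a 5th-order Butterworth band-pass with -3 dB cutoffs
at 0.008 and 0.2 Hz, applied with identical coefficients to every channel of
both participants so that any filter-induced lag is common to all channels
and cannot create spurious directionality.  Zero-phase (forward-backward)
application is the default; a causal forward-only mode is exposed because
the filter's passband phase is nearly linear and either choice is defensible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

__all__ = ["bandpass_filter", "butter_sos", "znormalize"]


def butter_sos(fs: float, low: float = 0.008, high: float = 0.2,
               order: int = 5) -> np.ndarray:
    """Design the Butterworth band-pass (second-order sections).

    Cutoffs are the -3 dB points of the analog prototype mapped by the
    bilinear transform (scipy's standard design contract).
    """
    if not 0.0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= fs / 2.0:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x: np.ndarray, fs: float, low: float = 0.008,
                    high: float = 0.2, order: int = 5,
                    mode: str = "zero_phase") -> np.ndarray:
    """Band-pass every column of ``x`` (L x C) with identical coefficients.

    mode="zero_phase" filters forward and backward (no phase distortion,
    squared magnitude response); mode="forward" applies the causal filter
    once.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("expected a 1-D or 2-D (samples x channels) array")
    if x.shape[0] <= 3 * order:
        raise ValueError(
            f"time series too short to filter: need more than {3 * order} samples"
        )
    sos = butter_sos(fs, low=low, high=high, order=order)
    if mode == "zero_phase":
        y = signal.sosfiltfilt(sos, x, axis=0)
    elif mode == "forward":
        y = signal.sosfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown filter mode {mode!r}; use 'zero_phase' or 'forward'")
    return y[:, 0] if squeeze else y


def znormalize(epoch, ddof: int = 1):
    """Standardize each column to mean 0 and unit sample variance.

    Accepts a DyadEpoch (returns a new epoch) or a plain array.  Idempotent
    within numerical tolerance.  A zero-variance column is an error naming
    the offending channel: a constant channel carries no dynamics and would
    make the causal estimates undefined.
    """
    is_epoch = not isinstance(epoch, np.ndarray) and hasattr(epoch, "data")
    x = np.asarray(epoch.data if is_epoch else epoch, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (samples x channels) array")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    bad = np.where(sd == 0.0)[0]
    if bad.size:
        raise ValueError(f"zero-variance channel(s) at column index {bad.tolist()}")
    z = (x - mean) / sd
    if is_epoch:
        return dataclasses.replace(epoch, data=z)
    return z
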