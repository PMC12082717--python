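"""Band-pass preprocessing.

Raw scalp EEG carries a slow drift and high-frequency acquisition noise, so
everything outside 0.5-75 Hz is removed with a linear-phase FIR band-pass
before feature extraction.  The filter is a Hamming-windowed sinc designed
by ``scipy.signal.firwin``; it is applied in a single FFT convolution pass
with the group delay compensated, which for a symmetric (linear-phase) FIR
is exactly zero-phase.  Edges are reflect-padded by one filter length so the
output keeps the input length and the first/last windows remain usable.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as _sig

from .errors import ParameterError
from .recording import Recording

DEFAULT_LOW_HZ = 0.5
DEFAULT_HIGH_HZ = 75.0
DEFAULT_TRANSITION_HZ = 0.25


def design_bandpass(fs: float, low_hz: float = DEFAULT_LOW_HZ,
                    high_hz: float = DEFAULT_HIGH_HZ,
                    transition_hz: float = DEFAULT_TRANSITION_HZ) -> np.ndarray:
    """Design the linear-phase FIR band-pass taps.

    The number of taps follows the Hamming-window rule ``N ~ 3.3 / dF`` for
    a transition of ``transition_hz`` (normalized by fs), forced odd so the
    group delay is an integer number of samples.
    """
    if not 0 < low_hz < high_hz:
        raise ParameterError(f"need 0 < low < high, got [{low_hz}, {high_hz}]")
    if high_hz >= fs / 2:
        raise ParameterError(
            f"high edge {high_hz} Hz must lie below Nyquist ({fs / 2} Hz)")
    if transition_hz <= 0:
        raise ParameterError("transition width must be positive")
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2
    return _sig.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs,
                       window="hamming")


def bandpass_array(x: np.ndarray, fs: float, low_hz: float = DEFAULT_LOW_HZ,
                   high_hz: float = DEFAULT_HIGH_HZ,
                   transition_hz: float = DEFAULT_TRANSITION_HZ) -> np.ndarray:
    """Zero-phase band-pass of a (channels x samples) or 1-D array."""
    taps = design_bandpass(fs, low_hz, high_hz, transition_hz)
    one_d = x.ndim == 1
    x2 = np.atleast_2d(np.asarray(x, dtype=np.float64))
    pad = len(taps)
    if x2.shape[1] < 2:
        raise ParameterError("signal too short to filter")
    padded = np.pad(x2, [(0, 0), (pad, pad)], mode="reflect")
    # overlap-add keeps long-record filtering O(n log ntaps); the taps are
    # symmetric, so centered "same" alignment is exactly zero-phase
    out = _sig.oaconvolve(padded, taps[None, :], mode="same", axes=1)
    out = out[:, pad:-pad]
    return out[0] if one_d else out


def bandpass(rec: Recording, low_hz: float = DEFAULT_LOW_HZ,
             high_hz: float = DEFAULT_HIGH_HZ,
             transition_hz: float = DEFAULT_TRANSITION_HZ) -> Recording:
    """Return a band-passed copy of ``rec`` with identical shape and rate."""
    filtered = bandpass_array(rec.signal, rec.fs, low_hz, high_hz, transition_hz)
    meta = dict(rec.meta, filtered=True,
                filter_band_hz=(float(low_hz), float(high_hz)))
    return Recording(list(rec.channel_labels), rec.fs, filtered,
                     rec.transducer_max.copy(), meta)
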