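"""Long-range temporal correlations: band-pass filtering, Hilbert
amplitude envelopes, and detrended fluctuation analysis (DFA).

The DFA exponent quantifies the decay of autocorrelations in an
oscillation's amplitude envelope: 0.5 for an uncorrelated signal, >0.5
for persistent (long-range correlated) fluctuations.  It is estimated as
the slope of log10(fluctuation) against log10(window size), where the
fluctuation at a given window size is the RMS of the linearly detrended
cumulative signal profile within overlapping windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BandScheme, make_band_scheme

#: Below this duration DFA estimates are considered unreliable (warning).
RELIABLE_DURATION_S = 100.0
#: Below this duration DFA is refused outright.
MIN_DURATION_S = 20.0


def design_bandpass(band: tuple[float, float], fs: float) -> np.ndarray:
    """Hamming-windowed FIR band-pass taps; transition width 25% of the
    lower band edge."""
    low, high = band
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} not inside (0, {nyq}) Hz")
    trans = 0.25 * low
    if high - low <= trans / 2:
        raise ValueError(
            f"band {band} too narrow for a transition width of {trans:.2f} Hz"
        )
    # Hamming design rule: numtaps ~ 3.3 / normalized transition width
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # force odd for a type-I linear-phase filter
    return sps.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=fs)


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-phase band-pass filtering.

    The symmetric (linear-phase) FIR taps are applied by a single FFT
    convolution centered on the signal, which is exactly zero-phase.
    """
    taps = design_bandpass(band, fs)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * len(taps):
        raise ValueError(
            f"signal too short ({x.shape[-1]} samples) for a {len(taps)}-tap filter"
        )
    return sps.fftconvolve(x, taps[(None,) * (x.ndim - 1)], mode="same", axes=-1)


def amplitude_envelope(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Hilbert amplitude envelope of the band-passed signal.

    One filter length is trimmed from each side to suppress filter and
    Hilbert edge transients.
    """
    taps = design_bandpass(band, fs)
    filtered = bandpass(x, band, fs)
    env = np.abs(sps.hilbert(filtered, axis=-1))
    trim = len(taps)
    return env[..., trim:-trim]


@dataclass(frozen=True)
class DfaConfig:
    """Fit-range configuration for DFA.

    fit_range : (low, high) window sizes in seconds (default 2-20 s)
    n_windows : number of log-spaced window sizes (default 10)
    overlap : fractional overlap between successive windows (default 0.5)
    detrend_order : polynomial detrending order (default 1, linear)
    """

    fit_range: tuple[float, float] = (2.0, 20.0)
    n_windows: int = 10
    overlap: float = 0.5
    detrend_order: int = 1

    def window_sizes(self, fs: float) -> np.ndarray:
        sizes = np.geomspace(self.fit_range[0], self.fit_range[1], self.n_windows)
        samples = np.unique(np.round(sizes * fs).astype(int))
        return samples[samples >= self.detrend_order + 2]


@dataclass(frozen=True)
class DfaResult:
    exponent: float
    fit_residual: float
    window_sizes_s: np.ndarray = field(repr=False)
    fluctuations: np.ndarray = field(repr=False)


def dfa(series: np.ndarray, fs: float, config: DfaConfig | None = None) -> DfaResult:
    """Detrended fluctuation analysis of a 1-D series.

    Raises for series shorter than 20 s; warns between 20 and 100 s,
    where the exponent estimate is noisy.
    """
    config = config or DfaConfig()
    x = np.asarray(series, dtype=float).ravel()
    duration = len(x) / fs
    if duration < MIN_DURATION_S:
        raise ValueError(
            f"series of {duration:.1f} s is too short for DFA (minimum "
            f"{MIN_DURATION_S:.0f} s)"
        )
    if duration < RELIABLE_DURATION_S:
        warnings.warn(
            f"series of {duration:.1f} s is below the ~{RELIABLE_DURATION_S:.0f} s "
            "needed for a reliable DFA estimate",
            UserWarning,
            stacklevel=2,
        )
    if np.std(x) == 0:
        raise ValueError("zero-variance series: DFA exponent undefined")

    sizes = config.window_sizes(fs)
    sizes = sizes[sizes <= len(x)]
    if len(sizes) < 3:
        raise ValueError("fewer than 3 usable window sizes; extend the signal")

    profile = np.cumsum(x - np.mean(x))
    flucts = np.empty(len(sizes))
    for i, n in enumerate(sizes):
        step = max(1, int(round(n * (1.0 - config.overlap))))
        starts = np.arange(0, len(profile) - n + 1, step)
        windows = profile[starts[:, None] + np.arange(n)]
        # vectorized polynomial detrend: residual = (I - H) w  with H the
        # hat matrix of the degree-d Vandermonde fit, shared across windows
        t = np.arange(n, dtype=float)
        V = np.vander(t, config.detrend_order + 1)
        coef, *_ = np.linalg.lstsq(V, windows.T, rcond=None)
        resid = windows.T - V @ coef
        flucts[i] = np.sqrt(np.mean(resid**2))

    log_n = np.log10(sizes / fs)
    log_f = np.log10(flucts)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    residual = float(np.sqrt(np.mean((log_f - (slope * log_n + intercept)) ** 2)))
    return DfaResult(
        exponent=float(slope),
        fit_residual=residual,
        window_sizes_s=sizes / fs,
        fluctuations=flucts,
    )


def dfa_table(
    signals: np.ndarray,
    fs: float,
    scheme: BandScheme | None = None,
    config: DfaConfig | None = None,
) -> pd.DataFrame:
    """Batch DFA: per parcel and per frequency bin of the band scheme.

    Returns a DataFrame (parcel, bin, dfa_exponent, fit_residual).
    """
    scheme = scheme or make_band_scheme()
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    rows = []
    for b in range(scheme.n_bins):
        band = (float(scheme.edges[b]), float(scheme.edges[b + 1]))
        env = amplitude_envelope(signals, band, fs)
        for parcel in range(signals.shape[0]):
            res = dfa(env[parcel], fs, config)
            rows.append((parcel, b, res.exponent, res.fit_residual))
    return pd.DataFrame(rows, columns=["parcel", "bin", "dfa_exponent", "fit_residual"])
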