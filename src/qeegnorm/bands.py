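"""Frequency-band scheme and Welch band power.

The analysis grid is 11 contiguous frequency bins inside 1-45 Hz: one
delta bin at 1-4 Hz and ten logarithmically spaced bins between 4 and
44.8 Hz (ratio ``(44.8/4)**(1/10)`` between successive edges).  The bins
are grouped into five canonical bands (delta, theta, alpha, beta,
beta-gamma) used for feature aggregation.

Power spectral densities are estimated with Welch's method (Hamming
window, segment length = FFT length = 10 * fs samples, 50% overlap),
giving a 0.1 Hz frequency resolution.  Absolute band power is the PSD
integrated over a bin, reported in dB (``10*log10``, unit reference);
relative band power is the bin integral as a percentage of the total
1-45 Hz integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Canonical band names in fixed order.
CANONICAL_BANDS = ("delta", "theta", "alpha", "beta", "beta_gamma")

#: Bin indices (0-based) belonging to each canonical band.
CANONICAL_GROUPS = {
    "delta": (0,),
    "theta": (1, 2, 3),
    "alpha": (4, 5),
    "beta": (6, 7),
    "beta_gamma": (8, 9, 10),
}

_LOW, _SPLIT, _HIGH = 1.0, 4.0, 44.8
_TOTAL_RANGE = (1.0, 45.0)  # integration range for relative power


@dataclass(frozen=True)
class BandScheme:
    """The 11-bin frequency scheme and its canonical grouping.

    Attributes
    ----------
    edges : ndarray, shape (12,)
        Unrounded bin edges in Hz; ``edges[0] = 1``, ``edges[1] = 4`` and
        the remaining edges follow the log-spacing recurrence.
    groups : dict
        Canonical band name -> tuple of bin indices.
    """

    edges: np.ndarray
    groups: dict = field(default_factory=lambda: dict(CANONICAL_GROUPS))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def display_edges(self) -> np.ndarray:
        """Edges rounded to one decimal, as printed in band labels."""
        return np.round(self.edges, 1)

    def bin_labels(self) -> list[str]:
        d = self.display_edges
        return [f"{d[i]:g}-{d[i + 1]:g}Hz" for i in range(self.n_bins)]

    def band_edges(self, band: str) -> tuple[float, float]:
        """(low, high) Hz span of a canonical band (union of its bins)."""
        bins = self.groups[band]
        return float(self.edges[bins[0]]), float(self.edges[bins[-1] + 1])


def make_band_scheme() -> BandScheme:
    """Build the standard 11-bin scheme (1-4 Hz + 10 log-spaced to 44.8 Hz)."""
    ratio = (_HIGH / _SPLIT) ** (1.0 / 10.0)
    edges = np.concatenate(
        [[_LOW], _SPLIT * ratio ** np.arange(11)]
    )
    return BandScheme(edges=edges)


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hamming window on a 0.1 Hz grid.

    Parameters
    ----------
    x : array, shape (..., n_samples)
        Signal(s); the PSD is computed along the last axis.
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    freqs, psd
        Frequency grid (spacing ``1/10`` Hz) and power spectral density
        normalized so that its integral approximates the signal variance.
    """
    if fs <= 0 or not np.isfinite(fs):
        raise ValueError(f"invalid sampling rate fs={fs!r}")
    nperseg = int(round(10 * fs))
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal has {x.shape[-1]} samples; Welch estimation needs at "
            f"least one segment of 10*fs = {nperseg} samples"
        )
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nperseg,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def _integrate(freqs: np.ndarray, psd: np.ndarray, low: float, high: float) -> np.ndarray:
    """Trapezoid integral of the PSD over [low, high].

    Bin edges generally fall between grid points, so the PSD is linearly
    interpolated at the exact edges; adjacent bins then share endpoint
    values and trapezoid additivity guarantees no double counting or gaps.
    """
    if low < freqs[0] - 1e-9 or high > freqs[-1] + 1e-9:
        raise ValueError(f"PSD grid does not cover the band [{low}, {high}] Hz")
    inside = (freqs > low) & (freqs < high)
    grid = np.concatenate([[low], freqs[inside], [high]])
    psd2 = np.atleast_2d(psd)
    lo_v = np.array([np.interp(low, freqs, row) for row in psd2])
    hi_v = np.array([np.interp(high, freqs, row) for row in psd2])
    vals = np.concatenate([lo_v[:, None], psd2[:, inside], hi_v[:, None]], axis=1)
    out = np.trapezoid(vals, grid, axis=-1)
    return out if np.ndim(psd) > 1 else out[0]


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, scheme: BandScheme | None = None
) -> pd.DataFrame:
    """Absolute (dB) and relative (%) power per bin for one or more parcels.

    Parameters
    ----------
    freqs, psd
        Output of :func:`welch_psd`; ``psd`` may be 1-D or (n_parcels, n_freqs).
    scheme
        Band scheme; defaults to :func:`make_band_scheme`.

    Returns
    -------
    DataFrame with columns (parcel, bin, absolute_db, relative_pct).
    """
    scheme = scheme or make_band_scheme()
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    total = _integrate(freqs, psd, *_TOTAL_RANGE)
    if np.any(total <= 0):
        bad = np.nonzero(total <= 0)[0]
        raise ValueError(f"zero total 1-45 Hz power for parcel index {bad[0]}")
    rows = []
    for b in range(scheme.n_bins):
        lo, hi = scheme.edges[b], scheme.edges[b + 1]
        p = _integrate(freqs, psd, lo, hi)
        with np.errstate(divide="ignore"):
            abs_db = 10.0 * np.log10(p)
        rel = 100.0 * p / total
        for parcel in range(psd.shape[0]):
            rows.append((parcel, b, abs_db[parcel], rel[parcel]))
    return pd.DataFrame(rows, columns=["parcel", "bin", "absolute_db", "relative_pct"])


def power_table(signals: np.ndarray, fs: float, scheme: BandScheme | None = None) -> pd.DataFrame:
    """Per-parcel band-power table straight from time series.

    ``signals`` is (n_parcels, n_samples).
    """
    freqs, psd = welch_psd(signals, fs)
    return band_powers(freqs, psd, scheme)
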