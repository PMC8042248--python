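"""Stockwell (S-) transform and its ripple-band spectral entropy.

The S-transform is a time-frequency representation with a frequency-scaled
Gaussian window (width proportional to period), computed here with the
standard FFT formulation: for analysis frequency bin k,

    S(t, f_k) = IFFT_m[ X(m + k) * exp(-2 pi^2 m^2 / k^2) ]

where X is the FFT of the signal.  Windows of signal with a *flat* ripple-band
S-spectrum (high Shannon entropy) carry no oscillatory activity and serve as
the detector's amplitude baseline; a ripple concentrates power in few bins
and lowers the entropy.
"""
from __future__ import annotations

import numpy as np

from .types import InvalidConfigError

__all__ = ["stockwell_transform", "stockwell_power_profile", "stockwell_entropy"]


def stockwell_transform(
    x: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    df: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """S-transform of ``x`` restricted to [fmin, fmax].

    Returns ``(freqs, S)`` with ``S`` of shape (n_freqs, len(x)), complex.
    ``df`` sets the frequency sampling step (defaults to the FFT bin width
    fs/len(x)); analysis frequencies are FFT bins, so df is rounded to a
    multiple of the bin width.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise InvalidConfigError("signal too short for an S-transform")
    bin_width = fs / n
    step = 1 if df is None else max(1, int(round(df / bin_width)))
    kmin = max(1, int(np.ceil(fmin / bin_width)))
    kmax = min(n // 2, int(np.floor(fmax / bin_width)))
    if kmax < kmin:
        raise InvalidConfigError(
            f"no FFT bin inside [{fmin}, {fmax}] Hz for a {n}-sample window"
        )
    ks = np.arange(kmin, kmax + 1, step)
    X = np.fft.fft(x)
    # Voice k: shift spectrum by k and apply the Gaussian in the frequency
    # domain; m runs over FFT frequencies (wrapped).  Vectorized over voices
    # with a precomputed gather index (equivalent to np.roll(X, -k)).
    m = np.fft.fftfreq(n) * n  # integer frequency index per position
    pos = np.arange(n)
    idx = (pos[None, :] + ks[:, None]) % n
    windows = np.exp(-2.0 * np.pi**2 * m[None, :] ** 2 / ks[:, None] ** 2)
    S = np.fft.ifft(X[idx] * windows, axis=1)
    return ks * bin_width, S


def stockwell_power_profile(
    x: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    df: float | None = None,
    t_slice: slice | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged S-power per frequency, optionally over a time sub-span."""
    freqs, S = stockwell_transform(x, fs, fmin, fmax, df)
    P = np.abs(S) ** 2
    if t_slice is not None:
        P = P[:, t_slice]
    return freqs, P.mean(axis=1)


def stockwell_entropy(
    x: np.ndarray,
    fs: float,
    window_s: float,
    band: tuple[float, float] = (80.0, 250.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Shannon entropy of the normalized ripple-band S-spectrum per window.

    The signal is cut into non-overlapping windows of ``window_s`` seconds;
    for each, the time-averaged S-power across band frequencies is normalized
    to a probability distribution and its entropy (nats) returned.  Flat
    spectrum -> entropy near log(#bins); a dominant oscillation -> much lower.

    Returns ``(window_start_samples, entropies)``.
    """
    x = np.asarray(x, dtype=float)
    wlen = int(round(window_s * fs))
    if wlen < 2 * fs / band[0]:
        raise InvalidConfigError(
            f"entropy window must hold at least two {band[0]} Hz cycles"
        )
    n_win = x.size // wlen
    if n_win == 0:
        raise InvalidConfigError("signal shorter than one entropy window")
    starts = np.arange(n_win) * wlen
    ent = np.empty(n_win)
    for i, s in enumerate(starts):
        _, prof = stockwell_power_profile(x[s : s + wlen], fs, band[0], band[1])
        total = prof.sum()
        if total <= 0:
            ent[i] = np.log(prof.size)  # silent window: maximally uninformative
            continue
        p = prof / total
        nz = p[p > 0]
        ent[i] = float(-(nz * np.log(nz)).sum())
    return starts, ent
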