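"""Model-order selection from the respiration spectrum.

The embedding order L is chosen so the regressor window spans two periods of
a representative respiratory frequency Fr.  Fr is read off the Welch PSD of
the respiration: inside the band holding 90% of the spectral mass, take the
lowest-frequency local maximum when three or more maxima exist, otherwise the
global maximum; clamp to >= 0.1 Hz so L stays bounded (L <= 40 at 2 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .preprocess import PSD

__all__ = ["OrderSelection", "select_order"]


@dataclass
class OrderSelection:
    Fr: float            # representative respiratory frequency, Hz
    L: int               # embedding order, ceil(2 * fs / Fr)
    band: tuple[float, float]   # 90%-power band edges, Hz
    n_maxima: int        # strict local maxima found inside the band
    clamped: bool        # True when Fr was raised to the 0.1 Hz floor


def _power_band(freqs: np.ndarray, power: np.ndarray) -> tuple[int, int]:
    """Indices [i_lo, i_hi] of the band holding the central 90% of the mass.

    Defined by the 5th and 95th percentiles of the cumulative spectral mass —
    a symmetric 5% trim at each tail.
    """
    cum = np.cumsum(power)
    cum = cum / cum[-1]
    i_lo = int(np.searchsorted(cum, 0.05))
    i_hi = int(np.searchsorted(cum, 0.95))
    return i_lo, max(i_hi, i_lo)


def select_order(resp_psd: PSD, fs: float) -> OrderSelection:
    """Apply the two-periods-of-Fr rule to a respiration PSD.

    Parameters
    ----------
    resp_psd : PSD
        Welch estimate of the respiration epoch; >= 8 bins, positive total
        power.
    fs : float
        Sampling rate of the signals the order will be applied to (Hz).
    """
    f, p = resp_psd.freqs, resp_psd.power
    if len(f) < 8:
        raise ValueError("PSD too coarse: need at least 8 frequency bins")
    if not np.any(p > 0):
        raise ValueError("PSD has zero total power")

    i_lo, i_hi = _power_band(f, p)
    band = p[i_lo : i_hi + 1]
    # strict local maxima; plateaus credited to their leftmost bin
    pk, props = find_peaks(band, plateau_size=1)
    peak_idx = props["left_edges"] + i_lo

    if len(peak_idx) >= 3:
        fr = float(f[peak_idx[0]])  # lowest-frequency maximum
    else:
        fr = float(f[i_lo + int(np.argmax(band))])

    clamped = fr < 0.1
    if clamped:
        fr = 0.1
    L = math.ceil(2 * fs / fr)
    return OrderSelection(
        Fr=fr, L=L, band=(float(f[i_lo]), float(f[i_hi])),
        n_maxima=int(len(peak_idx)), clamped=clamped,
    )
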