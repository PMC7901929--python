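"""Signal conditioning for cardiorespiratory coupling analysis.

Converts raw R-peak (or RR-interval) input and respiration recordings to the
uniform representation the coupling estimators expect: a 2 Hz tachogram and a
2 Hz respiration channel, both band-limited to 0.03-1 Hz with a zero-phase
Butterworth filter, cut into 5-min epochs.  Also provides the Welch spectral
estimate (Hamming taper, 40 s windows, 20 s overlap) used for model-order
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

logger = logging.getLogger(__name__)

__all__ = [
    "UniformSignal",
    "RPeakSeries",
    "Epoch",
    "PSD",
    "tachogram_from_rpeaks",
    "bandpass",
    "resample",
    "segment_epochs",
    "welch_psd",
    "read_signal_csv",
    "write_signal_csv",
    "read_event_times",
]


@dataclass
class UniformSignal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : ndarray
        Signal values; must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text channel label (e.g. ``"resp"``, ``"hrv"``).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in signal {self.label!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs


@dataclass
class RPeakSeries:
    """R-peak occurrence times in seconds, strictly increasing.

    Consecutive differences outside (0.2, 4.0) s — beats faster than 300 bpm
    or pauses longer than 4 s — mark the record as suspect via
    ``quality_ok``; conversion still proceeds.
    """

    peak_times: np.ndarray
    quality_ok: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.ndim != 1:
            raise ValueError("peak_times must be one-dimensional")
        d = np.diff(self.peak_times)
        if len(d) and not np.all(d > 0):
            raise ValueError("peak times must be strictly increasing")
        if len(d) and (np.any(d <= 0.2) or np.any(d >= 4.0)):
            self.quality_ok = False
            logger.warning(
                "RR intervals outside (0.2, 4.0) s; record flagged as suspect"
            )

    @classmethod
    def from_rr_intervals(cls, rr: np.ndarray, t0: float = 0.0) -> "RPeakSeries":
        """Build peak times from an RR-interval sequence (seconds)."""
        rr = np.asarray(rr, dtype=float)
        return cls(peak_times=t0 + np.concatenate([[0.0], np.cumsum(rr)]))


@dataclass
class Epoch:
    """One paired respiration/HRV segment (default 5 min at 2 Hz)."""

    resp: UniformSignal
    hrv: UniformSignal
    start_time: float = 0.0
    quality_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.resp.fs != self.hrv.fs:
            raise ValueError("resp and hrv must share the sampling rate")
        if len(self.resp) != len(self.hrv):
            raise ValueError("resp and hrv must have equal length")

    @property
    def fs(self) -> float:
        return self.resp.fs


@dataclass
class PSD:
    """One-sided power spectral density estimate."""

    freqs: np.ndarray
    power: np.ndarray
    total_power: float = field(init=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        self.total_power = float(np.trapezoid(self.power, self.freqs))


def tachogram_from_rpeaks(peaks: RPeakSeries, fs_out: float = 2.0) -> UniformSignal:
    """Interpolate the RR-interval series onto a uniform grid.

    Each RR value (seconds) is anchored at the time of the interval's closing
    peak; a cubic spline through these anchors is evaluated on a uniform grid
    at ``fs_out`` spanning the anchored range.

    Parameters
    ----------
    peaks : RPeakSeries
        At least 3 peak times.
    fs_out : float
        Output sampling rate in Hz (default 2).
    """
    t = peaks.peak_times
    if len(t) < 3:
        raise ValueError("at least 3 R-peaks are required")
    rr = np.diff(t)
    anchors = t[1:]  # closing peak of each interval
    spline = interpolate.CubicSpline(anchors, rr)
    n_out = int(np.floor((anchors[-1] - anchors[0]) * fs_out)) + 1
    grid = anchors[0] + np.arange(n_out) / fs_out
    return UniformSignal(samples=spline(grid), fs=fs_out, label="hrv")


def _design_bandpass(fs: float, low: float, high: float, order: int):
    """Return (b, a); degrade to high-pass at the Nyquist edge.

    At fs = 2 Hz the canonical 1 Hz upper edge coincides with Nyquist, where a
    band-pass is ill-posed and the low-pass half is vacuous (no energy exists
    above it); in that case only the high-pass half is applied.
    """
    nyq = fs / 2.0
    if high >= 0.95 * nyq:
        logger.info(
            "upper band edge %.3g Hz at/above 0.95*Nyquist (%.3g Hz); "
            "applying high-pass at %.3g Hz only",
            high, nyq, low,
        )
        return signal.butter(order, low, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(
    sig: UniformSignal, low: float = 0.03, high: float = 1.0, order: int = 4
) -> UniformSignal:
    """Zero-phase Butterworth band-pass (forward-backward application).

    Defaults preserve 0.03-1 Hz, covering the VLF tail through the maximal
    respiratory band at a 2 Hz sampling rate.  The edge padding is stretched
    well beyond scipy's default (up to 600 samples) because the 0.03 Hz edge
    puts poles close to the unit circle: short pads leave edge transients
    that also break the time-reversal symmetry of the zero-phase result.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = _design_bandpass(sig.fs, low, high, order)
    startup = 3 * (2 * sos.shape[0] + 1)
    if len(sig) <= 3 * startup:
        raise ValueError(
            f"signal of {len(sig)} samples too short for filter startup "
            f"({3 * startup} required)"
        )
    padlen = min(len(sig) - 1, 600)
    out = signal.sosfiltfilt(sos, sig.samples, padlen=padlen)
    return UniformSignal(samples=out, fs=sig.fs, label=sig.label)


def resample(sig: UniformSignal, fs_out: float = 2.0) -> UniformSignal:
    """Anti-aliased conversion to ``fs_out``.

    An 8th-order Butterworth low-pass at 0.8 * (fs_out / 2), applied
    zero-phase, precedes linear interpolation onto the new grid.  Used for
    respiration channels recorded at a higher rate.  Upsampling skips the
    anti-alias stage.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    x = sig.samples
    if fs_out < sig.fs:
        sos = signal.butter(8, 0.8 * fs_out / 2.0, btype="lowpass",
                            fs=sig.fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    t_in = np.arange(len(x)) / sig.fs
    n_out = int(np.floor(t_in[-1] * fs_out)) + 1
    t_out = np.arange(n_out) / fs_out
    return UniformSignal(samples=np.interp(t_out, t_in, x), fs=fs_out,
                         label=sig.label)


def segment_epochs(
    resp: UniformSignal, hrv: UniformSignal, epoch_s: float = 300.0
) -> list[Epoch]:
    """Cut the paired record into consecutive non-overlapping epochs.

    Epochs are half-open ``[k*epoch_s, (k+1)*epoch_s)`` starting at sample 0;
    a trailing remainder shorter than one epoch is dropped.  A record shorter
    than one epoch yields an empty list.
    """
    if resp.fs != hrv.fs:
        raise ValueError("resp and hrv must share the sampling rate")
    if len(resp) != len(hrv):
        raise ValueError("resp and hrv must have equal length")
    n_ep = int(round(epoch_s * resp.fs))
    epochs = []
    for k in range(len(resp) // n_ep):
        sl = slice(k * n_ep, (k + 1) * n_ep)
        epochs.append(
            Epoch(
                resp=UniformSignal(resp.samples[sl], resp.fs, resp.label),
                hrv=UniformSignal(hrv.samples[sl], hrv.fs, hrv.label),
                start_time=k * n_ep / resp.fs,
            )
        )
    return epochs


def welch_psd(
    sig: UniformSignal, window_s: float = 40.0, overlap_s: float = 20.0
) -> PSD:
    """Welch PSD with a Hamming taper (defaults: 40 s windows, 20 s overlap)."""
    nperseg = int(round(window_s * sig.fs))
    noverlap = int(round(overlap_s * sig.fs))
    if len(sig) < nperseg:
        raise ValueError(
            f"signal of {len(sig)} samples shorter than one {nperseg}-sample window"
        )
    freqs, power = signal.welch(
        sig.samples, fs=sig.fs, window="hamming",
        nperseg=nperseg, noverlap=noverlap, detrend="constant",
    )
    return PSD(freqs=freqs, power=power)


# ---------------------------------------------------------------------------
# plain-text I/O: two-column CSV (time_s,value) for signals, one value per
# line for peak times or RR intervals.  Times in seconds throughout.

def read_signal_csv(path) -> UniformSignal:
    """Read a two-column ``time_s,value`` CSV with a header row.

    The time column must be uniformly spaced; the sampling rate is inferred
    from it.
    """
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns time_s,value")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if len(dt) < 1 or np.ptp(dt) > 1e-6 * np.median(dt):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return UniformSignal(samples=v, fs=1.0 / float(np.median(dt)))


def write_signal_csv(path, sig: UniformSignal, t0: float = 0.0) -> None:
    t = t0 + np.arange(len(sig)) / sig.fs
    np.savetxt(path, np.column_stack([t, sig.samples]), delimiter=",",
               header="time_s,value", comments="")


def read_event_times(path, rr: bool = False) -> RPeakSeries:
    """Read peak times (default) or RR intervals (``rr=True``), seconds."""
    vals = np.atleast_1d(np.genfromtxt(path, dtype=float))
    if rr:
        return RPeakSeries.from_rr_intervals(vals)
    return RPeakSeries(peak_times=vals)
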