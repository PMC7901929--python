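"""Synthetic cardiorespiratory epochs with known ground-truth coupling.

Real polysomnographic epochs cannot be redistributed, so the pipeline is
exercised on generated 5-min, 2 Hz epochs that emulate their structure:

* respiration is either *narrowband* — a sinusoid around a nominal breathing
  frequency (default 0.25 Hz, i.e. 15 breaths/min) with slow 5% frequency
  jitter plus 5% measurement noise — or *broadband*, 0.1-0.6 Hz band-limited
  Gaussian noise mimicking the irregular, spectrally flat breathing seen
  during apneic episodes;
* HRV receives a linear drive (gain_linear times the lag-1 respiration), a
  quadratic drive (gain_quadratic times the mean-removed squared lag-1
  respiration), low-frequency noise confined to the 0.04-0.15 Hz LF band
  standing in for non-respiratory autonomic modulation, and a small
  white-noise floor.

Respiration is standardized to unit variance before the drives are applied,
so the gains are directly comparable across modes.  Both channels then pass
through the standard zero-phase band-pass, exactly as real recordings would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import Epoch, UniformSignal, bandpass

__all__ = ["EpochSpec", "generate_epoch"]


@dataclass
class EpochSpec:
    """Ground-truth recipe for one synthetic epoch."""

    resp_mode: str = "narrowband"   # or 'broadband'
    resp_freq: float = 0.25         # Hz, narrowband carrier
    gain_linear: float = 1.0
    gain_quadratic: float = 0.0
    noise_lf: float = 0.3           # LF-band HRV noise amplitude
    n_samples: int = 600            # 5 min at 2 Hz
    fs: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resp_mode not in ("narrowband", "broadband"):
            raise ValueError(f"unknown resp_mode {self.resp_mode!r}")
        if self.resp_mode == "narrowband" and not 0.1 < self.resp_freq < 0.5:
            raise ValueError("narrowband resp_freq must lie in (0.1, 0.5) Hz")
        if self.gain_linear < 0 or self.gain_quadratic < 0 or self.noise_lf < 0:
            raise ValueError("gains and noise amplitudes must be non-negative")
        if self.n_samples < 128:
            raise ValueError("epoch too short for a stable analysis")


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [low, high] Hz."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    # extra lead-in shields the epoch from filter transients
    x = sps.sosfilt(sos, rng.standard_normal(n + 512))[512:]
    return x / x.std()


def generate_epoch(spec: EpochSpec) -> tuple[Epoch, dict]:
    """Generate one epoch and its ground-truth metadata.

    Returns the band-passed (resp, hrv) pair and a dict recording the gains
    actually injected, for downstream verification.
    """
    rng = np.random.default_rng(spec.seed)
    n, fs = spec.n_samples, spec.fs

    if spec.resp_mode == "narrowband":
        # 5% slow frequency jitter via an integrated low-pass modulator
        mod = _bandlimited_noise(rng, n, fs, 0.005, 0.05)
        inst_freq = spec.resp_freq * (1.0 + 0.05 * mod)
        phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs
        resp = np.sin(phase) + 0.05 * rng.standard_normal(n)
    else:
        resp = _bandlimited_noise(rng, n, fs, 0.1, 0.6)
    resp = (resp - resp.mean()) / resp.std()

    r1 = np.concatenate([[0.0], resp[:-1]])      # lag-1 respiration
    quad = r1 ** 2
    quad -= quad.mean()
    hrv = (
        spec.gain_linear * r1
        + spec.gain_quadratic * quad
        + spec.noise_lf * _bandlimited_noise(rng, n, fs, 0.04, 0.15)
        + 0.05 * rng.standard_normal(n)
    )

    resp_f = bandpass(UniformSignal(resp, fs, "resp")).samples
    hrv_f = bandpass(UniformSignal(hrv, fs, "hrv")).samples
    # finite epochs of band-passed noise retain a small sample mean; remove
    # it so downstream variance ratios see exactly centered channels
    resp_sig = UniformSignal(resp_f - resp_f.mean(), fs, "resp")
    hrv_sig = UniformSignal(hrv_f - hrv_f.mean(), fs, "hrv")
    truth = {
        "resp_mode": spec.resp_mode,
        "gain_linear": spec.gain_linear,
        "gain_quadratic": spec.gain_quadratic,
        "noise_lf": spec.noise_lf,
        "seed": spec.seed,
    }
    return Epoch(resp=resp_sig, hrv=hrv_sig), truth
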