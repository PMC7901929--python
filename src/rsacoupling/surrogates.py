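"""Multivariate surrogate data and the nonlinearity significance test.

A surrogate pair must be consistent with the null hypothesis of a purely
linear (Gaussian) interaction: each channel keeps its amplitude distribution
and autocorrelation, and the pair keeps its cross-correlation, while any
nonlinear structure is destroyed.  This is achieved by adding one common
random phase vector to the Fourier phases of both channels (a shared
increment leaves the cross-spectrum — hence the cross-correlation — intact)
followed by per-channel iterative amplitude adjustment (IAAFT) so each
surrogate's sorted values equal the original channel's values exactly.

The significance test recomputes the RBF coupling index Pxk on n_surrogates
(default 24) such pairs, each traversing the identical tuning pipeline as the
original; the original is declared significantly nonlinear when it exceeds
the empirical 95th quantile of the surrogate values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .svr_coupling import (KernelSpec, TuningParams, build_design, fit,
                           predict_in_sample, tune_c_epsilon, tune_sigma2)

logger = logging.getLogger(__name__)

__all__ = ["SurrogateVerdict", "surrogate_pair", "nonlinearity_test"]

_MIN_LEN = 64  # below this the spectral estimates behind the null are unreliable


@dataclass
class SurrogateVerdict:
    """Outcome of the surrogate nonlinearity test for one epoch."""

    pxk_original: float
    pxk_surrogates: np.ndarray
    threshold: float          # empirical 95th quantile of the surrogate values
    significant: bool         # pxk_original > threshold
    n_failed: int = 0


def _rank_remap(cur: np.ndarray, target_sorted: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    ranks = np.argsort(np.argsort(cur, kind="stable"), kind="stable")
    return target_sorted[ranks], ranks


def surrogate_pair(
    x: np.ndarray, y: np.ndarray,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """One multivariate amplitude-adjusted phase-randomized surrogate pair.

    Initialization adds one conjugate-symmetric random phase vector (DC and
    Nyquist untouched) to the Fourier phases of BOTH channels.  The joint
    IAAFT refinement then alternates (i) an amplitude step that rank-remaps
    each channel onto its original sorted values and (ii) a spectrum step
    that restores the original Fourier amplitudes with phases of the form
    "original + a common per-frequency rotation", the rotation chosen
    closest to the current phases of both channels.  The surrogate phases
    therefore always differ from the originals by one shared vector, which
    preserves the cross-spectrum (hence the cross-correlation) exactly,
    while each channel keeps its amplitude multiset exactly.  Iteration
    stops at rank convergence of both channels or at ``max_iter``; the last
    step is always the amplitude remap.  Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("channels must have equal length")
    n = len(x)
    if n < _MIN_LEN:
        raise ValueError(f"need at least {_MIN_LEN} samples, got {n}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_freq = n // 2 + 1

    spec_x, spec_y = np.fft.rfft(x), np.fft.rfft(y)
    amp_x, amp_y = np.abs(spec_x), np.abs(spec_y)
    phi_x, phi_y = np.angle(spec_x), np.angle(spec_y)
    sorted_x, sorted_y = np.sort(x), np.sort(y)

    def rebuild(psi):
        psi = psi.copy()
        psi[0] = 0.0
        if n % 2 == 0:
            psi[-1] = 0.0
        cx = np.fft.irfft(amp_x * np.exp(1j * (phi_x + psi)), n)
        cy = np.fft.irfft(amp_y * np.exp(1j * (phi_y + psi)), n)
        return cx, cy

    cur_x, cur_y = rebuild(rng.uniform(0.0, 2.0 * np.pi, n_freq))
    prev = None
    for _ in range(max_iter):
        cur_x, rx = _rank_remap(cur_x, sorted_x)
        cur_y, ry = _rank_remap(cur_y, sorted_y)
        if prev is not None and np.array_equal(rx, prev[0]) \
                and np.array_equal(ry, prev[1]):
            break
        prev = (rx, ry)
        theta_x = np.angle(np.fft.rfft(cur_x))
        theta_y = np.angle(np.fft.rfft(cur_y))
        # common rotation closest to both channels' phase drifts, weighted
        # by spectral power (least-squares in signal space)
        psi = np.angle(amp_x ** 2 * np.exp(1j * (theta_x - phi_x))
                       + amp_y ** 2 * np.exp(1j * (theta_y - phi_y)))
        cur_x, cur_y = rebuild(psi)
    else:
        cur_x, _ = _rank_remap(cur_x, sorted_x)
        cur_y, _ = _rank_remap(cur_y, sorted_y)
    return cur_x, cur_y


def _pxk(resp: np.ndarray, hrv: np.ndarray, L: int, fs: float) -> float:
    design = build_design(resp, hrv, L, fs=fs)
    c, eps = tune_c_epsilon(design.y)
    s2 = tune_sigma2(design.X)
    tuning = TuningParams(c=c, epsilon=eps, sigma2=s2)
    model = fit(design, KernelSpec("rbf", sigma2=s2), tuning)
    yc = design.y - design.y.mean()
    yk = predict_in_sample(model) - design.y.mean()
    return float(yk @ yk) / float(yc @ yc)


def nonlinearity_test(
    resp: np.ndarray, hrv: np.ndarray, fs: float, L: int,
    n_surrogates: int = 24, seed: int = 0,
) -> SurrogateVerdict:
    """Surrogate test for a nonlinear component in the coupling.

    Pxk is computed on the original pair and on each surrogate pair with the
    same embedding order L; the bandwidth, regularization and tube width are
    re-tuned per surrogate so every surrogate traverses the identical
    pipeline.  Failed surrogate fits are dropped (and logged); the verdict
    requires at least ceil(5/6 * n_surrogates) successes.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be positive")
    resp = np.asarray(resp, dtype=float)
    hrv = np.asarray(hrv, dtype=float)
    pxk_orig = _pxk(resp, hrv, L, fs)
    rng = np.random.default_rng(seed)
    vals = []
    n_failed = 0
    for _ in range(n_surrogates):
        xs, ys = surrogate_pair(resp, hrv, seed=rng)
        try:
            vals.append(_pxk(xs, ys, L, fs))
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            logger.warning("surrogate fit failed: %s", exc)
    required = int(np.ceil(n_surrogates * 5.0 / 6.0))
    if len(vals) < required:
        raise RuntimeError(
            f"only {len(vals)}/{n_surrogates} surrogate fits succeeded "
            f"(need {required})"
        )
    vals = np.asarray(vals)
    threshold = float(np.quantile(vals, 0.95))
    return SurrogateVerdict(
        pxk_original=pxk_orig, pxk_surrogates=vals, threshold=threshold,
        significant=bool(pxk_orig > threshold), n_failed=n_failed,
    )
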