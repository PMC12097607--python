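"""Wavelet-threshold denoising of motion signals, plus a low-pass utility.

Pipeline: multi-level DWT -> noise-sd estimate from the finest detail level
(median absolute deviation / 0.6745) -> universal threshold
lambda = sigma sqrt(2 ln N) -> soft (or hard) coefficient shrinkage ->
inverse transform.  Defaults: Daubechies-4, 5 levels, symmetric boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.signal import butter, filtfilt

from .sim import ImuSeries


@dataclass(frozen=True)
class WaveletConfig:
    wavelet: str = "db4"
    levels: int = 5
    mode: str = "symmetric"
    threshold_mode: str = "soft"  # soft | hard
    sigma: float | None = None    # override the MAD noise estimate

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError(f"threshold_mode must be soft or hard, got {self.threshold_mode!r}")


@dataclass
class WaveletDecomposition:
    """Coefficient pyramid: [approx, detail_L, ..., detail_1] plus the length."""

    coeffs: list
    length: int
    config: WaveletConfig

    @property
    def approx(self) -> np.ndarray:
        return self.coeffs[0]

    @property
    def details(self) -> list:
        return self.coeffs[1:]


def decompose(signal: np.ndarray, cfg: WaveletConfig | None = None) -> WaveletDecomposition:
    """Multi-level discrete wavelet transform of a 1-D signal."""
    cfg = cfg or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("decompose expects a 1-D signal")
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(cfg.wavelet).dec_len)
    if cfg.levels > max_level:
        raise ValueError(
            f"signal of length {len(x)} supports at most {max_level} levels "
            f"for {cfg.wavelet}, requested {cfg.levels}"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet, mode=cfg.mode, level=cfg.levels)
    return WaveletDecomposition(coeffs=coeffs, length=len(x), config=cfg)


def universal_threshold(sigma: float, n: int) -> float:
    """Universal threshold lambda = sigma sqrt(2 ln N)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 2:
        raise ValueError("N must be >= 2")
    return float(sigma) * math.sqrt(2.0 * math.log(n))


def estimate_sigma(detail: np.ndarray) -> float:
    """Robust noise-sd estimate from detail coefficients: MAD / 0.6745."""
    d = np.asarray(detail, dtype=float)
    if d.size == 0:
        raise ValueError("empty coefficient array")
    return float(np.median(np.abs(d - np.median(d))) / 0.6745)


def threshold_coeffs(
    dec: WaveletDecomposition, lam: float, mode: str = "soft"
) -> WaveletDecomposition:
    """Shrink detail coefficients; approximation coefficients are untouched.

    soft: d = sign(p) max(|p| - lambda, 0); hard: d = p 1[|p| > lambda].
    """
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    new = [dec.coeffs[0].copy()]
    for d in dec.details:
        # lam == 0 is the identity; pywt's soft rule would hit 0/0 on zeros
        new.append(d.copy() if lam == 0 else pywt.threshold(d, lam, mode=mode))
    return WaveletDecomposition(coeffs=new, length=dec.length, config=dec.config)


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse transform, trimmed to the original signal length."""
    try:
        y = pywt.waverec(dec.coeffs, dec.config.wavelet, mode=dec.config.mode)
    except ValueError as exc:
        raise ValueError(f"inconsistent coefficient shapes: {exc}") from exc
    return y[: dec.length]


def denoise_signal(signal: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """One-shot wavelet denoising of a 1-D signal."""
    cfg = cfg or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(cfg.wavelet).dec_len)
    if max_level < 1:
        return x.copy()
    if cfg.levels > max_level:
        cfg = replace(cfg, levels=max_level)
    dec = decompose(x, cfg)
    sigma = cfg.sigma if cfg.sigma is not None else estimate_sigma(dec.details[-1])
    lam = universal_threshold(sigma, len(x))
    return reconstruct(threshold_coeffs(dec, lam, cfg.threshold_mode))


def denoise_imu(
    series: ImuSeries, cfg: WaveletConfig | None = None, channels: str = "all"
) -> ImuSeries:
    """Column-wise wavelet denoising of an IMU stream.

    channels: 'gyro', 'accel' or 'all'.
    """
    accel = series.accel.copy()
    gyro = series.gyro.copy()
    if channels in ("gyro", "all"):
        gyro = np.column_stack([denoise_signal(gyro[:, i], cfg) for i in range(3)])
    if channels in ("accel", "all"):
        accel = np.column_stack([denoise_signal(accel[:, i], cfg) for i in range(3)])
    if channels not in ("gyro", "accel", "all"):
        raise ValueError(f"channels must be gyro/accel/all, got {channels!r}")
    return ImuSeries(t=series.t.copy(), accel=accel, gyro=gyro)


def lowpass(signal: np.ndarray, cutoff_hz: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    Removes high-frequency content (sensor noise, soft-tissue oscillation)
    while preserving the low-frequency joint motion band.
    """
    if not 0 < cutoff_hz < rate / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={rate / 2})")
    b, a = butter(order, cutoff_hz, fs=rate)
    return filtfilt(b, a, np.asarray(signal, float), axis=0)


def lowpass_imu(series: ImuSeries, cutoff_hz: float, order: int = 4) -> ImuSeries:
    """Zero-phase low-pass of all six IMU channels."""
    return ImuSeries(
        t=series.t.copy(),
        accel=lowpass(series.accel, cutoff_hz, series.rate, order),
        gyro=lowpass(series.gyro, cutoff_hz, series.rate, order),
    )


def snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Signal-to-noise ratio of ``noisy`` against the known clean signal, dB."""
    clean = np.asarray(clean, float)
    noisy = np.asarray(noisy, float)
    err = noisy - clean
    return float(10.0 * np.log10(np.sum(clean**2) / np.sum(err**2)))
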