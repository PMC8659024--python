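"""Synthetic MRM chromatograms and signal-to-noise based detection.

Emulates a dilution-series detection-limit experiment: a Gaussian elution
peak whose area is proportional to the injected amount through a tag-dependent
response factor, on an additive baseline with white Gaussian noise.  A peak is
"detected" when its signal-to-noise ratio, estimated robustly from the
out-of-peak region, reaches a threshold (3:1 by default — the conventional
detection-limit criterion).

All randomness is driven by explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimParams",
    "Chromatogram",
    "simulate_trace",
    "estimate_snr",
    "apex_at",
    "detect",
    "lod_from_series",
    "fit_calibration",
]


@dataclass(frozen=True)
class SimParams:
    """Generating parameters for one simulated MRM trace.

    amount : injected amount, mol
    response_factor : peak area per mol of analyte (intensity·s/mol);
        fixed-charge tagging raises this by orders of magnitude
    rt : retention time of the peak apex, s
    peak_sigma : Gaussian peak width, s
    noise_sd : standard deviation of additive baseline noise, intensity units
    baseline : constant baseline offset, intensity units
    duration : trace length, s
    sample_interval : sampling period, s (must resolve the peak)
    seed : RNG seed for the noise realization
    """

    amount: float
    response_factor: float
    rt: float = 300.0
    peak_sigma: float = 5.0
    noise_sd: float = 1.0
    baseline: float = 10.0
    duration: float = 600.0
    sample_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.response_factor <= 0:
            raise ValueError("response_factor must be > 0")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("sample_interval and duration must be > 0")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        if self.sample_interval >= self.peak_sigma:
            raise ValueError("sample_interval must be smaller than peak_sigma")
        if self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("noise_sd and baseline must be >= 0")


@dataclass(frozen=True)
class Chromatogram:
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


def simulate_trace(params: SimParams) -> Chromatogram:
    """Gaussian peak + baseline + white noise, reproducible from the seed.

    intensity(t) = baseline + amount·response_factor·N(t; rt, σ) + ε,
    ε ~ Normal(0, noise_sd), with N the unit-area Gaussian kernel so that
    amount·response_factor is the peak *area*.
    """
    t = np.arange(0.0, params.duration, params.sample_interval)
    signal = params.baseline + params.amount * params.response_factor * stats.norm.pdf(
        t, loc=params.rt, scale=params.peak_sigma
    )
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd, size=t.shape) if params.noise_sd > 0 else 0.0
    return Chromatogram(times=t, intensities=signal + noise)


def _window_mask(trace: Chromatogram, peak_window: tuple[float, float]) -> np.ndarray:
    lo, hi = peak_window
    if hi <= lo:
        raise ValueError("empty peak window")
    return (trace.times >= lo) & (trace.times <= hi)


def estimate_snr(trace: Chromatogram, peak_window: tuple[float, float]) -> float:
    """(apex − baseline) / noise, with robust out-of-window estimates.

    Baseline is the median of points outside the window; noise is
    1.4826 × MAD of the same points (the normal-consistent robust scale, so
    the peak leaking slightly into the baseline region does not inflate it).
    The apex is the in-window maximum of a 3-point moving average: without
    the light smoothing the max-order statistic of the raw noise would both
    trigger on blanks and add an amount-independent bonus to real peaks.
    """
    mask = _window_mask(trace, peak_window)
    outside = trace.intensities[~mask]
    if not mask.any():
        raise ValueError("empty peak window")
    if outside.size < 20:
        raise ValueError("need >= 20 points outside the peak window")
    baseline = float(np.median(outside))
    noise = 1.4826 * float(np.median(np.abs(outside - baseline)))
    if noise == 0.0:
        raise ValueError("noise indeterminate")
    smoothed = np.convolve(trace.intensities, np.ones(3) / 3.0, mode="same")
    apex = float(smoothed[mask].max())
    return (apex - baseline) / noise


def apex_at(trace: Chromatogram, t: float) -> float:
    """Intensity at the sample nearest ``t``.

    The apex reader for calibration: evaluated at the known retention time it
    carries only the (mean-zero) noise of a single sample, unlike the
    max-over-window statistic whose noise bonus shrinks as the peak grows and
    would bias a fitted response slope.
    """
    idx = int(np.argmin(np.abs(trace.times - t)))
    return float(trace.intensities[idx])


def detect(trace: Chromatogram, peak_window: tuple[float, float], threshold: float = 3.0) -> bool:
    """True iff the window's S/N is at least ``threshold`` (default 3:1)."""
    return estimate_snr(trace, peak_window) >= threshold


def lod_from_series(
    amounts: Sequence[float],
    template: SimParams,
    replicates: int = 3,
    seed: int = 0,
    threshold: float = 3.0,
    window_sigmas: float = 3.0,
) -> float | None:
    """Limit of detection from a descending dilution series.

    Walks the amounts from largest to smallest, simulating ``replicates``
    independent traces per level; the LOD is the smallest amount for which
    every replicate at that level and at every larger level is detected
    (all-replicates rule).  Returns None if nothing is detected.
    Deterministic given ``seed``.
    """
    amounts = list(amounts)
    if sorted(amounts, reverse=True) != amounts:
        raise ValueError("amounts must be in descending order")
    window = (
        template.rt - window_sigmas * template.peak_sigma,
        template.rt + window_sigmas * template.peak_sigma,
    )
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(amounts) * replicates)]
    lod: float | None = None
    k = 0
    for amount in amounts:
        all_detected = True
        for _ in range(replicates):
            params = replace(template, amount=amount, seed=child_seeds[k])
            k += 1
            if not detect(simulate_trace(params), window, threshold):
                all_detected = False
        if not all_detected:
            break
        lod = amount
    return lod


def fit_calibration(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Ordinary least squares of apex intensity on amount → (slope, intercept, R²)."""
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("calibration amounts are all identical")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
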