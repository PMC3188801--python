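"""Haar wavelet analysis of ancestry signals.

A signal of length 2^L is decomposed onto the orthogonal basis of 2^L − 1
rectangular Haar wavelets plus the constant vector.  A wavelet at level l
(l = 1..L) has support 2^(L−l+1) samples, amplitude 1 and zero mean, so the
level indexes frequency: a square wave whose half-period is a fraction
p of the signal length concentrates its energy at level l = log2(1/p).

The transform here keeps the averaging normalization in which a coefficient
equals the mean contrast of the signal over the wavelet's two half-supports
(divide-by-2 cascade), so coefficients are directly comparable across
levels as block-amplitude measurements.  The noise model for admixture
signals treats low-amplitude coefficients and the highest-frequency levels
as noise; filtering is hard amplitude thresholding, a level cutoff, and
subtraction of a per-level parental baseline from the level summary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WaveletSpectrum",
    "LevelSummary",
    "NoiseFilterSpec",
    "haar_transform",
    "inverse_haar",
    "haar_wavelet",
    "threshold_filter",
    "drop_high_levels",
    "default_max_level",
    "wavelet_summary",
    "subtract_baseline",
    "wavelet_center",
    "normalize_center",
    "estimate_noise_filter",
    "filtered_center",
]


@dataclass
class WaveletSpectrum:
    """Haar coefficients of a length-2^L signal.

    ``coeffs[l-1]`` holds the 2^(l−1) coefficients of level l; ``average``
    is the signal mean (the final low-pass output).  ``length_morgans``
    carries the genetic length of the source signal for later
    chromosome-length normalization of the center statistic.
    """

    coeffs: list[np.ndarray]
    average: float
    length_morgans: float | None = None

    @property
    def levels(self) -> int:
        return len(self.coeffs)

    @property
    def coefficient_count(self) -> int:
        return sum(c.size for c in self.coeffs)

    def copy(self) -> "WaveletSpectrum":
        return WaveletSpectrum([c.copy() for c in self.coeffs], self.average,
                               self.length_morgans)

    def validate(self) -> None:
        for l, c in enumerate(self.coeffs, start=1):
            if c.size != 2 ** (l - 1):
                raise ValueError(
                    f"level {l} must hold {2 ** (l - 1)} coefficients, got {c.size}"
                )


@dataclass
class LevelSummary:
    """Per-level mean absolute coefficient s_l and the data needed to
    normalize the derived center statistic."""

    s: np.ndarray
    length_morgans: float | None = None

    @property
    def total(self) -> float:
        return float(self.s.sum())


def _check_power_of_two(n: int) -> int:
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(f"signal length must be a power of two, got {n}")
    return n.bit_length() - 1


def haar_transform(signal, length_morgans: float | None = None) -> WaveletSpectrum:
    """Haar wavelet transform by the divide-by-2 filter cascade.

    At each stage the signal is split into a low-pass half
    (γ'_k = (γ_{2k−1} + γ_{2k})/2) and the detail coefficients of the
    current finest level (wt = (γ_{2k−1} − γ_{2k})/2, signed so that a
    wavelet equal to +1 on the first half of its support has coefficient
    +1); the cascade recurses on the low-pass half down to the signal mean.
    """
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(g)):
        raise ValueError("signal must be finite")
    L = _check_power_of_two(g.size)
    coeffs: list[np.ndarray] = [np.empty(0)] * L
    for l in range(L, 0, -1):
        coeffs[l - 1] = (g[0::2] - g[1::2]) / 2.0
        g = (g[0::2] + g[1::2]) / 2.0
    return WaveletSpectrum(coeffs, float(g[0]), length_morgans)


def inverse_haar(spec: WaveletSpectrum) -> np.ndarray:
    """Reconstruct the signal; exact inverse of :func:`haar_transform`."""
    spec.validate()
    g = np.array([spec.average])
    for l in range(1, spec.levels + 1):
        wt = spec.coeffs[l - 1]
        out = np.empty(2 * g.size)
        out[0::2] = g + wt
        out[1::2] = g - wt
        g = out
    return g


def haar_wavelet(L: int, l: int, p: int) -> np.ndarray:
    """The basis wavelet ω_{l,p} of a length-2^L space: a rectangular wave
    of amplitude 1 and zero mean, +1 on the first half of its support."""
    if not (1 <= l <= L):
        raise ValueError("level out of range")
    if not (1 <= p <= 2 ** (l - 1)):
        raise ValueError("position out of range")
    n = 2 ** L
    half = 2 ** (L - l)
    start = (p - 1) * 2 * half
    w = np.zeros(n)
    w[start : start + half] = 1.0
    w[start + half : start + 2 * half] = -1.0
    return w


def _broadcast_thresholds(spec: WaveletSpectrum, thresholds) -> list[np.ndarray]:
    L = spec.levels
    if np.isscalar(thresholds):
        t = [np.full(2 ** (l - 1), float(thresholds)) for l in range(1, L + 1)]
    else:
        seq = list(thresholds)
        if len(seq) != L:
            raise ValueError(f"expected {L} per-level thresholds, got {len(seq)}")
        t = []
        for l, tl in enumerate(seq, start=1):
            arr = np.asarray(tl, dtype=float)
            if arr.ndim == 0:
                arr = np.full(2 ** (l - 1), float(arr))
            elif arr.size != 2 ** (l - 1):
                raise ValueError(f"level {l} threshold layout mismatch")
            t.append(arr)
    for arr in t:
        if np.any(arr < 0):
            raise ValueError("thresholds must be non-negative")
    return t


def threshold_filter(spec: WaveletSpectrum, thresholds) -> WaveletSpectrum:
    """Hard amplitude threshold: zero every coefficient with |wt| <= t.

    ``thresholds`` may be a scalar, one value per level, or a full
    per-coefficient layout; the signal average is untouched.
    """
    t = _broadcast_thresholds(spec, thresholds)
    out = spec.copy()
    for l in range(spec.levels):
        c = out.coeffs[l]
        c[np.abs(c) <= t[l]] = 0.0
    return out


def default_max_level(L: int) -> int:
    """Default high-frequency cutoff: keep levels 1..L−3 (7 when L = 10)."""
    return max(1, L - 3)


def drop_high_levels(spec: WaveletSpectrum, max_level: int) -> WaveletSpectrum:
    """Zero all coefficients at levels above ``max_level`` (noise removal:
    wavelets narrower than the resolution the data supports)."""
    if not (1 <= max_level <= spec.levels):
        raise ValueError(f"max_level must lie in [1, {spec.levels}]")
    out = spec.copy()
    for l in range(max_level, spec.levels):
        out.coeffs[l][:] = 0.0
    return out


def wavelet_summary(spec: WaveletSpectrum) -> LevelSummary:
    """Level summary s_l = sum_k |wt_{l,k}| / 2^(l−1)."""
    s = np.array([np.abs(c).sum() / c.size for c in spec.coeffs])
    return LevelSummary(s, spec.length_morgans)


def subtract_baseline(summary: LevelSummary, baseline) -> LevelSummary:
    """Subtract a per-level parental baseline, flooring at zero.

    This removes the level profile present in every individual, admixed or
    not — in effect subtracting the parental signal, so internal admixture
    of a parental panel does not leak into the admixed cohort's center.
    """
    b = np.asarray(baseline, dtype=float)
    if b.shape != summary.s.shape:
        raise ValueError("baseline length must match the number of levels")
    if np.any(b < 0):
        raise ValueError("baseline must be non-negative")
    return LevelSummary(np.maximum(summary.s - b, 0.0), summary.length_morgans)


def wavelet_center(summary: LevelSummary) -> float:
    """Dominant frequency C(γ) = Σ l·s_l / Σ s_l of a level summary."""
    total = summary.total
    if total <= 0.0:
        raise ValueError("center undefined: all level summaries are zero")
    levels = np.arange(1, summary.s.size + 1)
    return float((levels * summary.s).sum() / total)


def normalize_center(center: float, signal_length: float,
                     reference_length: float) -> float:
    """Adjust a center for the genetic length of its source signal.

    A block of fixed width in Morgans sits one level higher on a chromosome
    twice as long, so comparable centers subtract log2 of the length ratio
    to a common reference (chromosome 1 in this package's defaults).
    """
    if signal_length <= 0 or reference_length <= 0:
        raise ValueError("lengths must be positive")
    return center - float(np.log2(signal_length / reference_length))


@dataclass
class NoiseFilterSpec:
    """The three-stage noise filter estimated from parental individuals.

    ``thresholds`` feed :func:`threshold_filter` (amplitudes seen among
    parental individuals are noise); ``max_level`` feeds
    :func:`drop_high_levels`; ``baseline`` is subtracted from the level
    summary (the parental signal itself).  Stages apply in that order.
    ``min_total`` is the largest residual summary total left by a parental
    individual after all three stages: a signal whose residual does not
    exceed it carries no admixture signal and gets no center.
    """

    thresholds: object
    max_level: int
    baseline: np.ndarray | None = None
    min_total: float = 0.0

    def apply(self, spec: WaveletSpectrum) -> LevelSummary:
        spec = threshold_filter(spec, self.thresholds)
        spec = drop_high_levels(spec, self.max_level)
        summary = wavelet_summary(spec)
        if self.baseline is not None:
            summary = subtract_baseline(summary, self.baseline)
        return summary


def estimate_noise_filter(
    parental_spectra: Sequence[WaveletSpectrum],
    max_level: int | None = None,
    mode: str = "level_quantile",
    quantile: float = 0.90,
) -> NoiseFilterSpec:
    """Calibrate the noise filter on the spectra of parental individuals.

    The thresholds are chosen so that oscillations present within the
    parental panels are ignored.  ``mode='level_quantile'`` (default) sets
    one threshold per level at the ``quantile`` of the pooled parental |wt|
    of that level; the noise that survives the threshold is then absorbed
    by the baseline, the parental mean of the post-threshold level summary,
    so the expected parental (noise) contribution to an admixed summary
    cancels.  ``mode='level_max'`` uses the per-level maximum instead (an
    extreme-value statistic: it grows with panel size and also removes
    genuine admixture coefficients of comparable size, biasing centers
    down); ``mode='scalar'`` uses a single pooled quantile.
    """
    if not parental_spectra:
        raise ValueError("need at least one parental spectrum")
    L = parental_spectra[0].levels
    if any(s.levels != L for s in parental_spectra):
        raise ValueError("parental spectra must share a common length")
    if max_level is None:
        max_level = default_max_level(L)
    if mode == "level_quantile":
        thresholds = np.array([
            float(np.quantile(
                np.concatenate([np.abs(s.coeffs[l]) for s in parental_spectra]),
                quantile))
            for l in range(L)
        ])
    elif mode == "level_max":
        thresholds = np.array([
            max(float(np.abs(s.coeffs[l]).max()) for s in parental_spectra)
            for l in range(L)
        ])
    elif mode == "scalar":
        pooled = np.concatenate(
            [np.abs(c) for s in parental_spectra for c in s.coeffs])
        thresholds = float(np.quantile(pooled, quantile))
    else:
        raise ValueError(f"unknown threshold mode: {mode!r}")
    nf = NoiseFilterSpec(thresholds, max_level, baseline=None)
    base = np.mean([nf.apply(s).s for s in parental_spectra], axis=0)
    nf = NoiseFilterSpec(thresholds, max_level, baseline=base)
    nf.min_total = max(nf.apply(s).total for s in parental_spectra)
    return nf


def filtered_center(
    values: np.ndarray,
    length_morgans: float,
    reference_length: float,
    noise_filter: NoiseFilterSpec | None = None,
    max_level: int | None = None,
) -> float:
    """Length-normalized WT center of a signal after noise filtering.

    Missing values are treated as ancestry-neutral (0).  Returns NaN when
    nothing survives the filter (no admixture signal).
    """
    vals = np.nan_to_num(np.asarray(values, dtype=float))
    spec = haar_transform(vals, length_morgans=length_morgans)
    floor = 0.0
    if noise_filter is not None:
        summary = noise_filter.apply(spec)
        floor = noise_filter.min_total
    else:
        spec = drop_high_levels(
            spec, default_max_level(spec.levels) if max_level is None else max_level)
        summary = wavelet_summary(spec)
    if summary.total <= floor:
        return float("nan")
    return normalize_center(wavelet_center(summary), length_morgans,
                            reference_length)
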