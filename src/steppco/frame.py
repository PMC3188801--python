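"""StepPCO: stepwise PCA ancestry signals along a chromosome.

The first principal axis (PA1) of the pooled parental panels defines the
direction of variation separating the two ancestries; an admixed genome is
then measured window by window along the chromosome.  Window sizes are not
fixed: centered on each of K equispaced points (in genetic distance), a
window grows until the parental projections are separated by λ standard
deviations (λ-separation), so regions rich in informative SNPs get small
windows and uninformative regions get large ones.  The per-window axis
measurements, rescaled so the parental poles sit at −1 and +1, form the
StepPCO signal of one individual chromosome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .iodata import GenotypeMatrix, SNPPanel


class FrameCoverageError(ValueError):
    """Raised when the λ-optimal windows leave a gap on the chromosome."""


@dataclass
class PrincipalAxis:
    """PA1 of the pooled parental panels in SNP coordinates.

    ``coefficients`` span the axis (defined up to a positive factor) and are
    oriented so population Q projects to the positive side; ``center`` holds
    the per-SNP means removed before projection during axis estimation.
    """

    coefficients: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not np.any(self.coefficients):
            raise ValueError("principal axis must have a non-zero coefficient")


@dataclass
class Window:
    """A contiguous SNP range [first, last] centered at a point on the
    genetic map; ``usable`` is False when λ-separation was unattainable
    even at full chromosome width."""

    first: int
    last: int
    center_cm: float
    width_cm: float
    usable: bool = True

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError("window first index must be <= last")
        if self.width_cm < 0:
            raise ValueError("window width must be non-negative")

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1


@dataclass
class AncestrySignal:
    """Length-K StepPCO signal of one (unphased diploid) sample: parental
    poles at −1/+1, NaN at unusable bins."""

    values: np.ndarray
    bin_centers: np.ndarray
    sample_id: str | None = None
    length_morgans: float | None = None

    @property
    def n_usable(self) -> int:
        return int(np.isfinite(self.values).sum())


def principal_axis(P: GenotypeMatrix, Q: GenotypeMatrix) -> PrincipalAxis:
    """First principal axis of the pooled parental samples.

    Calls are mean-centered per SNP (missing values mean-imputed for the
    estimation only, never for window measurements) and no variance scaling
    is applied, so the axis lives in the raw call space the window
    measurement operates on.  Orientation is fixed so that Q's mean
    projection is positive (axis directed from P to Q).
    """
    _check_shared_panel(P, Q)
    if P.n_samples < 2 or Q.n_samples < 2:
        raise ValueError("need at least two samples per parental panel")
    X = np.hstack([P.calls, Q.calls])
    mu = np.where(np.all(np.isnan(X), axis=1), 0.0, np.nanmean(X, axis=1))
    X = np.where(np.isnan(X), mu[:, None], X) - mu[:, None]
    gram = X.T @ X
    vals, vecs = np.linalg.eigh(gram)
    if vals[-1] <= 1e-12 * max(1.0, abs(vals).max()):
        raise ValueError("degenerate parental panels: no axis of variation")
    v = vecs[:, -1]
    a = X @ v
    a /= np.linalg.norm(a)
    if a[np.argmax(np.abs(a))] == 0:  # pragma: no cover - defensive
        raise ValueError("degenerate principal axis")
    if float(X[:, P.n_samples:].T @ a @ np.ones(Q.n_samples)) < 0:
        a = -a
    return PrincipalAxis(a, mu)


def window_measurement(e: np.ndarray, window: Window,
                       axis: PrincipalAxis) -> float:
    """Axis-weighted mean call in a window: Σ a_i e_i / Σ |a_i|.

    Missing calls are excluded from the numerator and their |a_i| from the
    denominator; the value is invariant under positive rescaling of the
    axis.
    """
    sl = slice(window.first, window.last + 1)
    a = axis.coefficients[sl]
    ev = np.asarray(e, dtype=float)[sl]
    ok = np.isfinite(ev)
    den = float(np.abs(a[ok]).sum())
    if den == 0.0:
        raise ValueError("window measurement undefined: all calls missing or "
                         "all axis coefficients zero in the window")
    return float((a[ok] * ev[ok]).sum() / den)


def is_separated(alpha_projs, beta_projs, lambda_sep: float) -> bool:
    """λ-separation test |Eα − Eβ| >= λ(σ(α) + σ(β)) on parental window
    projections (sample mean and sample standard deviation)."""
    a = np.asarray(alpha_projs, dtype=float)
    b = np.asarray(beta_projs, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two projections per population")
    return bool(abs(a.mean() - b.mean()) >=
                lambda_sep * abs(a.std(ddof=1) + b.std(ddof=1)))


class _ProjectionTable:
    """Prefix sums of axis-weighted calls for O(1) window projections."""

    def __init__(self, axis: PrincipalAxis, gm: GenotypeMatrix):
        a = axis.coefficients[:, None]
        ok = np.isfinite(gm.calls)
        n, s = gm.calls.shape
        self.num = np.zeros((n + 1, s))
        self.den = np.zeros((n + 1, s))
        np.cumsum(np.where(ok, gm.calls, 0.0) * a, axis=0, out=self.num[1:])
        np.cumsum(np.abs(a) * ok, axis=0, out=self.den[1:])

    def measurements(self, first: int, last: int) -> np.ndarray:
        den = self.den[last + 1] - self.den[first]
        num = self.num[last + 1] - self.num[first]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)


def _separated(ma: np.ndarray, mb: np.ndarray, lam: float) -> bool:
    a = ma[np.isfinite(ma)]
    b = mb[np.isfinite(mb)]
    if a.size < 2 or b.size < 2:
        return False
    return abs(a.mean() - b.mean()) >= lam * (a.std(ddof=1) + b.std(ddof=1))


def _grow_window(x: float, pos: np.ndarray, tab_p: _ProjectionTable,
                 tab_q: _ProjectionTable, lam: float) -> Window:
    """Smallest window centered at x in which the parents are λ-separated.

    SNPs enter in order of genetic distance from x (ties toward the lower
    index), which enumerates every candidate width at which membership
    changes; at chromosome ends growth continues one-sided.
    """
    n = pos.size
    j = int(np.searchsorted(pos, x))
    if j == 0:
        lo = hi = 0
    elif j >= n:
        lo = hi = n - 1
    else:
        lo = hi = j - 1 if (x - pos[j - 1]) <= (pos[j] - x) else j
    while True:
        if _separated(tab_p.measurements(lo, hi), tab_q.measurements(lo, hi), lam):
            return Window(lo, hi, x, float(pos[hi] - pos[lo]), True)
        left = x - pos[lo - 1] if lo > 0 else math.inf
        right = pos[hi + 1] - x if hi < n - 1 else math.inf
        if left is math.inf and right is math.inf:
            return Window(lo, hi, x, float(pos[hi] - pos[lo]), False)
        if left <= right:
            lo -= 1
        else:
            hi += 1


def optimal_window(x: float, axis: PrincipalAxis, P: GenotypeMatrix,
                   Q: GenotypeMatrix, lambda_sep: float = 3.0) -> Window:
    """λ-optimal window centered at genetic position ``x`` (cM)."""
    _check_shared_panel(P, Q)
    return _grow_window(x, P.panel.genetic_pos, _ProjectionTable(axis, P),
                        _ProjectionTable(axis, Q), lambda_sep)


def _check_shared_panel(P: GenotypeMatrix, Q: GenotypeMatrix) -> None:
    if P.panel is not Q.panel:
        if (P.panel.n_snps != Q.panel.n_snps or
                not np.array_equal(P.panel.snp_id, Q.panel.snp_id)):
            raise ValueError("parental panels must share one SNP panel")


@dataclass
class StepPCOFrame:
    """Everything needed to turn a genotype vector into an ancestry signal:
    the principal axis, the K bin centers, their λ-optimal windows and the
    per-window parental projection statistics."""

    panel: SNPPanel
    axis: PrincipalAxis
    lambda_sep: float
    n_bins: int
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    windows: list[Window]
    mean_p: np.ndarray
    sd_p: np.ndarray
    mean_q: np.ndarray
    sd_q: np.ndarray
    usable: np.ndarray

    @property
    def span_morgans(self) -> float:
        return self.panel.span_morgans

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def audit(self) -> dict:
        """Per-bin construction report (window extent, size, separation)."""
        gap = np.abs(self.mean_q - self.mean_p)
        sds = self.sd_p + self.sd_q
        with np.errstate(divide="ignore", invalid="ignore"):
            achieved = np.where(sds > 0, gap / sds, np.inf)
        return {
            "n_bins": self.n_bins,
            "lambda": self.lambda_sep,
            "n_usable": self.n_usable,
            "mean_window_snps": float(np.mean([w.n_snps for w in self.windows])),
            "bins": [
                {
                    "bin": k,
                    "center_cm": float(self.bin_centers[k]),
                    "first": w.first,
                    "last": w.last,
                    "n_snps": w.n_snps,
                    "width_cm": w.width_cm,
                    "separation": float(achieved[k]),
                    "usable": bool(self.usable[k]),
                }
                for k, w in enumerate(self.windows)
            ],
        }

    def audit_json(self) -> str:
        return json.dumps(self.audit(), indent=1)


def build_frame(P: GenotypeMatrix, Q: GenotypeMatrix, n_bins: int = 1024,
                lambda_sep: float = 3.0,
                axis: PrincipalAxis | None = None) -> StepPCOFrame:
    """Construct the StepPCO frame from two parental panels.

    ``n_bins`` (a power of two, to suit the later wavelet analysis) bin
    centers are equispaced in genetic distance over the chromosome; each
    gets its λ-optimal window.  The union of windows is audited to cover
    every SNP with no gaps (guaranteed for sufficiently large ``n_bins``;
    a :class:`FrameCoverageError` reports any gap).
    """
    _check_shared_panel(P, Q)
    P.panel.single_chromosome()
    if n_bins < 1 or (n_bins & (n_bins - 1)) != 0:
        raise ValueError("n_bins must be a power of two")
    if lambda_sep <= 0:
        raise ValueError("lambda_sep must be positive")
    if axis is None:
        axis = principal_axis(P, Q)
    pos = P.panel.genetic_pos
    edges = np.linspace(pos[0], pos[-1], n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    tab_p = _ProjectionTable(axis, P)
    tab_q = _ProjectionTable(axis, Q)
    windows = [_grow_window(x, pos, tab_p, tab_q, lambda_sep) for x in centers]

    firsts = np.array([w.first for w in windows])
    lasts = np.array([w.last for w in windows])
    if firsts.min() != 0 or lasts.max() != P.panel.n_snps - 1:
        raise FrameCoverageError("windows do not reach the chromosome ends; "
                                 "increase n_bins")
    reach = np.maximum.accumulate(lasts)
    gaps = np.nonzero(firsts[1:] > reach[:-1] + 1)[0]
    if gaps.size:
        k = int(gaps[0]) + 1
        raise FrameCoverageError(
            f"coverage gap before bin {k} (center {centers[k]:.3f} cM); "
            "increase n_bins")

    mp = np.empty(n_bins)
    sp = np.empty(n_bins)
    mq = np.empty(n_bins)
    sq = np.empty(n_bins)
    usable = np.empty(n_bins, dtype=bool)
    for k, w in enumerate(windows):
        ma = tab_p.measurements(w.first, w.last)
        mb = tab_q.measurements(w.first, w.last)
        ma, mb = ma[np.isfinite(ma)], mb[np.isfinite(mb)]
        mp[k] = ma.mean() if ma.size else np.nan
        sp[k] = ma.std(ddof=1) if ma.size > 1 else np.nan
        mq[k] = mb.mean() if mb.size else np.nan
        sq[k] = mb.std(ddof=1) if mb.size > 1 else np.nan
        usable[k] = w.usable and np.isfinite(mp[k]) and np.isfinite(mq[k]) \
            and mq[k] != mp[k]
    return StepPCOFrame(P.panel, axis, lambda_sep, n_bins, edges, centers,
                        windows, mp, sp, mq, sq, usable)


def steppco_signal(r: np.ndarray, frame: StepPCOFrame,
                   sample_id: str | None = None) -> AncestrySignal:
    """StepPCO signal of one genotype vector on the frame's panel.

    Each bin's window measurement is affinely rescaled so the parental mean
    projections map to −1 (P) and +1 (Q); unusable bins are NaN.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (frame.panel.n_snps,):
        raise ValueError("genotype vector does not match the frame's panel")
    a = frame.axis.coefficients
    ok = np.isfinite(r)
    num = np.concatenate(([0.0], np.cumsum(np.where(ok, r, 0.0) * a)))
    den = np.concatenate(([0.0], np.cumsum(np.abs(a) * ok)))
    first = np.array([w.first for w in frame.windows])
    last = np.array([w.last for w in frame.windows])
    d = den[last + 1] - den[first]
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(d > 0, (num[last + 1] - num[first]) / d, np.nan)
        s = -1.0 + 2.0 * (m - frame.mean_p) / (frame.mean_q - frame.mean_p)
    s[~frame.usable] = np.nan
    return AncestrySignal(values=s, bin_centers=frame.bin_centers.copy(),
                          sample_id=sample_id,
                          length_morgans=frame.span_morgans)


def signals_for(gm: GenotypeMatrix, frame: StepPCOFrame) -> list[AncestrySignal]:
    """StepPCO signals for every sample of a genotype matrix."""
    if gm.panel.n_snps != frame.panel.n_snps or \
            not np.array_equal(gm.panel.snp_id, frame.panel.snp_id):
        raise ValueError("genotype matrix does not match the frame's panel")
    return [steppco_signal(gm.calls[:, j], frame, sid)
            for j, sid in enumerate(gm.samples)]


def admixture_proportion(signal: AncestrySignal) -> float:
    """Fraction of Q ancestry: mean over usable bins of (1 + S)/2.

    Bin values are NOT clamped to [−1, 1] before averaging: the measurement
    noise around the poles is symmetric, so the linear mean is unbiased
    while clamping would push pole-hugging signals toward 0.5.  The final
    proportion is clipped into [0, 1].
    """
    ok = np.isfinite(signal.values)
    if not ok.any():
        raise ValueError("no usable bins: admixture proportion undefined")
    s = signal.values[ok]
    return float(np.clip(((1.0 + s) / 2.0).mean(), 0.0, 1.0))
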