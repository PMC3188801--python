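"""Artificially admixed genomes and the switch-rate calibration.

Hybrid haploid genomes are built by laying an exponential recombination map
over phased parental haplotypes: ancestry is resampled at the chromosome
start and at points whose gaps are Exponential(λ) in genetic distance, each
time choosing the Q-side ancestry with probability α (so a switch occurs
with probability 1 − e^(−λg) over a gap of g Morgans, and realized switches
occur at rate 2λα(1−α) per Morgan).  Pairs of haploids are merged into
unphased diploids, the StepPCO + wavelet pipeline is run on them, and the
relation between the dominant wavelet frequency (center) and the log of the
realized switches per Morgan — linear over a wide λ range — is fitted by
least squares, giving an estimator of ancestry switches per Morgan from an
observed center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forward_sim import REFERENCE_LENGTH_MORGANS
from .frame import build_frame, signals_for, steppco_signal
from .iodata import (
    GenotypeMatrix,
    SNPPanel,
    haplotypes_from_frequencies,
    synthesize_parental_panels,
)
from .wavelets import estimate_noise_filter, filtered_center, haar_transform

#: switch intensities (per Morgan) used for the calibration grid
LAMBDA_GRID = (6, 10, 20, 40, 60, 100, 200, 400)


def beta_parameters(mean: float = 0.20, sd: float = 0.10) -> tuple[float, float]:
    """Shape parameters (a, b) of a Beta distribution from its moments."""
    if not (0 < mean < 1):
        raise ValueError("mean must lie in (0, 1)")
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError("sd too large for a Beta distribution with this mean")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


@dataclass
class AncestryMap:
    """Realized local-ancestry labels of one hybrid haploid genome.

    ``switch_points`` are the positions (Morgans) where the label actually
    changes, after coalescing same-label resampling points;
    ``segment_labels`` has one more entry than switch points
    (0 = P/African side, 1 = Q/European side).
    """

    switch_points: np.ndarray
    segment_labels: np.ndarray
    length: float
    alpha: float
    lambda_exp: float

    def __post_init__(self):
        self.switch_points = np.asarray(self.switch_points, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype=np.int8)
        if self.segment_labels.size != self.switch_points.size + 1:
            raise ValueError("need one more segment label than switch points")
        if self.switch_points.size and (
                np.any(np.diff(self.switch_points) <= 0)
                or self.switch_points[0] <= 0
                or self.switch_points[-1] >= self.length):
            raise ValueError("switch points must be increasing inside (0, length)")

    @property
    def n_switches(self) -> int:
        return self.switch_points.size

    @property
    def switches_per_morgan(self) -> float:
        return self.n_switches / self.length

    def label_at(self, x) -> np.ndarray:
        idx = np.searchsorted(self.switch_points, np.asarray(x, dtype=float),
                              side="right")
        return self.segment_labels[idx]


def simulate_ancestry_map(lambda_exp: float, alpha: float, length: float,
                          rng: np.random.Generator) -> AncestryMap:
    """Draw one hybrid ancestry map of ``length`` Morgans.

    Resampling points are laid at Exponential(λ) gaps; at the chromosome
    start and at each point the ancestry label is drawn i.i.d. (Q with
    probability α).  Only label changes are kept as switches.
    """
    if lambda_exp < 0:
        raise ValueError("lambda_exp must be non-negative")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if lambda_exp == 0:
        points = np.empty(0)
    else:
        n_guess = max(8, int(lambda_exp * length * 1.5) + 8)
        gaps = rng.exponential(1.0 / lambda_exp, n_guess)
        points = np.cumsum(gaps)
        while points.size and points[-1] < length:
            points = np.concatenate(
                [points, points[-1] + np.cumsum(rng.exponential(1.0 / lambda_exp, n_guess))])
        points = points[points < length]
    labels = (rng.random(points.size + 1) < alpha).astype(np.int8)
    changed = np.nonzero(np.diff(labels) != 0)[0]
    return AncestryMap(points[changed], labels[np.concatenate(([0], changed + 1))],
                       length, alpha, lambda_exp)


def build_hybrids(
    hap_p: np.ndarray,
    hap_q: np.ndarray,
    panel: SNPPanel,
    lambda_exp: float,
    n_haploids: int = 40,
    alpha: float | None = None,
    alpha_mean: float = 0.20,
    alpha_sd: float = 0.10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Construct artificially admixed diploids from phased parental panels.

    Each haploid hybrid draws its own ancestry fraction α from a
    Beta(mean ``alpha_mean``, sd ``alpha_sd``) (or a fixed ``alpha``), lays
    down an exponential ancestry map and copies alleles from one donor
    haplotype per ancestry; donors are never reused.  Consecutive haploids
    are merged pairwise into unphased diploid dosages.  Returns the diploid
    matrix and a truth dict (per-haploid α, switch points, realized switch
    rates; per-diploid mean switch rate).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_haploids < 2 or n_haploids % 2:
        raise ValueError("n_haploids must be a positive even number")
    if hap_p.shape[0] != panel.n_snps or hap_q.shape[0] != panel.n_snps:
        raise ValueError("haplotype panels must match the SNP panel")
    if hap_p.shape[1] < n_haploids or hap_q.shape[1] < n_haploids:
        raise ValueError("haplotype pool exhausted: donors are never reused, "
                         f"need {n_haploids} per population")
    length = panel.span_morgans
    pos_m = panel.unit_positions() * length
    a_shape, b_shape = beta_parameters(alpha_mean, alpha_sd)

    haploids = np.empty((panel.n_snps, n_haploids), dtype=np.int8)
    alphas = np.empty(n_haploids)
    maps: list[AncestryMap] = []
    for i in range(n_haploids):
        a = float(alpha) if alpha is not None else float(rng.beta(a_shape, b_shape))
        amap = simulate_ancestry_map(lambda_exp, a, length, rng)
        lab = amap.label_at(pos_m)
        haploids[:, i] = np.where(lab == 1, hap_q[:, i], hap_p[:, i])
        alphas[i] = a
        maps.append(amap)

    dosage = haploids[:, 0::2].astype(float) + haploids[:, 1::2] - 1.0
    samples = [f"HYB{i:03d}" for i in range(n_haploids // 2)]
    gm = GenotypeMatrix(panel, samples, dosage)
    rates = np.array([m.switches_per_morgan for m in maps])
    truth = {
        "lambda": lambda_exp,
        "alpha": alphas.tolist(),
        "switch_points": [m.switch_points.tolist() for m in maps],
        "switches_per_morgan": rates.tolist(),
        "diploid_switches_per_morgan": (
            (rates[0::2] + rates[1::2]) / 2.0).tolist(),
    }
    return gm, truth


@dataclass
class SwitchCalibration:
    """Least-squares fit of WT center on log(ancestry switches per Morgan)."""

    intercept: float
    slope: float
    r_squared: float
    lambda_grid: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("degenerate calibration: zero or non-finite slope")


def calibrate_switch_regression(centers, switch_rates) -> SwitchCalibration:
    """Fit center = intercept + slope · log(switches/Morgan) by OLS."""
    c = np.asarray(centers, dtype=float)
    r = np.asarray(switch_rates, dtype=float)
    if c.size != r.size or c.size < 3:
        raise ValueError("need at least three (center, rate) pairs")
    if np.any(r <= 0):
        raise ValueError("switch rates must be positive")
    x = np.log(r)
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all rates equal")
    fit = stats.linregress(x, c)
    return SwitchCalibration(float(fit.intercept), float(fit.slope),
                             float(fit.rvalue ** 2))


def estimate_switches_per_morgan(center: float,
                                 cal: SwitchCalibration) -> float:
    """Invert the calibration: switches/Morgan for an observed center."""
    return float(np.exp((center - cal.intercept) / cal.slope))


def run_switch_calibration(
    lambda_grid=LAMBDA_GRID,
    n_snps: int = 16384,
    n_per_pop: int = 40,
    divergence: float = 0.4,
    n_haploids: int = 20,
    n_bins: int = 2048,
    lambda_sep: float = 3.0,
    span_cm: float = 278.0,
    seed: int | None = None,
) -> tuple[SwitchCalibration, pd.DataFrame]:
    """Run the full calibration experiment on synthetic parental panels.

    Builds a StepPCO frame from synthesized parental panels, constructs
    ``n_haploids`` hybrid genomes for each λ on the grid, measures the mean
    WT center of the hybrid diploids after amplitude thresholding (no level
    cutoff: the high-λ grid points live above the dating cutoff and the
    calibration needs them), and regresses center on log realized switch
    rate.  Returns the fit and the per-λ table.

    The defaults emulate strongly differentiated parental panels at array
    density: at λ = 400 switches/Morgan the ancestry blocks are ~0.009
    Morgans wide, so the adaptive windows must resolve below that scale
    (here ~20 SNPs ≈ 0.003 Morgans) for the center-log(rate) relation to
    stay linear across the whole grid.
    """
    master = np.random.SeedSequence(seed)
    s_panel, s_hap, s_hyb = master.spawn(3)
    P, Q, (f_p, f_q) = synthesize_parental_panels(
        n_snps, n_per_pop, divergence, seed=s_panel, span_cm=span_cm)
    frame = build_frame(P, Q, n_bins=n_bins, lambda_sep=lambda_sep)
    span_m = frame.span_morgans

    rng_h = np.random.default_rng(s_hap)
    pool = len(lambda_grid) * n_haploids
    hap_p = haplotypes_from_frequencies(f_p, pool, rng_h)
    hap_q = haplotypes_from_frequencies(f_q, pool, rng_h)

    parental_spectra = [
        haar_transform(np.nan_to_num(sig.values), span_m)
        for sig in signals_for(P, frame) + signals_for(Q, frame)
    ]
    L = parental_spectra[0].levels
    nf = estimate_noise_filter(parental_spectra, max_level=L)

    rng = np.random.default_rng(s_hyb)
    rows = []
    for j, lam in enumerate(lambda_grid):
        cols = slice(j * n_haploids, (j + 1) * n_haploids)
        gm, truth = build_hybrids(hap_p[:, cols], hap_q[:, cols], P.panel,
                                  lam, n_haploids=n_haploids, rng=rng)
        centers = [
            filtered_center(sig.values, span_m, REFERENCE_LENGTH_MORGANS,
                            noise_filter=nf)
            for sig in signals_for(gm, frame)
        ]
        centers = np.asarray(centers)
        centers = centers[np.isfinite(centers)]
        rows.append({
            "lambda": lam,
            "mean_center": float(centers.mean()),
            "true_switches_per_morgan": float(
                np.mean(truth["switches_per_morgan"])),
            "n_diploids": gm.n_samples,
        })
    table = pd.DataFrame(rows)
    cal = calibrate_switch_regression(table["mean_center"],
                                      table["true_switches_per_morgan"])
    cal.lambda_grid = tuple(lambda_grid)
    return cal, table
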