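"""Model/results façade over the StepPCO + wavelet pipeline.

:class:`StepPCOModel` bundles the data of one analysis — an admixed panel
and its two proposed parental panels on a shared SNP panel — and ``fit()``
runs the frame construction, per-sample ancestry signals, admixture
proportions and noise-filtered wavelet centers, returning a
:class:`StepPCOResults` whose ``date()`` hands the cohort centers to a
reference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dating import DatingResult, ReferenceCurve, date_admixture
from .frame import (
    StepPCOFrame,
    admixture_proportion,
    build_frame,
    signals_for,
)
from .forward_sim import REFERENCE_LENGTH_MORGANS
from .iodata import GenotypeMatrix, RecombinationMap, interpolate_genetic_positions, read_genotypes
from .wavelets import NoiseFilterSpec, estimate_noise_filter, filtered_center, haar_transform


class StepPCOModel:
    """One-chromosome admixture scan of an admixed panel.

    Parameters
    ----------
    admixed, parental_p, parental_q : GenotypeMatrix
        Panels sharing one SNP panel; P maps to the −1 pole, Q to +1.
    n_bins : int
        Number of signal bins (power of two; 1024 by default).
    lambda_sep : float
        Separation requirement for the adaptive windows (3 by default).
    """

    def __init__(self, admixed: GenotypeMatrix, parental_p: GenotypeMatrix,
                 parental_q: GenotypeMatrix, n_bins: int = 1024,
                 lambda_sep: float = 3.0):
        self.admixed = admixed
        self.parental_p = parental_p
        self.parental_q = parental_q
        self.n_bins = n_bins
        self.lambda_sep = lambda_sep

    @classmethod
    def from_files(cls, admixed_path, parental_p_path, parental_q_path,
                   recombination_map=None, dialect: str = "tsv", **kwargs):
        """Build the model from genotype files (native TSV by default),
        optionally re-interpolating genetic positions from a map file."""
        mats = [read_genotypes(p, dialect)
                for p in (admixed_path, parental_p_path, parental_q_path)]
        if recombination_map is not None:
            rmap = RecombinationMap.read(recombination_map)
            panel = interpolate_genetic_positions(mats[0].panel, rmap)
            mats = [GenotypeMatrix(panel, m.samples, m.calls) for m in mats]
        else:
            panel = mats[0].panel
            mats = [mats[0]] + [GenotypeMatrix(panel, m.samples, m.calls)
                                for m in mats[1:]]
        return cls(*mats, **kwargs)

    def fit(self, noise_mode: str = "level_quantile",
            max_level: int | None = None) -> "StepPCOResults":
        """Run the scan: frame, signals, proportions and filtered centers."""
        frame = build_frame(self.parental_p, self.parental_q,
                            n_bins=self.n_bins, lambda_sep=self.lambda_sep)
        signals = signals_for(self.admixed, frame)
        parental_signals = (signals_for(self.parental_p, frame)
                            + signals_for(self.parental_q, frame))
        span = frame.span_morgans
        spectra = [haar_transform(np.nan_to_num(s.values), span)
                   for s in parental_signals]
        nf = estimate_noise_filter(spectra, max_level=max_level, mode=noise_mode)
        proportions = np.array([admixture_proportion(s) for s in signals])
        # centers on the 1-Morgan reference scale used by reference curves
        centers = np.array([
            filtered_center(s.values, span, REFERENCE_LENGTH_MORGANS,
                            noise_filter=nf)
            for s in signals
        ])
        return StepPCOResults(self, frame, signals, parental_signals,
                              proportions, centers, nf)


@dataclass
class StepPCOResults:
    """Fitted StepPCO scan: signals, admixture proportions and WT centers."""

    model: StepPCOModel
    frame: StepPCOFrame
    signals: list
    parental_signals: list
    proportions: np.ndarray
    centers: np.ndarray
    noise_filter: NoiseFilterSpec

    @property
    def sample_ids(self) -> list[str]:
        return list(self.model.admixed.samples)

    @property
    def mean_proportion(self) -> float:
        return float(self.proportions.mean())

    @property
    def cohort_center(self) -> float:
        c = self.centers[np.isfinite(self.centers)]
        return float(c.mean()) if c.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_ids,
            "q_proportion": self.proportions,
            "wt_center": self.centers,
        })

    def date(self, curve: ReferenceCurve, generation_time: float = 30.0) -> DatingResult:
        """Date the cohort's admixture against a simulated reference curve."""
        finite = self.centers[np.isfinite(self.centers)]
        if finite.size == 0:
            raise ValueError("no admixture signal: every cohort center is "
                             "undefined after noise filtering")
        return date_admixture(finite, curve, generation_time)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "StepPCO admixture scan",
            "======================",
            f"SNPs: {self.frame.panel.n_snps}   bins: {self.frame.n_bins} "
            f"(usable {self.frame.n_usable})   lambda: {self.frame.lambda_sep:g}",
            f"mean window size: "
            f"{np.mean([w.n_snps for w in self.frame.windows]):.1f} SNPs",
            f"cohort mean Q-ancestry proportion: {self.mean_proportion:.3f}",
            f"cohort mean WT center: {self.cohort_center:.3f}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def plot_signal(self, sample: str, ax=None):
        """Step plot of one sample's ancestry signal along the chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        idx = self.sample_ids.index(sample)
        sig = self.signals[idx]
        ax.step(sig.bin_centers, sig.values, where="mid", lw=0.8)
        ax.axhline(1.0, color="C1", lw=0.8)
        ax.axhline(-1.0, color="C0", lw=0.8)
        ax.set_xlabel("position (cM)")
        ax.set_ylabel("ancestry signal")
        ax.set_title(sample)
        return ax
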