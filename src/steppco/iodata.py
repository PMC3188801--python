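"""Genotype matrices, genetic maps and synthetic data generation.

The package-native exchange format is a plain TSV: one row per SNP with
columns ``snp_id``, ``chrom``, ``bp``, ``cM`` followed by one dosage column
per sample coded 0/1/2 (``NA`` for missing).  Internally calls are coded
−1/0/+1 for the two homozygotes and the heterozygote, with ``NaN`` for
missing.  PLINK ``.traw`` tables and biallelic VCF (via cyvcf2, optional)
can also be ingested.

Genetic positions are stored in centimorgans and interpolated piecewise
linearly from a HapMap-style recombination-rate table (position bp,
rate cM/Mb, cumulative cM); SNPs falling outside the map are clamped to the
nearest map endpoint with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

TSV_COLUMNS = ("snp_id", "chrom", "bp", "cM")

#: genetic length used for synthetic chromosomes (human chromosome 1, cM)
DEFAULT_SPAN_CM = 278.0


@dataclass
class SNPPanel:
    """Per-SNP metadata: ids, chromosome, physical (bp) and genetic (cM)
    positions, ordered by physical position."""

    snp_id: np.ndarray
    chromosome: np.ndarray
    physical_pos: np.ndarray
    genetic_pos: np.ndarray

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.physical_pos = np.asarray(self.physical_pos, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        n = self.snp_id.size
        if not (self.chromosome.size == self.physical_pos.size ==
                self.genetic_pos.size == n):
            raise ValueError("panel columns must have equal length")
        if not np.all(np.isfinite(self.genetic_pos)):
            raise ValueError("genetic positions must be finite")
        if np.any(self.genetic_pos < 0) or np.any(self.physical_pos < 0):
            raise ValueError("positions must be non-negative")
        df = pd.DataFrame({"c": self.chromosome, "i": self.snp_id})
        if df.duplicated().any():
            dup = df[df.duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id {dup['i']!r} on chromosome {dup['c']!r}")
        for _, grp in df.assign(g=self.genetic_pos, p=self.physical_pos).groupby("c", sort=False):
            g = grp.sort_values("p")["g"].to_numpy()
            if np.any(np.diff(g) < 0):
                raise ValueError("genetic positions must be non-decreasing "
                                 "in physical order")

    @property
    def n_snps(self) -> int:
        return self.snp_id.size

    def single_chromosome(self) -> str:
        chroms = pd.unique(self.chromosome)
        if chroms.size != 1:
            raise ValueError("operation requires a single-chromosome panel")
        return str(chroms[0])

    @property
    def span_cm(self) -> float:
        return float(self.genetic_pos[-1] - self.genetic_pos[0])

    @property
    def span_morgans(self) -> float:
        return self.span_cm / 100.0

    def unit_positions(self) -> np.ndarray:
        """Genetic positions rescaled to the unit map [0, 1]."""
        g = self.genetic_pos
        span = g[-1] - g[0]
        if span <= 0:
            raise ValueError("panel has zero genetic span")
        return (g - g[0]) / span


@dataclass
class GenotypeMatrix:
    """A SNP-by-sample matrix of diploid calls in {−1, 0, +1, NaN}."""

    panel: SNPPanel
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if not self.samples:
            raise ValueError("genotype matrix has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.calls.shape != (self.panel.n_snps, len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.panel.n_snps} SNPs x {len(self.samples)} samples")
        vals = self.calls[np.isfinite(self.calls)]
        if not np.isin(vals, (-1.0, 0.0, 1.0)).all():
            raise ValueError("non-missing calls must be -1, 0 or +1")

    @property
    def n_snps(self) -> int:
        return self.panel.n_snps

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _matrix_from_dosages(panel: SNPPanel, samples: list[str],
                         dos: np.ndarray) -> GenotypeMatrix:
    bad = np.isfinite(dos) & ~np.isin(dos, (0.0, 1.0, 2.0))
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        raise ValueError(
            f"row {row} (snp {panel.snp_id[row]!r}): dosage outside {{0,1,2}} "
            "— multi-allelic or malformed")
    return GenotypeMatrix(panel, samples, dos - 1.0)


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV lacks required columns: {missing}")
    samples = [c for c in df.columns if c not in TSV_COLUMNS]
    if not samples:
        raise ValueError("genotype TSV has no sample columns")
    panel = SNPPanel(df["snp_id"].to_numpy(), df["chrom"].to_numpy(),
                     df["bp"].to_numpy(), df["cM"].to_numpy())
    dos = df[samples].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # distinguish unparsable tokens from explicit NA
    raw = df[samples].to_numpy(dtype=object)
    unparsed = np.vectorize(
        lambda v: isinstance(v, str) and v.strip().upper() not in ("", "NA", "NAN"))(raw)
    if (np.isnan(dos) & unparsed).any():
        row = int(np.argwhere((np.isnan(dos) & unparsed).any(axis=1))[0][0])
        raise ValueError(f"row {row}: unparsable genotype token")
    return _matrix_from_dosages(panel, samples, dos)


def _read_traw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    fixed = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"traw file lacks required columns: {missing}")
    samples = [c for c in df.columns if c not in fixed]
    if not samples:
        raise ValueError("traw file has no sample columns")
    panel = SNPPanel(df["SNP"].astype(str).to_numpy(),
                     df["CHR"].astype(str).to_numpy(),
                     df["POS"].to_numpy(),
                     # PLINK stores Morgans in (C)M by convention; treat as cM
                     df["(C)M"].to_numpy())
    dos = df[samples].to_numpy(dtype=float)
    return _matrix_from_dosages(panel, samples, dos)


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no samples")
    ids, chroms, pos, rows = [], [], [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(f"row {i} ({var.ID or var.POS}): not biallelic")
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        gt = np.asarray(var.gt_types, dtype=float)  # 0 HOM_REF,1 HET,2 UNK,3 HOM_ALT
        row = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        rows.append(row)
    panel = SNPPanel(np.array(ids), np.array(chroms), np.array(pos),
                     np.zeros(len(ids)))
    return _matrix_from_dosages(panel, samples, np.array(rows))


_DIALECTS = {"tsv": _read_tsv, "traw": _read_traw, "vcf": _read_vcf}


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix; ``dialect`` is 'tsv', 'traw' or 'vcf'."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _DIALECTS[dialect](path)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the package-native genotype TSV (dosage codes 0/1/2, NA)."""
    df = pd.DataFrame({
        "snp_id": gm.panel.snp_id,
        "chrom": gm.panel.chromosome,
        "bp": gm.panel.physical_pos,
        "cM": gm.panel.genetic_pos,
    })
    dos = gm.calls + 1.0
    for j, s in enumerate(gm.samples):
        col = dos[:, j]
        df[s] = pd.array(np.where(np.isfinite(col), col, np.nan)).astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class RecombinationMap:
    """HapMap-style recombination map (position bp, rate cM/Mb, cumulative cM)."""

    position_bp: np.ndarray
    rate_cm_per_mb: np.ndarray
    cumulative_cm: np.ndarray

    def __post_init__(self):
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.rate_cm_per_mb = np.asarray(self.rate_cm_per_mb, dtype=float)
        self.cumulative_cm = np.asarray(self.cumulative_cm, dtype=float)
        if not (self.position_bp.size == self.rate_cm_per_mb.size ==
                self.cumulative_cm.size):
            raise ValueError("map columns must have equal length")
        if self.position_bp.size < 2:
            raise ValueError("map needs at least two knots")
        if np.any(np.diff(self.position_bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        if np.any(self.rate_cm_per_mb < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def read(cls, path) -> "RecombinationMap":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep=r"\s+")
        if df.shape[1] < 3:
            raise ValueError("recombination map needs >= 3 columns "
                             "(position, rate, cumulative)")
        cols = df.columns[:3]
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                   df[cols[2]].to_numpy())

    def interpolate(self, positions_bp) -> np.ndarray:
        """Cumulative cM at physical positions (piecewise linear, clamped)."""
        pos = np.asarray(positions_bp)
        if np.any(pos < self.position_bp[0]) or np.any(pos > self.position_bp[-1]):
            warnings.warn("SNPs outside the recombination map were clamped "
                          "to the nearest map endpoint", stacklevel=2)
        return np.interp(pos, self.position_bp, self.cumulative_cm)


def interpolate_genetic_positions(panel: SNPPanel,
                                  rmap: RecombinationMap) -> SNPPanel:
    """Return a panel with genetic positions interpolated from the map."""
    g = rmap.interpolate(panel.physical_pos)
    return replace(panel, genetic_pos=g)


def synthesize_parental_panels(
    n_snps: int,
    n_per_pop: int,
    divergence: float,
    seed: int | None = None,
    span_cm: float = DEFAULT_SPAN_CM,
    chromosome: str = "1",
) -> tuple[GenotypeMatrix, GenotypeMatrix, tuple[np.ndarray, np.ndarray]]:
    """Generate two parental panels with a controlled allele-frequency gap.

    Per SNP an ancestral frequency a ~ U(0.1, 0.9) is drawn and the two
    population frequencies set to f_P = a(1−divergence) and
    f_Q = a + divergence(1−a), so the per-SNP frequency difference equals
    ``divergence`` exactly: 0 makes the populations exchangeable, 1 fixes
    opposite alleles everywhere.  Genotypes are Hardy–Weinberg draws; SNPs
    are evenly spaced on a ``span_cm`` genetic map (chromosome-1-like by
    default).  Returns the two matrices (sharing one panel) and the
    per-population frequencies of the +1-pole allele.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, n_snps)
    f_p = anc * (1.0 - divergence)
    f_q = anc + divergence * (1.0 - anc)
    panel = _even_panel(n_snps, span_cm, chromosome)
    calls_p = rng.binomial(2, f_p[:, None], (n_snps, n_per_pop)) - 1.0
    calls_q = rng.binomial(2, f_q[:, None], (n_snps, n_per_pop)) - 1.0
    gm_p = GenotypeMatrix(panel, [f"P{i:03d}" for i in range(n_per_pop)], calls_p)
    gm_q = GenotypeMatrix(panel, [f"Q{i:03d}" for i in range(n_per_pop)], calls_q)
    return gm_p, gm_q, (f_p, f_q)


def _even_panel(n_snps: int, span_cm: float, chromosome: str) -> SNPPanel:
    g = np.linspace(0.0, span_cm, n_snps)
    bp = np.linspace(1, 250_000_000, n_snps).round().astype(np.int64)
    ids = np.array([f"snp{i:06d}" for i in range(n_snps)], dtype=object)
    return SNPPanel(ids, np.full(n_snps, chromosome, dtype=object), bp, g)


def haplotypes_from_frequencies(freqs: np.ndarray, n_haplotypes: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Phased 0/1 haplotypes drawn i.i.d. from per-SNP allele frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return (rng.random((freqs.size, n_haplotypes)) < freqs[:, None]).astype(np.int8)


def genotypes_from_breakpoints(
    diploid,
    freqs: tuple[np.ndarray, np.ndarray],
    panel: SNPPanel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Draw a diploid genotype vector from a pair of breakpoint chromosomes.

    The panel's genetic positions are rescaled onto the unit map of the
    chromosomes; at each SNP, each haplotype's allele is a Bernoulli draw
    from the frequency of its local ancestry (A → population P frequencies,
    B → population Q), and the two alleles are summed into an unphased
    dosage coded {−1, 0, +1}.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    f_p = np.asarray(freqs[0], dtype=float)
    f_q = np.asarray(freqs[1], dtype=float)
    if np.any((f_p < 0) | (f_p > 1)) or np.any((f_q < 0) | (f_q > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if f_p.size != panel.n_snps or f_q.size != panel.n_snps:
        raise ValueError("frequency vectors must match the panel size")
    u = panel.unit_positions()
    dosage = np.zeros(panel.n_snps)
    for chrom in diploid:
        anc = chrom.ancestry_at(u)
        f = np.where(anc == 1, f_q, f_p)
        dosage += rng.random(panel.n_snps) < f
    return dosage - 1.0
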