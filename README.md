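# steppco

Local genomic ancestry scans and wavelet-transform dating of admixture
events from genome-wide SNP data.

When two populations admix, recombination breaks the ancestral genomes
into blocks that get narrower and more numerous every generation, so the
block structure of an admixed genome carries a clock.  This package
implements a two-part method for reading it from unphased diploid SNP
genotypes:

1. **StepPCO** — a stepwise-PCA genome scan.  The first principal axis of
   two parental reference panels defines the direction separating the
   ancestries; an admixed chromosome is measured in K adaptive windows
   (K = 1024 by default), each grown from its center until the parental
   projections are separated by λ = 3 standard deviations,
   |Eα − Eβ| ≥ λ(σ(α)+σ(β)).  The window measurement
   M_w(e) = Σ a_i e_i / Σ |a_i| is rescaled so the parental poles sit at
   ±1, giving a per-chromosome ancestry signal S(r) and per-individual
   admixture proportions.
2. **Wavelet dating** — the signal is decomposed on the Haar basis;
   after noise filtering (amplitude thresholds, a high-frequency level
   cutoff and subtraction of the parental baseline, all calibrated on the
   parental panels), the dominant frequency C(γ) = Σ l·s_l / Σ s_l with
   s_l = Σ|wt_{l,k}|/2^(l−1) measures the typical ancestry-block width.
   Comparing the cohort's mean center with forward simulations of an
   admixed population (breakpoint-tracking recombination, growth from
   N = 1000 to 10,000 over 2000 generations, pulse or continuous
   migration) dates the admixture event with a 95% CI, at 30 years per
   generation.

The package also builds HAPMIX-style artificial hybrid genomes with
exponential ancestry maps and calibrates the linear relation between the
wavelet center and log ancestry switches per Morgan.

Intended users: population geneticists with two parental reference panels
and an admixed sample of unphased genotypes, and method developers who
need the forward simulator or the wavelet statistic on their own.

## Worked example

Simulate a 20% admixture pulse, sample a cohort 12 generations later,
genotype it on a synthetic chromosome-1-like panel, and recover both the
admixture proportion and the age of the event:

```python
import numpy as np
from steppco import (StepPCOModel, build_reference_curve,
                     synthesize_parental_panels)
from steppco.iodata import GenotypeMatrix, genotypes_from_breakpoints
from steppco.forward_sim import SimulationParams, simulate_population

P, Q, freqs = synthesize_parental_panels(8192, 40, divergence=0.3, seed=7)
run = simulate_population(SimulationParams(migration=0.2, max_generation=12,
                                           sampling_generations=(12,), seed=8))
chroms = run[0].chromosomes
rng = np.random.default_rng(9)
calls = np.column_stack([
    genotypes_from_breakpoints((chroms[2*i], chroms[2*i+1]), freqs,
                               P.panel, rng=rng) for i in range(10)])
cohort = GenotypeMatrix(P.panel, [f"IND{i:02d}" for i in range(10)], calls)

res = StepPCOModel(cohort, P, Q, n_bins=1024).fit()
print(res.summary())
```

```
StepPCO admixture scan
======================
SNPs: 8192   bins: 1024 (usable 1024)   lambda: 3
mean window size: 37.1 SNPs
cohort mean Q-ancestry proportion: 0.176
cohort mean WT center: 2.275

sample  q_proportion  wt_center
 IND00         0.203      2.359
 IND01         0.320      1.713
 ...
```

The cohort averages 17.6% Q ancestry — the generator's migrant fraction
was 20% — and individual proportions vary realistically (0.07–0.32).
Dating compares the cohort center with a reference curve simulated at the
matching rate; because this cohort is measured through genotypes and a
StepPCO frame, the curve is built through the same measurement
(`center_fn`), which keeps curve and cohort on one scale:

```python
def center_fn(dip, rng_):
    from steppco.frame import steppco_signal
    from steppco.wavelets import filtered_center
    g = genotypes_from_breakpoints(dip, freqs, P.panel, rng=rng_)
    return filtered_center(steppco_signal(g, res.frame).values,
                           res.frame.span_morgans, 1.0,
                           noise_filter=res.noise_filter)

curve = build_reference_curve(0.2, n_sims=20, max_generation=50, seed=10,
                              center_fn=center_fn)
print(res.date(curve).summary())
```

```
Admixture dating
----------------
observed WT center : 2.275
reference rate (m) : 0.200
time since admixture: 14.4 generations (95% CI 9.1-21.6)
in years (30 yr/gen): 431 (272-647)
```

The 95% CI covers the true age (12 generations).  See `docs/methods.md`
for the models, filter calibration, CI construction and limitations.

A command-line interface exposes the same pipeline on files
(`steppco --help`): subcommands `steppco` (scan), `wavelet` (spectral
summaries), `simulate`, `hybrids` and `date`; genotypes travel as plain
TSV (snp id, chromosome, bp, cM, then 0/1/2 dosage columns), with PLINK
`.traw` and biallelic VCF ingestion available.

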