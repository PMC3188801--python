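"""Shared fixtures: the synthetic study conditions used across the suite.

The heavy objects (StepPCO frame at the standard window resolution,
reference curves, replicate population runs) are session-scoped so the
dating and recovery tests share one set of simulations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from steppco.dating import build_reference_curve
from steppco.forward_sim import SimulationParams, simulate_population
from steppco.frame import (
    admixture_proportion,
    build_frame,
    signals_for,
    steppco_signal,
)
from steppco.iodata import genotypes_from_breakpoints, synthesize_parental_panels
from steppco.wavelets import estimate_noise_filter, filtered_center, haar_transform

# Study conditions: ~8k SNPs over a chromosome-1-like 278 cM map with a
# parental allele-frequency divergence of 0.3 gives a realistic window
# resolution for array data (~0.5% of the chromosome per window).
N_SNPS = 8192
N_PER_POP = 40
DIVERGENCE = 0.3
COHORT_GENS = (5, 10, 20, 25, 50, 100)


@pytest.fixture(scope="session")
def pipeline():
    P, Q, freqs = synthesize_parental_panels(N_SNPS, N_PER_POP, DIVERGENCE,
                                             seed=1234)
    frame = build_frame(P, Q, n_bins=1024)
    span = frame.span_morgans
    parental_signals = signals_for(P, frame) + signals_for(Q, frame)
    spectra = [haar_transform(np.nan_to_num(s.values), span)
               for s in parental_signals]
    noise_filter = estimate_noise_filter(spectra)
    return {
        "P": P, "Q": Q, "freqs": freqs, "frame": frame, "span": span,
        "parental_signals": parental_signals, "noise_filter": noise_filter,
    }


@pytest.fixture(scope="session")
def run_cohort(pipeline):
    """Full-pipeline cohort statistics from one sampled generation.

    Pairs the sampled breakpoint chromosomes into diploids, draws genotypes
    at the study divergence, runs StepPCO and the filtered wavelet center,
    and returns (per-diploid centers, per-diploid Q proportions).
    """

    def _run(sample, rng):
        chroms = sample.chromosomes
        order = rng.permutation(len(chroms))
        centers, props = [], []
        for i in range(len(order) // 2):
            dip = (chroms[order[2 * i]], chroms[order[2 * i + 1]])
            g = genotypes_from_breakpoints(dip, pipeline["freqs"],
                                           pipeline["P"].panel, rng=rng)
            sig = steppco_signal(g, pipeline["frame"])
            props.append(admixture_proportion(sig))
            centers.append(filtered_center(
                sig.values, pipeline["span"], 1.0,
                noise_filter=pipeline["noise_filter"]))
        return np.asarray(centers), np.asarray(props)

    return _run


def _replicate_runs(m: float, n_reps: int, seed: int):
    children = np.random.SeedSequence(seed).spawn(n_reps)
    runs = []
    for child in children:
        params = SimulationParams(migration=m, max_generation=max(COHORT_GENS),
                                  sampling_generations=COHORT_GENS, seed=child)
        runs.append(simulate_population(params))
    return runs


@pytest.fixture(scope="session")
def cohort_sims_m20():
    return _replicate_runs(0.2, 20, 31415)


@pytest.fixture(scope="session")
def cohort_sims_m40():
    return _replicate_runs(0.4, 20, 27182)


@pytest.fixture(scope="session")
def curve_m20():
    return build_reference_curve(0.2, n_sims=20, max_generation=300, seed=2024)


@pytest.fixture(scope="session")
def curve_m40():
    # horizon one sampling point past 100 so cohorts at true T=100 invert
    # without boundary truncation
    return build_reference_curve(0.4, n_sims=20, max_generation=173, seed=2025)


@pytest.fixture(scope="session")
def steppco_center_fn(pipeline):
    """Diploid -> WT center measured through genotypes and the StepPCO
    frame, the same way the test cohorts are measured."""

    def _center(dip, rng):
        g = genotypes_from_breakpoints(dip, pipeline["freqs"],
                                       pipeline["P"].panel, rng=rng)
        sig = steppco_signal(g, pipeline["frame"])
        return filtered_center(sig.values, pipeline["span"], 1.0,
                               noise_filter=pipeline["noise_filter"])

    return _center


@pytest.fixture(scope="session")
def measured_curve_m20(steppco_center_fn):
    # reference curve under the StepPCO measurement model, for dating
    # cohorts that are themselves measured through StepPCO
    return build_reference_curve(0.2, n_sims=20, max_generation=173,
                                 seed=2026, center_fn=steppco_center_fn)


@pytest.fixture(scope="session")
def measured_curve_m40(steppco_center_fn):
    return build_reference_curve(0.4, n_sims=20, max_generation=173,
                                 seed=2027, center_fn=steppco_center_fn)
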