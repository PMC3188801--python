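"""Forward-time breakpoint-tracking simulation of an admixed population.

Chromosomes are modelled purely by their ancestry-switch coordinates on the
unit genetic map, which makes whole-population recombination dynamics cheap:
a meiosis only merges two sorted coordinate lists.  The demographic model is
a growing population of monogamous random pairs with Poisson offspring
numbers, founded by a resident population A that receives migrants from a
population B either as a single pulse or as a constant influx spread over a
number of generations.

Coordinates are fractions of the total genetic length of the chromosome;
the defaults emulate human chromosome 1 (2.78 crossovers per meiosis,
2.78 Morgans of map length).
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .wavelets import (
    default_max_level,
    drop_high_levels,
    haar_transform,
    normalize_center,
    wavelet_center,
    wavelet_summary,
)

#: crossovers per chromosome per generation observed for human chromosome 1
CHR1_RECOMBINATION_RATE = 2.78
#: genetic length of human chromosome 1 in Morgans (1 Morgan = 1 expected
#: crossover per meiosis, so numerically equal to the rate above)
CHR1_LENGTH_MORGANS = 2.78
#: centers are reported on the scale of a 1-Morgan signal: the length
#: normalization subtracts log2 of the chromosome's genetic length
REFERENCE_LENGTH_MORGANS = 1.0

# Geometric sampling grid (ratio ~1.41) used when recording statistics at
# "exponentially growing" time points; capped at 2000 generations.
SAMPLING_SCHEDULE = (
    1, 2, 3, 4, 6, 8, 11, 16, 22, 31, 44, 62, 87, 123, 173, 244,
    344, 486, 686, 968, 1367, 1930,
)

ANCESTRY_A = 0
ANCESTRY_B = 1


class BreakpointChromosome:
    """A chromosome represented by its ancestry switch points.

    Parameters
    ----------
    switches : sequence of float
        Strictly increasing coordinates in (0, 1) at which the local
        ancestry changes.
    start : int
        Ancestry label of the leftmost segment; 0 = A (resident),
        1 = B (migrant).
    """

    __slots__ = ("switches", "start")

    def __init__(self, switches: Sequence[float] = (), start: int = ANCESTRY_A):
        self.switches = switches if type(switches) is list else list(switches)
        self.start = int(start)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BreakpointChromosome(n_breakpoints={self.n_breakpoints}, start={self.start})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BreakpointChromosome)
            and self.start == other.start
            and self.switches == other.switches
        )

    def validate(self) -> None:
        sw = self.switches
        if any(not (0.0 < x < 1.0) for x in sw):
            raise ValueError("switch positions must lie strictly inside (0, 1)")
        if any(sw[i] >= sw[i + 1] for i in range(len(sw) - 1)):
            raise ValueError("switch positions must be strictly increasing")
        if self.start not in (ANCESTRY_A, ANCESTRY_B):
            raise ValueError("start ancestry label must be 0 or 1")

    @property
    def n_breakpoints(self) -> int:
        return len(self.switches)

    @property
    def alpha(self) -> float:
        """Fraction of the chromosome with B (migrant) ancestry."""
        if not self.switches:
            return float(self.start)
        pts = np.empty(len(self.switches) + 2)
        pts[0] = 0.0
        pts[1:-1] = self.switches
        pts[-1] = 1.0
        seg = np.diff(pts)
        # segment i has label start ^ (i & 1); B segments start at index
        # 0 when start == 1, at index 1 otherwise
        off = 0 if self.start == ANCESTRY_B else 1
        return float(seg[off::2].sum())

    def ancestry_at(self, x) -> np.ndarray:
        """Ancestry label (0/1) at one or more positions on the unit map."""
        x = np.asarray(x, dtype=float)
        counts = np.searchsorted(np.asarray(self.switches), x, side="right")
        return (self.start + counts) % 2

    def b_fraction(self, edges: np.ndarray) -> np.ndarray:
        """Fraction of B ancestry inside each interval of a bin grid.

        ``edges`` is an increasing array of K+1 bin edges in [0, 1];
        returns K per-bin B-ancestry fractions.
        """
        edges = np.asarray(edges, dtype=float)
        sw = np.asarray(self.switches, dtype=float)
        pts = np.concatenate(([0.0], sw))
        seg_is_b = (self.start + np.arange(pts.size)) % 2 == ANCESTRY_B
        seg_len = np.diff(np.append(pts, 1.0))
        cum_b = np.concatenate(([0.0], np.cumsum(np.where(seg_is_b, seg_len, 0.0))))
        idx = np.searchsorted(pts, edges, side="right") - 1
        measure = cum_b[idx] + np.where(seg_is_b[idx], edges - pts[idx], 0.0)
        width = np.diff(edges)
        return np.diff(measure) / width


PURE_A = BreakpointChromosome((), ANCESTRY_A)
PURE_B = BreakpointChromosome((), ANCESTRY_B)


@dataclass
class HotspotMap:
    """Piecewise-linear genetic<->physical map with recombination hotspots.

    The chromosome's physical coordinate runs over [0, 1]; ``cdf_physical``
    and ``cdf_genetic`` are matching knot vectors of the genetic-map CDF,
    with endpoints (0, 0) and (1, 1).  ``hotspot_intervals`` lists the
    physical (start, end) extents of the hotspots.
    """

    cdf_physical: np.ndarray
    cdf_genetic: np.ndarray
    hotspot_intervals: np.ndarray  # shape (n, 2)

    def __post_init__(self):
        p = np.asarray(self.cdf_physical, float)
        g = np.asarray(self.cdf_genetic, float)
        if p.shape != g.shape or p.ndim != 1 or p.size < 2:
            raise ValueError("malformed map knots")
        if np.any(np.diff(p) < 0) or np.any(np.diff(g) < 0):
            raise ValueError("map CDF must be monotone")
        if not (p[0] == 0 and g[0] == 0 and p[-1] == 1 and g[-1] == 1):
            raise ValueError("map CDF endpoints must be (0,0) and (1,1)")

    def genetic_to_physical(self, u) -> np.ndarray:
        """Invert the genetic CDF: map uniform genetic positions to physical."""
        return np.interp(u, self.cdf_genetic, self.cdf_physical)

    def physical_to_genetic(self, x) -> np.ndarray:
        return np.interp(x, self.cdf_physical, self.cdf_genetic)

    def fraction_in_hotspots(self, positions: np.ndarray) -> float:
        if len(self.hotspot_intervals) == 0:
            return 0.0
        pos = np.asarray(positions, float)
        starts = self.hotspot_intervals[:, 0]
        ends = self.hotspot_intervals[:, 1]
        i = np.searchsorted(starts, pos, side="right") - 1
        i = np.clip(i, 0, len(starts) - 1)
        inside = (pos >= starts[i]) & (pos < ends[i])
        return float(inside.mean())


def hotspot_map(
    n_hotspots: int = 800,
    hotspot_width: float = 1e-5,
    hotspot_mass: float = 0.8,
    intensity_shape: float = 0.3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> HotspotMap:
    """Generate a random recombination map with hotspots.

    ``hotspot_mass`` is the fraction of all recombination concentrated in
    hotspots (0.8 emulates the human genome); hotspot positions are placed
    by exponential spacing, widths are fixed at ``hotspot_width`` (as a
    fraction of the physical length), and per-hotspot intensities are
    Gamma-distributed with shape ``intensity_shape``.  These parameter
    values are placeholders to be overridden with literature values when
    fidelity to a particular genome is required.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_hotspots == 0 or hotspot_mass == 0.0:
        knots = np.array([0.0, 1.0])
        return HotspotMap(knots, knots.copy(), np.empty((0, 2)))
    if not (0.0 < hotspot_mass <= 1.0):
        raise ValueError("hotspot_mass must lie in (0, 1]")
    gaps = rng.exponential(1.0 / n_hotspots, n_hotspots)
    centers = np.cumsum(gaps)
    centers = centers[centers < 1.0 - hotspot_width]
    if centers.size == 0:
        raise ValueError("degenerate hotspot map: no hotspots fell inside the chromosome")
    starts = np.maximum(centers - hotspot_width / 2.0, 0.0)
    ends = np.minimum(starts + hotspot_width, 1.0)
    # drop overlaps to keep intervals disjoint
    keep = np.concatenate(([True], starts[1:] >= ends[:-1]))
    starts, ends = starts[keep], ends[keep]
    weights = rng.gamma(intensity_shape, 1.0, starts.size)
    if weights.sum() <= 0:
        raise ValueError("degenerate hotspot map: zero total hotspot intensity")
    weights = weights / weights.sum() * hotspot_mass

    background = 1.0 - hotspot_mass
    # knots: 0, (start, end) of each hotspot, 1
    phys = np.empty(2 * starts.size + 2)
    gen = np.empty_like(phys)
    phys[0], gen[0] = 0.0, 0.0
    outside = 1.0 - (ends - starts).sum()
    g = 0.0
    j = 1
    prev = 0.0
    for s, e, w in zip(starts, ends, weights):
        g += background * (s - prev) / outside
        phys[j], gen[j] = s, g
        j += 1
        g += w
        phys[j], gen[j] = e, g
        j += 1
        prev = e
    g += background * (1.0 - prev) / outside
    phys[j], gen[j] = 1.0, g
    gen /= gen[j]
    gen[j] = 1.0
    return HotspotMap(phys, gen, np.column_stack([starts, ends]))


def crossover_positions(
    rate: float,
    rng: np.random.Generator,
    recomb_map: HotspotMap | None = None,
) -> np.ndarray:
    """Draw the crossover positions of one meiosis.

    The number of crossovers is Poisson(``rate``); positions are uniform on
    the genetic map and, when a hotspot map is given, are translated to
    physical coordinates through the map's inverse CDF.
    """
    if rate < 0:
        raise ValueError("recombination rate must be non-negative")
    k = rng.poisson(rate)
    if k == 0:
        return np.empty(0)
    u = rng.random(k)
    u.sort()
    if recomb_map is not None:
        u = recomb_map.genetic_to_physical(u)
    return u


def _gamete(c0: BreakpointChromosome, c1: BreakpointChromosome,
            xs: list, src: int) -> BreakpointChromosome:
    """Merge two parental chromosomes at crossover points ``xs``.

    ``src`` selects the chromosome contributing the leftmost segment.
    Crossovers between same-ancestry segments are silent (coalesced), so the
    output switches are true ancestry switches.
    """
    if not xs:
        return (c0, c1)[src]
    chroms = (c0, c1)
    out: list = []
    cur = src
    prev = 0.0
    glab = -1
    cur_anc = -1
    for x in xs + [1.0]:
        c = chroms[cur]
        sw = c.switches
        lo = bisect_right(sw, prev)
        hi = bisect_left(sw, x)
        anc = c.start ^ (lo & 1)
        if glab < 0:
            glab = anc
        elif anc != cur_anc:
            out.append(prev)
        if hi > lo:
            out.extend(sw[lo:hi])
            cur_anc = anc ^ ((hi - lo) & 1)
        else:
            cur_anc = anc
        cur ^= 1
        prev = x
    return BreakpointChromosome(out, glab)


def meiosis(
    parent_pair: tuple[BreakpointChromosome, BreakpointChromosome],
    rate: float = CHR1_RECOMBINATION_RATE,
    rng: np.random.Generator | None = None,
    recomb_map: HotspotMap | None = None,
) -> BreakpointChromosome:
    """Produce one gamete from a diploid parent.

    Poisson(``rate``) crossovers are placed uniformly on the genetic map
    (or via the hotspot map's inverse CDF) and the gamete alternates between
    the two parental chromosomes, starting from a fair random choice.
    """
    if rng is None:
        rng = np.random.default_rng()
    xs = crossover_positions(rate, rng, recomb_map)
    src = int(rng.integers(0, 2))
    if xs.size == 0:
        return parent_pair[src]
    return _gamete(parent_pair[0], parent_pair[1], list(xs), src)


@dataclass
class SimulationParams:
    """Demographic and recombination parameters of a forward simulation.

    ``migration`` is the total migrant fraction m; with
    ``migration_duration == 1`` the full pulse enters at generation 0,
    otherwise m/d of the population is replaced by migrants in each of the
    first d generations (continuous admixture).
    """

    migration: float = 0.20
    migration_duration: int = 1
    n0: int = 1000
    n_final: int = 10_000
    growth_span: int = 2000
    recombination_rate: float = CHR1_RECOMBINATION_RATE
    recomb_map: HotspotMap | None = None
    max_generation: int = 2000
    sampling_generations: tuple[int, ...] | None = None
    n_sample_chromosomes: int = 100
    seed: int | None = None

    @property
    def growth_factor(self) -> float:
        return (self.n_final / self.n0) ** (1.0 / self.growth_span)

    @property
    def schedule(self) -> tuple[int, ...]:
        if self.sampling_generations is not None:
            return tuple(sorted(set(self.sampling_generations)))
        gens = [t for t in SAMPLING_SCHEDULE if t <= self.max_generation]
        if self.max_generation not in gens:
            gens.append(self.max_generation)
        return tuple(gens)

    def validate(self) -> None:
        if not (0.0 <= self.migration < 1.0):
            raise ValueError("migration fraction must lie in [0, 1)")
        if self.recombination_rate < 0:
            raise ValueError("recombination rate must be non-negative")
        if self.migration_duration < 1:
            raise ValueError("migration_duration must be >= 1")
        if self.n0 < 2 or self.n_final < 2:
            raise ValueError("population sizes must be >= 2")
        if self.max_generation < 1:
            raise ValueError("max_generation must be >= 1")


@dataclass
class GenerationSample:
    """Chromosomes sampled from one generation of a simulation."""

    generation: int
    chromosomes: list = field(repr=False)
    population_size: int = 0

    @property
    def alphas(self) -> np.ndarray:
        return np.array([c.alpha for c in self.chromosomes])

    @property
    def breakpoints(self) -> np.ndarray:
        return np.array([c.n_breakpoints for c in self.chromosomes])

    @property
    def e_alpha(self) -> float:
        return float(self.alphas.mean())

    @property
    def var_alpha(self) -> float:
        a = self.alphas
        return float(a.var(ddof=1)) if a.size > 1 else 0.0


def simulate_population(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list[GenerationSample]:
    """Run the forward simulation and return the sampled generations.

    Each generation the population is split randomly into monogamous pairs;
    each pair produces a Poisson number of offspring whose mean tracks the
    geometric growth schedule n0 -> n_final (mean = target size / number of
    pairs), so the census follows the schedule with only non-accumulating
    Poisson fluctuation instead of drifting as a free branching process.
    Offspring receive one gamete from each parent.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    g = params.growth_factor
    rate = params.recombination_rate
    rmap = params.recomb_map

    pop: list = [(PURE_A, PURE_A)] * params.n0
    if params.migration_duration == 1:
        n_mig = int(round(params.migration * params.n0))
        pop = [(PURE_B, PURE_B)] * n_mig + pop[n_mig:]
    per_gen_influx = params.migration / params.migration_duration

    schedule = set(params.schedule)
    samples: list[GenerationSample] = []
    target = float(params.n0)

    for gen in range(1, params.max_generation + 1):
        n = len(pop)
        order = rng.permutation(n)
        n_pairs = n // 2
        if n_pairs == 0:
            raise RuntimeError(
                f"population went extinct at generation {gen} (seed={params.seed})"
            )
        target *= g
        counts = rng.poisson(target / n_pairs, n_pairs)
        total = int(counts.sum())
        if total == 0:
            raise RuntimeError(
                f"population went extinct at generation {gen} (seed={params.seed})"
            )
        nxo = rng.poisson(rate, 2 * total)
        starts = rng.integers(0, 2, 2 * total)
        upos = rng.random(int(nxo.sum()))
        if rmap is not None:
            upos = rmap.genetic_to_physical(upos)
        newpop: list = []
        append = newpop.append
        gi = 0
        ui = 0
        for pi in range(n_pairs):
            c = counts[pi]
            if c == 0:
                continue
            ia, ib = order[2 * pi], order[2 * pi + 1]
            a0, a1 = pop[ia]
            b0, b1 = pop[ib]
            for _ in range(c):
                k = nxo[gi]
                if k:
                    xs = sorted(upos[ui : ui + k])
                    ui += k
                    ga = _gamete(a0, a1, xs, int(starts[gi]))
                else:
                    ga = (a0, a1)[starts[gi]]
                gi += 1
                k = nxo[gi]
                if k:
                    xs = sorted(upos[ui : ui + k])
                    ui += k
                    gb = _gamete(b0, b1, xs, int(starts[gi]))
                else:
                    gb = (b0, b1)[starts[gi]]
                gi += 1
                append((ga, gb))
        pop = newpop

        if params.migration_duration > 1 and gen <= params.migration_duration:
            n_mig = int(round(per_gen_influx * len(pop)))
            if n_mig > 0:
                idx = rng.choice(len(pop), n_mig, replace=False)
                for i in idx:
                    pop[i] = (PURE_B, PURE_B)

        if gen in schedule:
            n_take = min(params.n_sample_chromosomes, len(pop))
            idx = rng.choice(len(pop), n_take, replace=False)
            sides = rng.integers(0, 2, n_take)
            chroms = [pop[i][s] for i, s in zip(idx, sides)]
            samples.append(GenerationSample(gen, chroms, len(pop)))
    return samples


def expected_breakpoints(t_gen: float, rate: float, e_alpha: float,
                         var_alpha: float) -> float:
    """Expected ancestry switches per chromosome, 2*T*R*(Eα(1−Eα) − var α)."""
    if not (0.0 <= e_alpha <= 1.0):
        raise ValueError("e_alpha must lie in [0, 1]")
    if var_alpha < 0:
        raise ValueError("var_alpha must be non-negative")
    return 2.0 * t_gen * rate * (e_alpha * (1.0 - e_alpha) - var_alpha)


def chromosomes_to_signal(
    diploid: tuple[BreakpointChromosome, BreakpointChromosome],
    n_bins: int = 1024,
    length_morgans: float = CHR1_LENGTH_MORGANS,
):
    """Exact per-bin ancestry dosage of a diploid, on the StepPCO scale.

    Each of ``n_bins`` equal bins gets the B-ancestry fraction of its
    genetic span summed over the two chromosomes and mapped linearly to
    [−1, +1]: pure A → −1, pure B → +1, one segment of each → 0.
    """
    from .frame import AncestrySignal  # local import to avoid cycle

    if n_bins < 1 or (n_bins & (n_bins - 1)) != 0:
        raise ValueError("n_bins must be a power of two")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values = diploid[0].b_fraction(edges) + diploid[1].b_fraction(edges) - 1.0
    centers_cm = (edges[:-1] + edges[1:]) / 2.0 * length_morgans * 100.0
    return AncestrySignal(values=values, bin_centers=centers_cm,
                          length_morgans=length_morgans)


def diploid_wavelet_center(
    diploid,
    n_bins: int = 1024,
    max_level: int | None = None,
    length_morgans: float = CHR1_LENGTH_MORGANS,
    reference_length: float = REFERENCE_LENGTH_MORGANS,
) -> float:
    """Length-normalized WT center of a diploid's exact ancestry signal.

    Returns NaN when the filtered spectrum carries no signal (for example a
    diploid with uniform ancestry).
    """
    sig = chromosomes_to_signal(diploid, n_bins, length_morgans)
    spec = haar_transform(sig.values, length_morgans=length_morgans)
    if max_level is None:
        max_level = default_max_level(spec.levels)
    spec = drop_high_levels(spec, max_level)
    summary = wavelet_summary(spec)
    if summary.total <= 0.0:
        return float("nan")
    c = wavelet_center(summary)
    return normalize_center(c, length_morgans, reference_length)


def collect_statistics(
    samples: list[GenerationSample],
    n_bins: int = 1024,
    max_level: int | None = None,
    length_morgans: float = CHR1_LENGTH_MORGANS,
    reference_length: float = REFERENCE_LENGTH_MORGANS,
    recombination_rate: float = CHR1_RECOMBINATION_RATE,
    rng: np.random.Generator | None = None,
    center_fn=None,
) -> pd.DataFrame:
    """Per-generation admixture, breakpoint and wavelet-center statistics.

    Sampled chromosomes are paired at random (without replacement) into
    diploids to match unphased data; the WT center of each diploid is
    computed after removing levels above ``max_level`` (default: level 7
    for 1024 bins) and normalizing for chromosome length.

    ``center_fn(diploid, rng) -> float`` replaces the exact-signal center
    with a custom measurement (e.g. the genotype + StepPCO pipeline) so
    that reference curves can be built under the same measurement model as
    the cohorts that will be dated against them.
    """
    if not samples:
        raise ValueError("no generation samples supplied")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for s in samples:
        alphas = s.alphas
        bkpts = s.breakpoints
        n = len(s.chromosomes)
        order = rng.permutation(n)
        centers = []
        for i in range(n // 2):
            dip = (s.chromosomes[order[2 * i]], s.chromosomes[order[2 * i + 1]])
            if center_fn is not None:
                c = center_fn(dip, rng)
            else:
                c = diploid_wavelet_center(dip, n_bins, max_level,
                                           length_morgans, reference_length)
            if math.isfinite(c):
                centers.append(c)
        centers = np.asarray(centers)
        e_alpha = float(alphas.mean())
        var_alpha = float(alphas.var(ddof=1)) if n > 1 else 0.0
        rows.append({
            "generation": s.generation,
            "n_chromosomes": n,
            "e_alpha": e_alpha,
            "var_alpha": var_alpha,
            "mean_breakpoints": float(bkpts.mean()),
            "expected_breakpoints": expected_breakpoints(
                s.generation, recombination_rate, e_alpha, var_alpha),
            "mean_center": float(centers.mean()) if centers.size else float("nan"),
            "sd_center": float(centers.std(ddof=1)) if centers.size > 1 else float("nan"),
            "n_centers": int(centers.size),
        })
    return pd.DataFrame(rows)
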