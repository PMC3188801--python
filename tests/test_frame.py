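"""StepPCO frame construction, window logic and ancestry signals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from steppco.forward_sim import BreakpointChromosome, PURE_A, PURE_B, chromosomes_to_signal
from steppco.frame import (
    PrincipalAxis,
    Window,
    admixture_proportion,
    build_frame,
    is_separated,
    optimal_window,
    principal_axis,
    signals_for,
    steppco_signal,
    window_measurement,
)
from steppco.iodata import GenotypeMatrix, genotypes_from_breakpoints, synthesize_parental_panels


@pytest.fixture(scope="module")
def small_panels():
    P, Q, freqs = synthesize_parental_panels(400, 20, 0.5, seed=7, span_cm=50.0)
    return P, Q, freqs


@pytest.fixture(scope="module")
def small_frame(small_panels):
    P, Q, _ = small_panels
    return build_frame(P, Q, n_bins=64)


class TestPrincipalAxis:
    def test_matches_dense_eigendecomposition(self):
        P, Q, _ = synthesize_parental_panels(40, 6, 0.5, seed=3)
        axis = principal_axis(P, Q)
        X = np.hstack([P.calls, Q.calls])
        Xc = X - X.mean(axis=1, keepdims=True)
        vals, vecs = np.linalg.eigh(Xc @ Xc.T)
        lead = vecs[:, -1]
        cos = abs(np.dot(lead, axis.coefficients))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_orientation_points_to_q(self):
        P, Q, _ = synthesize_parental_panels(60, 8, 0.8, seed=4)
        axis = principal_axis(P, Q)
        Xc = np.hstack([P.calls, Q.calls])
        Xc = Xc - Xc.mean(axis=1, keepdims=True)
        q_proj = (Xc[:, P.n_samples:] * axis.coefficients[:, None]).sum(axis=0)
        assert q_proj.mean() > 0

    def test_fixed_difference_panels_fully_separate(self):
        P, Q, _ = synthesize_parental_panels(30, 4, 1.0, seed=5)
        axis = principal_axis(P, Q)
        p_proj = [window_measurement(P.calls[:, j], Window(0, 29, 0, 0), axis)
                  for j in range(4)]
        q_proj = [window_measurement(Q.calls[:, j], Window(0, 29, 0, 0), axis)
                  for j in range(4)]
        assert max(p_proj) < min(q_proj)
        assert is_separated(p_proj, q_proj, 3.0)

    def test_degenerate_panels_rejected(self):
        P, Q, _ = synthesize_parental_panels(10, 3, 0.5, seed=6)
        zeros = GenotypeMatrix(P.panel, ["a", "b"], np.zeros((10, 2)))
        with pytest.raises(ValueError, match="degenerate|axis"):
            principal_axis(zeros, GenotypeMatrix(P.panel, ["c", "d"],
                                                 np.zeros((10, 2))))


class TestWindowMeasurement:
    AXIS = PrincipalAxis(np.array([2.0, -1.0, 1.0]), np.zeros(3))
    W = Window(0, 2, 0.0, 1.0)

    def test_printed_formula_instance(self):
        assert window_measurement(np.array([1.0, 1.0, 0.0]), self.W,
                                  self.AXIS) == pytest.approx(0.25)

    def test_all_heterozygote_is_zero(self):
        assert window_measurement(np.zeros(3), self.W, self.AXIS) == 0.0

    def test_invariant_under_positive_axis_rescaling(self):
        e = np.array([1.0, -1.0, 0.0])
        scaled = PrincipalAxis(3.0 * self.AXIS.coefficients, np.zeros(3))
        assert window_measurement(e, self.W, self.AXIS) == pytest.approx(
            window_measurement(e, self.W, scaled))

    def test_missing_calls_drop_from_both_sums(self):
        e = np.array([1.0, np.nan, 0.0])
        # (2*1 + 0) / (2 + 1)
        assert window_measurement(e, self.W, self.AXIS) == pytest.approx(2 / 3)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            window_measurement(np.full(3, np.nan), self.W, self.AXIS)


class TestSeparation:
    def test_equal_means_never_separated(self):
        assert not is_separated([0.1, 0.3], [0.3, 0.1], 0.5)

    def test_zero_sd_limit(self):
        assert is_separated([1.0, 1.0], [-1.0, -1.0], 3.0)

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 5.0))
    def test_agrees_with_direct_inequality(self, seed, lam):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        expect = abs(a.mean() - b.mean()) >= lam * (a.std(ddof=1) + b.std(ddof=1))
        assert is_separated(a, b, lam) == expect


class TestOptimalWindow:
    def _brute_force(self, x, axis, P, Q, lam):
        # enumerate candidate windows as prefixes of the SNPs sorted by
        # distance from x (ties toward the lower index), independent of the
        # incremental two-pointer growth used by the implementation
        pos = P.panel.genetic_pos
        order = sorted(range(pos.size), key=lambda i: (abs(pos[i] - x), i))
        for k in range(1, pos.size + 1):
            members = sorted(order[:k])
            assert members == list(range(members[0], members[-1] + 1))
            w = Window(members[0], members[-1], x, pos[members[-1]] - pos[members[0]])
            a = [window_measurement(P.calls[:, j], w, axis)
                 for j in range(P.n_samples)]
            b = [window_measurement(Q.calls[:, j], w, axis)
                 for j in range(Q.n_samples)]
            if is_separated(a, b, lam):
                return w
        return None

    def test_matches_brute_force_scan(self):
        P, Q, _ = synthesize_parental_panels(60, 10, 0.5, seed=8, span_cm=30.0)
        axis = principal_axis(P, Q)
        for x in (0.0, 7.3, 15.0, 22.2, 30.0):
            got = optimal_window(x, axis, P, Q, 3.0)
            want = self._brute_force(x, axis, P, Q, 3.0)
            assert got.usable
            assert (got.first, got.last) == (want.first, want.last)

    def test_zero_divergence_is_flagged_unusable(self):
        P, Q, _ = synthesize_parental_panels(120, 10, 0.0, seed=9)
        axis = principal_axis(P, Q)
        w = optimal_window(60.0, axis, P, Q, 3.0)
        assert not w.usable
        assert (w.first, w.last) == (0, 119)  # grew to the whole chromosome

    def test_fixed_panels_need_a_single_snp(self):
        P, Q, _ = synthesize_parental_panels(50, 6, 1.0, seed=10)
        axis = principal_axis(P, Q)
        w = optimal_window(100.0, axis, P, Q, 3.0)
        assert w.usable and w.n_snps == 1


class TestBuildFrame:
    def test_bin_centers_are_equispaced_midpoints(self):
        # moderate divergence so the minimal windows still cover the ends
        P, Q, _ = synthesize_parental_panels(64, 6, 0.3, seed=11, span_cm=7.0)
        frame = build_frame(P, Q, n_bins=8)
        np.testing.assert_allclose(frame.bin_centers,
                                   0.4375 + 0.875 * np.arange(8))

    def test_power_of_two_enforced(self, small_panels):
        P, Q, _ = small_panels
        with pytest.raises(ValueError, match="power of two"):
            build_frame(P, Q, n_bins=100)

    def test_every_usable_window_satisfies_the_separation_condition(self, small_panels, small_frame):
        P, Q, _ = small_panels
        for k, w in enumerate(small_frame.windows):
            a = [window_measurement(P.calls[:, j], w, small_frame.axis)
                 for j in range(P.n_samples)]
            b = [window_measurement(Q.calls[:, j], w, small_frame.axis)
                 for j in range(Q.n_samples)]
            if small_frame.usable[k]:
                assert is_separated(a, b, 3.0)

    def test_windows_cover_every_snp_without_gaps(self, small_frame):
        covered = np.zeros(400, dtype=bool)
        for w in small_frame.windows:
            covered[w.first:w.last + 1] = True
        assert covered.all()

    def test_audit_report_schema(self, small_frame):
        audit = small_frame.audit()
        assert audit["n_bins"] == 64 and len(audit["bins"]) == 64
        row = audit["bins"][0]
        assert {"center_cm", "n_snps", "width_cm", "separation",
                "usable"} <= set(row)

    def test_window_width_shrinks_with_divergence(self):
        widths = []
        for d in (0.2, 0.6):
            P, Q, _ = synthesize_parental_panels(800, 20, d, seed=12)
            frame = build_frame(P, Q, n_bins=256)
            widths.append(np.mean([w.n_snps for w in frame.windows]))
        assert widths[1] < widths[0]


class TestSignals:
    def test_parental_holdout_samples_sit_at_their_poles(self, pipeline):
        # at the study's window resolution, fresh draws from the parental
        # allele frequencies must land on the normalized poles
        rng = np.random.default_rng(13)
        for f, pole in ((pipeline["freqs"][0], -1.0),
                        (pipeline["freqs"][1], +1.0)):
            means = [np.nanmean(steppco_signal(rng.binomial(2, f) - 1.0,
                                               pipeline["frame"]).values)
                     for _ in range(5)]
            assert np.mean(means) == pytest.approx(pole, abs=0.1)

    def test_one_haplotype_from_each_population_sits_at_zero(self):
        # fixed differences make 1-SNP windows; n_bins >= n_snps keeps coverage
        P, Q, _ = synthesize_parental_panels(200, 8, 1.0, seed=14)
        frame = build_frame(P, Q, n_bins=256)
        het = np.zeros(200)  # fixed differences: one allele from each side
        sig = steppco_signal(het, frame)
        np.testing.assert_allclose(sig.values, 0.0, atol=1e-9)

    def test_sign_matches_true_local_ancestry(self, pipeline):
        dip = (BreakpointChromosome([0.3, 0.6], start=0),
               BreakpointChromosome([0.5], start=1))
        rng = np.random.default_rng(15)
        g = genotypes_from_breakpoints(dip, pipeline["freqs"],
                                       pipeline["P"].panel, rng=rng)
        sig = steppco_signal(g, pipeline["frame"])
        truth = chromosomes_to_signal(dip, n_bins=1024).values
        hom = np.abs(truth) == 1.0
        agree = np.sign(sig.values[hom]) == np.sign(truth[hom])
        assert agree.mean() >= 0.95

    def test_admixture_proportion_poles_and_midpoint(self, small_frame):
        sig = steppco_signal(np.zeros(400), small_frame)
        k = small_frame.n_bins
        sig.values[:] = -1.0
        assert admixture_proportion(sig) == 0.0
        sig.values[:] = 0.0
        assert admixture_proportion(sig) == 0.5

    def test_admixture_proportion_recovers_block_fraction(self, pipeline):
        # diploid with exactly 30% B ancestry
        dip = (BreakpointChromosome([0.3], start=1),
               BreakpointChromosome([0.3, 0.6], start=0))
        rng = np.random.default_rng(16)
        props = []
        for _ in range(10):
            g = genotypes_from_breakpoints(dip, pipeline["freqs"],
                                           pipeline["P"].panel, rng=rng)
            props.append(admixture_proportion(
                steppco_signal(g, pipeline["frame"])))
        assert np.mean(props) == pytest.approx(0.30, abs=0.03)

    def test_signal_shape_mismatch_rejected(self, small_frame):
        with pytest.raises(ValueError, match="panel"):
            steppco_signal(np.zeros(17), small_frame)

    def test_signals_for_matches_per_sample_loop(self, small_panels, small_frame):
        P, _, _ = small_panels
        sigs = signals_for(P, small_frame)
        assert len(sigs) == P.n_samples
        one = steppco_signal(P.calls[:, 3], small_frame, P.samples[3])
        np.testing.assert_allclose(sigs[3].values, one.values, equal_nan=True)
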