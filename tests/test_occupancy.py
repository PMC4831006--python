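"""Poisson occupancy statistics: estimators, intervals, deconvolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import chemodrop as cd
from chemodrop.occupancy import OccupancyCount, clopper_pearson, round_sig


class TestPoissonPmf:
    @pytest.mark.parametrize(
        "k, lam, expected",
        [
            (0, 0.0, 1.0),
            (0, 0.1, 0.9048),  # e^{-0.1}
            (1, 2.3026, 0.2303),  # lam*e^{-lam} at lam = -ln 0.1
        ],
    )
    def test_values(self, k, lam, expected):
        assert cd.poisson_pmf(k, lam) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("k, lam", [(-1, 1.0), (0.5, 1.0), (0, -0.1)])
    def test_domain_errors(self, k, lam):
        with pytest.raises(ValueError):
            cd.poisson_pmf(k, lam)

    @given(lam=st.floats(0.0, 20.0))
    @settings(max_examples=50, derandomize=True)
    def test_normalises_and_matches_closed_form(self, lam):
        ks = np.arange(0, 120)
        p = cd.poisson_pmf(ks, lam)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        # independent closed form lam^k e^-lam / k! at a few k
        for k in (0, 1, 3, 7):
            direct = lam**k * math.exp(-lam) / math.factorial(k)
            assert p[k] == pytest.approx(direct, rel=1e-12, abs=1e-300)


class TestEstimateLambda:
    def test_ninety_percent_occupied_prints_2_30(self):
        est = cd.estimate_lambda(OccupancyCount(n_total=100, n_growth=90))
        assert round(est.lambda_hat, 2) == 2.30

    def test_zero_occupied_gives_zero(self):
        est = cd.estimate_lambda(OccupancyCount(n_total=100, n_growth=0))
        assert est.lambda_hat == 0.0
        assert est.ci_low == 0.0

    def test_ci_matches_bruteforce_binomial_inversion(self):
        """95% interval for 15/1000 against direct inversion of the binomial CDF."""
        est = cd.estimate_lambda(OccupancyCount(n_total=1000, n_growth=15), conf=0.95)
        assert est.lambda_hat == pytest.approx(0.0151, abs=5e-5)

        def invert(target, k, n, upper):
            # bisect p so that the binomial tail probability hits alpha/2
            lo, hi = 0.0, 1.0
            for _ in range(80):
                mid = (lo + hi) / 2
                tail = (
                    1 - stats.binom.cdf(k - 1, n, mid) if upper else stats.binom.cdf(k, n, mid)
                )
                # upper bound: find largest p with P(X <= k) >= alpha/2 etc.
                if upper:
                    if tail < target:
                        lo = mid
                    else:
                        hi = mid
                else:
                    if tail > target:
                        lo = mid
                    else:
                        hi = mid
            return (lo + hi) / 2

        p_lo = invert(0.025, 15, 1000, upper=True)
        p_hi = invert(0.025, 15, 1000, upper=False)
        assert est.ci_low == pytest.approx(-math.log1p(-p_lo), rel=1e-4)
        assert est.ci_high == pytest.approx(-math.log1p(-p_hi), rel=1e-4)

    def test_roundtrip_identity(self):
        for n_occ, n in [(1, 7), (50, 100), (999, 1000)]:
            est = cd.estimate_lambda(OccupancyCount(n_total=n, n_growth=n_occ))
            assert 1 - math.exp(-est.lambda_hat) == pytest.approx(n_occ / n, abs=1e-12)

    @given(n=st.integers(2, 5000), frac=st.floats(0.001, 0.999))
    @settings(max_examples=60, derandomize=True)
    def test_roundtrip_identity_property(self, n, frac):
        n_occ = min(n - 1, max(0, int(frac * n)))
        est = cd.estimate_lambda(OccupancyCount(n_total=n, n_growth=n_occ))
        assert 1 - math.exp(-est.lambda_hat) == pytest.approx(n_occ / n, abs=1e-12)
        assert est.ci_low <= est.lambda_hat <= est.ci_high

    def test_saturation_raises(self):
        with pytest.raises(cd.SaturatedOccupancyError):
            cd.estimate_lambda(OccupancyCount(n_total=50, n_growth=50))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            OccupancyCount(n_total=10, n_growth=11)
        with pytest.raises(ValueError):
            OccupancyCount(n_total=10, n_growth=-1)

    def test_coverage_of_lambda_interval(self, rng):
        """Clopper-Pearson coverage stays within 2% of nominal across lambdas."""
        n, reps, conf = 100, 2000, 0.95
        for lam in (0.05, 0.5, 2.0):
            p = 1 - math.exp(-lam)
            ks = rng.binomial(n, p, size=reps)
            hits = 0
            for k in ks:
                if k == n:
                    continue  # saturated draws carry no interval
                est = cd.estimate_lambda(OccupancyCount(n_total=n, n_growth=int(k)), conf=conf)
                hits += est.ci_low <= lam <= est.ci_high
            assert hits / reps >= conf - 0.02


class TestSingleCellDesign:
    def test_lambda_0_1_gives_95_percent(self):
        assert round(100 * cd.single_cell_given_growth(0.1)) == 95

    def test_small_lambda_limit_is_one(self):
        assert cd.single_cell_given_growth(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_lambda_one(self):
        assert cd.single_cell_given_growth(1.0) == pytest.approx(0.5820, abs=5e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cd.single_cell_given_growth(0.0)

    @pytest.mark.parametrize("lam, expected", [(0.1, 0.9048), (0.0, 1.0), (2.3026, 0.1000)])
    def test_empty_fraction(self, lam, expected):
        assert cd.empty_fraction(lam) == pytest.approx(expected, abs=5e-5)

    def test_against_monte_carlo(self, rng):
        """Closed forms agree with 10^6 Poisson draws within 3 standard errors."""
        n = 10**6
        for lam in (0.1, 1.0):
            draws = rng.poisson(lam, n)
            p_empty = (draws == 0).mean()
            se_empty = math.sqrt(p_empty * (1 - p_empty) / n)
            assert abs(cd.empty_fraction(lam) - p_empty) < 3 * se_empty
            occupied = draws[draws > 0]
            p_single = (occupied == 1).mean()
            se_single = math.sqrt(p_single * (1 - p_single) / len(occupied))
            assert abs(cd.single_cell_given_growth(lam) - p_single) < 3 * se_single


class TestDeconvolution:
    def test_mixture_baseline_fractions(self):
        counts = OccupancyCount(n_total=1000, n_growth=116, n_fluor=80, n_growth_nonfluor=36)
        ref, nl = cd.deconvolve_dual_label(counts)
        assert 0.083 <= ref.lambda_hat <= 0.084
        assert round_sig(nl.lambda_hat, 2) == 0.040

    def test_no_reference_means_target_is_total(self):
        counts = OccupancyCount(n_total=1000, n_growth=100, n_fluor=0, n_growth_nonfluor=100)
        ref, nl = cd.deconvolve_dual_label(counts)
        assert ref.lambda_hat == 0.0
        total = cd.estimate_lambda(OccupancyCount(n_total=1000, n_growth=100))
        assert nl.lambda_hat == pytest.approx(total.lambda_hat, abs=1e-12)

    def test_large_tally_closed_form(self):
        counts = OccupancyCount(
            n_total=10000, n_growth=2710, n_fluor=170, n_growth_nonfluor=2540
        )
        _, nl = cd.deconvolve_dual_label(counts)
        assert nl.lambda_hat == pytest.approx(0.299, abs=5e-4)

    def test_all_growth_fluorescent_gives_zero_target(self):
        # union equals the fluorescent tally: nothing left for the target species
        counts = OccupancyCount(n_total=100, n_growth=30, n_fluor=30, n_growth_nonfluor=0)
        ref, nl = cd.deconvolve_dual_label(counts)
        assert ref.lambda_hat > 0
        assert nl.lambda_hat == 0.0

    def test_recovery_from_simulated_dual_loading(self, rng):
        """Independent two-species Poisson loading is recovered by deconvolution."""
        lam_ref, lam_nl, n = 0.084, 0.040, 10000
        ref_counts = rng.poisson(lam_ref, n)
        nl_counts = rng.poisson(lam_nl, n)
        tally = OccupancyCount(
            n_total=n,
            n_growth=int(((ref_counts > 0) | (nl_counts > 0)).sum()),
            n_fluor=int((ref_counts > 0).sum()),
            n_growth_nonfluor=int(((ref_counts == 0) & (nl_counts > 0)).sum()),
        )
        ref, nl = cd.deconvolve_dual_label(tally)
        assert abs(ref.lambda_hat - lam_ref) < 3 * ref.ci_half_width
        assert abs(nl.lambda_hat - lam_nl) < 3 * nl.ci_half_width

    def test_requires_dual_tallies(self):
        with pytest.raises(ValueError):
            cd.deconvolve_dual_label(OccupancyCount(n_total=100, n_growth=10))


class TestEnrichment:
    def test_mixture_numbers(self):
        res = cd.enrichment_factor(before=(0.040, 0.084), after=(0.298, 0.017))
        assert res.ratio_before == pytest.approx(0.48, abs=0.005)
        assert 17.5 <= res.ratio_after <= 17.8
        assert 36.0 <= res.enrichment_factor <= 37.0

    def test_no_change_gives_unity(self):
        res = cd.enrichment_factor(before=(0.1, 0.2), after=(0.1, 0.2))
        assert res.enrichment_factor == pytest.approx(1.0)

    def test_arithmetic(self):
        res = cd.enrichment_factor(before=(0.1, 0.1), after=(0.2, 0.05))
        assert res.enrichment_factor == pytest.approx(4.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            cd.enrichment_factor(before=(0.1, 0.0), after=(0.2, 0.1))


class TestDensityConversions:
    @pytest.mark.parametrize(
        "density, volume, expected",
        [(0.6e6, 13, 7.8), (0, 5.5, 0.0), (0.6e3, 13, 0.0078)],
    )
    def test_lambda_from_density(self, density, volume, expected):
        assert cd.lambda_from_density(density, volume) == pytest.approx(expected, rel=1e-9)

    def test_occupancy_curve_monotone_with_limits(self):
        dens = [0.0, 0.6e3, 0.6e4, 0.6e5, 0.6e6, 1e8]
        curve = cd.expected_occupancy_curve(dens, 13.0)
        assert curve[0] == 0.0
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] == pytest.approx(1.0, abs=1e-6)
        # composition of the two primitives
        assert curve[1] == pytest.approx(1 - math.exp(-cd.lambda_from_density(0.6e3, 13.0)))


def test_clopper_pearson_edge_cases():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0 and 0 < hi < 1
    lo, hi = clopper_pearson(10, 10)
    assert hi == 1.0 and 0 < lo < 1
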