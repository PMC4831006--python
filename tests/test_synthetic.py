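"""Synthetic device generators: encapsulation, traces, chemotactic sorting."""

import math

import numpy as np
import pytest
from scipy import stats

import chemodrop as cd
from chemodrop.synth import TraceParams
from chemodrop.traces import Trace


SP = cd.SpeciesParams(name="target")
SP_LAB = cd.SpeciesParams(name="ref", labelled=True)


def density_for_lambda(lam: float, volume_nl: float) -> float:
    return lam / (volume_nl * 1e-6)


class TestEncapsulate:
    def test_zero_density_all_empty(self):
        drops = cd.encapsulate([SP], [0.0], 13.0, 500, seed=1)
        assert all(not d.growth and d.founders == (0,) for d in drops)

    def test_occupied_fraction_matches_poisson(self):
        lam, n = 0.1, 100_000
        drops = cd.encapsulate([SP], [density_for_lambda(lam, 13.0)], 13.0, n, seed=2)
        f = cd.tally_droplets(drops).n_growth / n
        p = 1 - math.exp(-lam)
        assert abs(f - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_dual_species_class_fractions(self):
        """Empty / ref-only / target-only / both match product-Poisson predictions."""
        lam_t, lam_r, n = 0.040, 0.084, 100_000
        drops = cd.encapsulate(
            [SP, SP_LAB],
            [density_for_lambda(lam_t, 5.5), density_for_lambda(lam_r, 5.5)],
            5.5,
            n,
            seed=3,
        )
        both = sum(d.founders[0] > 0 and d.founders[1] > 0 for d in drops) / n
        ref_only = sum(d.founders[0] == 0 and d.founders[1] > 0 for d in drops) / n
        t_only = sum(d.founders[0] > 0 and d.founders[1] == 0 for d in drops) / n
        empty = sum(d.founders == (0, 0) for d in drops) / n
        pt, pr = 1 - math.exp(-lam_t), 1 - math.exp(-lam_r)
        for obs, exp in [
            (both, pt * pr),
            (ref_only, (1 - pt) * pr),
            (t_only, pt * (1 - pr)),
            (empty, (1 - pt) * (1 - pr)),
        ]:
            assert abs(obs - exp) < 3 * math.sqrt(exp * (1 - exp) / n)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0])
    def test_founder_counts_fit_poisson_pmf(self, lam):
        """Chi-square goodness-of-fit of founder counts is not rejected at 1%."""
        n = 100_000
        drops = cd.encapsulate([SP], [density_for_lambda(lam, 13.0)], 13.0, n, seed=int(lam * 10))
        counts = np.bincount([d.founders[0] for d in drops])
        expected = n * cd.poisson_pmf(np.arange(len(counts)), lam)
        expected[-1] = n - expected[:-1].sum()  # fold the tail into the last bin
        # merge bins until every expected count is >= 5
        obs, exp = [], []
        o_acc = e_acc = 0.0
        for o, e in zip(counts, expected):
            o_acc += o
            e_acc += e
            if e_acc >= 5:
                obs.append(o_acc)
                exp.append(e_acc)
                o_acc = e_acc = 0.0
        obs[-1] += o_acc
        exp[-1] += e_acc
        stat, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_growth_thinning(self):
        """Viability thinning makes growth occupancy Poisson with mean lam*p."""
        lam, p_grow, n = 1.0, 0.5, 100_000
        sp = cd.SpeciesParams(name="frail", growth_probability=p_grow)
        drops = cd.encapsulate([sp], [density_for_lambda(lam, 13.0)], 13.0, n, seed=7)
        f = cd.tally_droplets(drops).n_growth / n
        p = 1 - math.exp(-lam * p_grow)
        assert abs(f - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_fluorescence_requires_labelled_founder(self):
        drops = cd.encapsulate(
            [SP, SP_LAB],
            [density_for_lambda(0.5, 13.0), density_for_lambda(0.5, 13.0)],
            13.0,
            5000,
            seed=4,
        )
        assert all(d.fluorescent == (d.founders[1] > 0) for d in drops)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            cd.encapsulate([SP], [1e5], 0.0, 10, seed=0)
        with pytest.raises(ValueError):
            cd.encapsulate([SP], [1e5], 13.0, 0, seed=0)
        with pytest.raises(ValueError):
            cd.encapsulate([SP], [-1.0], 13.0, 10, seed=0)


class TestSynthTrace:
    def test_zero_droplets_gives_flat_baseline(self):
        st = cd.synth_trace([], TraceParams(noise_sd=0.0, duration_cv=0.0), seed=0)
        assert np.all(st.bright == 1.0)
        assert st.truth == []

    def test_noiseless_single_droplet_template(self):
        p = TraceParams(noise_sd=0.0, duration_cv=0.0)
        drop = cd.DropletRecord(0, 13.0, (0,), growth=False, fluorescent=False)
        st = cd.synth_trace([drop], p, seed=0)
        t = st.truth[0]
        # plateau exactly at the empty level strictly inside the two peaks
        interior = st.bright[t.front_peak_idx + 20 : t.back_peak_idx - 20]
        assert np.all(interior == p.empty_plateau_level)
        # apexes exactly on the boundary samples, at oil + peak amplitude
        for peak in (t.front_peak_idx, t.back_peak_idx):
            assert st.bright[peak] == pytest.approx(p.oil_level + p.boundary_peak_amplitude)
        # oil exactly outside the droplet, away from the peak tails
        assert np.all(st.bright[: t.front_peak_idx - 20] == p.oil_level)

    def test_growth_plateau_is_darker(self):
        p = TraceParams(noise_sd=0.0, duration_cv=0.0)
        drops = [
            cd.DropletRecord(0, 13.0, (1,), growth=True, fluorescent=False),
            cd.DropletRecord(1, 13.0, (0,), growth=False, fluorescent=False),
        ]
        st = cd.synth_trace(drops, p, seed=0)
        g, e = st.truth
        assert st.bright[(g.front_peak_idx + g.back_peak_idx) // 2] < st.bright[
            (e.front_peak_idx + e.back_peak_idx) // 2
        ]

    def test_bookkeeping_matches_droplet_count(self):
        drops = cd.encapsulate([SP], [density_for_lambda(0.77, 13.0)], 13.0, 100, seed=5)
        st = cd.synth_trace(drops, seed=6)
        assert len(st.truth) == 100
        assert [t.growth for t in st.truth] == [d.growth for d in drops]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TraceParams(growth_plateau_level=0.9)  # above the empty plateau
        with pytest.raises(ValueError):
            TraceParams(noise_sd=0.3)  # beyond half the plateau separation


class TestDeterminism:
    def test_same_seed_bit_identical(self, solved_gradient):
        a = cd.encapsulate([SP, SP_LAB], [1e5, 2e5], 13.0, 200, seed=11)
        b = cd.encapsulate([SP, SP_LAB], [1e5, 2e5], 13.0, 200, seed=11)
        assert a == b
        sa = cd.synth_trace(a, seed=12)
        sb = cd.synth_trace(b, seed=12)
        assert np.array_equal(sa.bright, sb.bright) and np.array_equal(sa.fluor, sb.fluor)
        sp = [cd.SpeciesParams(name="s", chemotactic_sensitivity=1.0)]
        ra = cd.simulate_sorting(solved_gradient, sp, 500, seed=13)
        rb = cd.simulate_sorting(solved_gradient, sp, 500, seed=13)
        assert ra == rb


class TestSorting:
    def test_passive_uniform_release_follows_flow_split(self, zero_gradient):
        """Without chemotaxis, routing is passive partitioning at the splitter."""
        sp = cd.SpeciesParams(name="passive", chemotactic_sensitivity=0.0)
        n = 5000
        res = cd.simulate_sorting(zero_gradient, [sp], n, seed=21, release="uniform")
        f_expected = 1 - zero_gradient.flow.waste_fraction
        se = math.sqrt(f_expected * (1 - f_expected) / n)
        assert abs(res["passive"].fraction - f_expected) < 3 * se

    def test_sensitive_species_collected_more(self, solved_gradient):
        species = [
            cd.SpeciesParams(name="sens", chemotactic_sensitivity=1.0),
            cd.SpeciesParams(name="insens", chemotactic_sensitivity=0.0),
        ]
        n = 5000
        res = cd.simulate_sorting(solved_gradient, species, n, seed=22)
        f1, f0 = res["sens"].fraction, res["insens"].fraction
        # one-sided two-proportion comparison at 3 sigma
        pbar = (f1 + f0) / 2
        se = math.sqrt(2 * pbar * (1 - pbar) / n)
        assert f1 - f0 > 3 * se

    def test_zero_gradient_control_indistinguishable(self, zero_gradient):
        species = [
            cd.SpeciesParams(name="sens", chemotactic_sensitivity=1.0),
            cd.SpeciesParams(name="insens", chemotactic_sensitivity=0.0),
        ]
        n = 5000
        res = cd.simulate_sorting(zero_gradient, species, n, seed=23)
        f1, f0 = res["sens"].fraction, res["insens"].fraction
        pbar = (f1 + f0) / 2
        se = math.sqrt(2 * pbar * (1 - pbar) / n)
        assert abs(f1 - f0) < 3 * se

    def test_bad_inputs(self, solved_gradient):
        with pytest.raises(ValueError):
            cd.simulate_sorting(solved_gradient, [SP], 0, seed=0)
        with pytest.raises(ValueError):
            cd.simulate_sorting(solved_gradient, [SP], 10, seed=0, release="sideways")
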