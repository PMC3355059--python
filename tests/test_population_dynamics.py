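"""Population profiles, cross-correlation synchrony, gradient regressions."""

import math

import numpy as np
import pandas as pd
import pytest

from colliculus import (
    CellDensity,
    SaccadeVector,
    SpikeTrain,
    afferent_map,
    cross_correlate,
    gradient_regressions,
    population_profile,
    spike_density,
    weighted_trial_average,
)
from colliculus.bursts import DensityFunction


GRID = np.arange(-100.0, 201.0)


def density_of(spikes, sigma=5.0):
    return spike_density(SpikeTrain(spikes), sigma, GRID)


def trial(vec, spikes, onset=0.0):
    return (vec, SpikeTrain(spikes), onset)


class TestWeightedTrialAverage:
    def test_single_matching_trial_passthrough(self):
        target = SaccadeVector(10.0, 0.0)
        out = weighted_trial_average([trial(target, [5.0, 12.0])], target, t_grid=GRID)
        assert np.allclose(out.values, density_of([5.0, 12.0]).values)

    def test_equal_distances_average_equally(self):
        target = SaccadeVector(10.0, 0.0)
        a = SaccadeVector(11.0, 0.0)
        b = SaccadeVector(9.1, 0.0)  # roughly mirrored in u around the target
        out = weighted_trial_average([trial(a, [0.0]), trial(b, [40.0])], target,
                                     t_grid=GRID)
        ratio = (out.values[GRID == 0.0] / out.values[GRID == 40.0]).item()
        # weights are within a few percent of equal, not exactly equal
        assert 0.8 < ratio < 1.25

    def test_far_trials_excluded(self):
        target = SaccadeVector(10.0, 0.0)
        near = SaccadeVector(10.5, 0.0)
        far = SaccadeVector(25.0, 0.0)
        out = weighted_trial_average([trial(near, [0.0]), trial(far, [40.0])], target,
                                     t_grid=GRID)
        assert out.values[GRID == 40.0] < 1e-6
        assert out.values[GRID == 0.0] > 70.0

    def test_no_matching_trials_flagged(self):
        target = SaccadeVector(10.0, 0.0)
        out = weighted_trial_average([trial(SaccadeVector(30.0, 0.0), [0.0])], target,
                                     t_grid=GRID)
        assert out is None


class TestPopulationProfile:
    def test_single_cell_at_node(self):
        target = SaccadeVector(10.0, 0.0)
        u_c = afferent_map(target).u
        dens = density_of([0.0, 5.0])
        prof = population_profile([CellDensity(u_c, dens, 10.0, 18.0)], target)
        node = prof.at(u_c)
        assert np.allclose(node.values, dens.values)

    def test_two_equidistant_cells_average(self):
        target = SaccadeVector(10.0, 0.0)
        u_c = afferent_map(target).u
        f = density_of([0.0])
        g = density_of([30.0])
        prof = population_profile(
            [CellDensity(u_c - 0.2, f, 10.0, 18.0), CellDensity(u_c + 0.2, g, 10.0, 18.0)],
            target,
        )
        assert np.allclose(prof.at(u_c).values, (f.values + g.values) / 2.0)

    def test_gaussian_weight_at_quarter_mm(self):
        target = SaccadeVector(10.0, 0.0)
        u_c = afferent_map(target).u
        f = density_of([0.0])
        g = density_of([30.0])
        prof = population_profile(
            [CellDensity(u_c, f, 10.0, 18.0), CellDensity(u_c + 0.25, g, 10.0, 18.0)],
            target,
        )
        w = math.exp(-0.5)
        expected = (f.values + w * g.values) / (1 + w)
        assert np.allclose(prof.at(u_c).values, expected)

    def test_weak_and_distant_cells_dropped(self):
        target = SaccadeVector(10.0, 0.0)
        u_c = afferent_map(target).u
        weak = CellDensity(u_c, density_of([0.0]), 0.5, 18.0)   # below 5% of peak
        far = CellDensity(u_c + 2.0, density_of([0.0]), 10.0, 18.0)  # beyond 1.25 mm
        prof = population_profile([weak, far], target)
        assert prof.empty_nodes.all()

    def test_scale_conservation(self):
        target = SaccadeVector(10.0, 0.0)
        u_c = afferent_map(target).u
        f = density_of([0.0, 10.0])
        cells = [CellDensity(u_c + du, f, 10.0, 18.0) for du in (-0.3, 0.0, 0.4)]
        prof1 = population_profile(cells, target)
        scaled = [
            CellDensity(c.u_c, DensityFunction(f.t_grid, 3.0 * f.values, 5.0), 10.0, 18.0)
            for c in cells
        ]
        prof3 = population_profile(scaled, target)
        assert np.allclose(prof3.activity, 3.0 * prof1.activity)


class TestCrossCorrelate:
    def test_autocorrelation_is_one_at_zero_lag(self):
        f = density_of([0.0, 4.0, 9.0])
        xc = cross_correlate(f, f, (-20.0, 60.0))
        assert xc.r0 == pytest.approx(1.0, abs=1e-12)
        assert xc.optimal_delay == 0.0

    def test_shifted_copy_recovers_the_shift(self):
        f = density_of([0.0, 4.0, 9.0])
        g = density_of([10.0, 14.0, 19.0])  # same burst 10 ms later
        xc = cross_correlate(f, g, (-20.0, 60.0))
        assert xc.optimal_delay == 10.0
        assert xc.r_opt == pytest.approx(1.0, abs=1e-6)

    def test_scaled_copy_keeps_unit_correlation(self):
        f = density_of([0.0, 4.0, 9.0])
        half = DensityFunction(f.t_grid, 0.5 * f.values, 5.0)
        xc = cross_correlate(f, half, (-20.0, 60.0))
        assert xc.r0 == pytest.approx(1.0, abs=1e-12)

    def test_swap_symmetry(self):
        f = density_of([0.0, 4.0])
        g = density_of([7.0, 20.0])
        a = cross_correlate(f, g, (-30.0, 60.0), max_lag=30)
        b = cross_correlate(g, f, (-30.0, 60.0), max_lag=30)
        assert a.optimal_delay == pytest.approx(-b.optimal_delay, abs=1.0)

    def test_delay_invariant_to_kernel_width(self):
        for sigma in (2.0, 5.0, 10.0):
            f = density_of([0.0, 5.0, 11.0], sigma)
            g = density_of([8.0, 13.0, 19.0], sigma)
            xc = cross_correlate(f, g, (-20.0, 60.0))
            assert xc.optimal_delay == 8.0

    def test_zero_energy_profile_flagged(self):
        f = density_of([0.0])
        zero = DensityFunction(f.t_grid, np.zeros_like(f.values), 5.0)
        with pytest.raises(ValueError):
            cross_correlate(f, zero, (-20.0, 60.0))


class TestGradientRegressions:
    def test_noise_free_linear_relation_recovered_exactly(self):
        r = np.linspace(3.0, 33.0, 20)
        table = pd.DataFrame({"R_pref": r, "gamma1": 0.01 * r - 0.09})
        out = gradient_regressions(table)
        assert out.loc["gamma1", "slope"] == pytest.approx(0.01, abs=1e-12)
        assert out.loc["gamma1", "intercept"] == pytest.approx(-0.09, abs=1e-12)
        assert out.loc["gamma1", "r"] == pytest.approx(1.0)

    def test_identical_values_flagged_not_fitted(self):
        table = pd.DataFrame({"R_pref": np.linspace(3, 33, 12), "N_s": 18.0})
        out = gradient_regressions(table)
        assert out.loc["N_s", "slope"] == 0.0
        assert math.isnan(out.loc["N_s", "r"])
        assert out.loc["N_s", "stars"] == "n.s."

    def test_few_cells_warns(self):
        table = pd.DataFrame({"R_pref": [5.0, 6.0, 7.0], "N_s": [17.0, 18.0, 19.0]})
        with pytest.warns(UserWarning):
            gradient_regressions(table)

    def test_missing_rpref_rejected(self):
        with pytest.raises(ValueError):
            gradient_regressions(pd.DataFrame({"N_s": [1.0, 2.0]}))
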