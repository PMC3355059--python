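"""Synthetic population generator: placement, trials, datasets."""

import numpy as np
import pytest

from colliculus import (
    SaccadeVector,
    SyntheticConfig,
    afferent_map,
    burst_window,
    cross_correlate,
    generate_dataset,
    make_map_population,
    rose_scan_targets,
    simulate_trial,
    spike_density,
)
from colliculus.synthetic_data import burst_duration, burst_template, gamma_shape


class TestPopulation:
    def test_count_and_peak_spikes(self):
        cfg = SyntheticConfig(n_cells=100, seed=0)
        pop = make_map_population(cfg)
        assert len(pop) == 100
        assert all(c.field.N_pref == 18.0 for c in pop)

    def test_same_seed_reproduces_population(self):
        cfg = SyntheticConfig(n_cells=50, seed=7)
        a = make_map_population(cfg)
        b = make_map_population(cfg)
        assert all(x.site == y.site for x, y in zip(a, b))

    def test_preferred_amplitude_monotone_in_u(self):
        from scipy.stats import spearmanr

        pop = make_map_population(SyntheticConfig(n_cells=64, seed=1))
        # preferred amplitude grows along the rostral-caudal axis; the
        # medial-lateral coordinate adds only mild scatter
        rho = spearmanr([c.site.u for c in pop], [c.pref_vec.R for c in pop]).statistic
        assert rho > 0.9
        # strictly monotone along the meridian itself
        from colliculus import MapPoint, efferent_map

        line = [efferent_map(MapPoint(u, 0.0)).R for u in np.linspace(0.1, 3.9, 20)]
        assert np.all(np.diff(line) > 0)


class TestTemplate:
    def test_duration_model(self):
        cfg = SyntheticConfig()
        assert burst_duration(10.0, cfg) == pytest.approx(38.0)

    def test_shape_anchors_and_monotonicity(self):
        cfg = SyntheticConfig()
        assert gamma_shape(5.0, cfg) == pytest.approx(8.0)
        assert gamma_shape(30.0, cfg) == pytest.approx(3.0)
        ks = [gamma_shape(r, cfg) for r in np.linspace(3, 35, 20)]
        assert np.all(np.diff(ks) < 0)

    def test_template_is_a_distribution_peaked_at_Tp(self):
        cfg = SyntheticConfig()
        for R in (5.0, 15.0, 30.0):
            bins, probs = burst_template(R, cfg, onset=70.0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= 0.0)
            assert bins[np.argmax(probs)] == pytest.approx(70.0 + cfg.T_p, abs=1.0)
            # support confined to the count window [onset-20, onset-20+D)
            assert bins[0] == 50.0 and len(bins) == round(burst_duration(R, cfg))


class TestSimulateTrial:
    def test_same_seed_identical_spikes_and_trace(self, small_population):
        cfg, pop = small_population
        a = simulate_trial(SaccadeVector(12, 0), pop, cfg, rng=99)
        b = simulate_trial(SaccadeVector(12, 0), pop, cfg, rng=99)
        assert a.trial == b.trial
        assert all(
            np.array_equal(a.trains[c.cell_id].spike_times, b.trains[c.cell_id].spike_times)
            for c in pop
        )

    def test_mean_count_at_center_cell(self, small_population):
        """The cell at the population center fires on average about
        N0 (+ the additive Poisson mean) spikes for its preferred saccade."""
        cfg, pop = small_population
        rng = np.random.default_rng(5)
        cell = min(pop, key=lambda c: abs(c.site.u - 2.0) + abs(c.site.v))
        counts = []
        for _ in range(300):
            res = simulate_trial(cell.pref_vec, pop, cfg, rng=rng, jitter_target=False)
            if res.trial is None:
                continue
            w = burst_window(res.trial.onset, res.trial.offset)
            counts.append(res.trains[cell.cell_id].in_window(*w).size)
        mean = np.mean(counts)
        expected = cfg.N0 + cfg.additive_rate
        mc_se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * mc_se + 0.2  # rounding bias allowance
        assert np.std(counts) / mean == pytest.approx(cfg.cv, abs=0.05)

    def test_recruited_cells_share_synchronized_scaled_bursts(self, small_population):
        cfg, pop = small_population
        rng = np.random.default_rng(8)
        target = SaccadeVector(14.0, 0.0)
        center = afferent_map(target)
        # two recruited cells at different u
        cells = sorted(pop, key=lambda c: (c.site.u - center.u) ** 2 + c.site.v**2)[:6]
        grid = np.arange(0.0, 251.0)
        acc = {c.cell_id: np.zeros_like(grid) for c in cells}
        for _ in range(40):
            res = simulate_trial(target, pop, cfg, rng=rng, jitter_target=False)
            for c in cells:
                acc[c.cell_id] += spike_density(res.trains[c.cell_id], 5.0, grid).values
        from colliculus.bursts import DensityFunction

        dens = {
            cid: DensityFunction(grid, v / 40.0, 5.0) for cid, v in acc.items()
        }
        ids = [c.cell_id for c in cells]
        for other in ids[1:]:
            xc = cross_correlate(dens[ids[0]], dens[other], (30.0, 150.0))
            assert xc.r0 > 0.95
            assert abs(xc.optimal_delay) <= 2.0

    def test_unreachable_target_flagged(self, small_population):
        cfg, pop = small_population
        # silence everything: target far outside every cell's reach
        res = simulate_trial(SaccadeVector(0.1, 0.0), pop[-3:], cfg, rng=1,
                             jitter_target=False)
        assert res.trial is None


class TestGenerateDataset:
    def test_trial_count_per_cell_and_validity(self):
        cfg = SyntheticConfig(n_cells=1, u_range=(1.8, 2.2), v_range=(-0.2, 0.2), seed=4)
        targets = rose_scan_targets(amplitudes=(5, 9, 14), directions=(0, 30, -30))
        ds = generate_dataset(cfg, targets=targets, n_reps=5, seed=4)
        ds.validate()
        n_expected = 5 * len(targets) - ds.manifest["n_flagged_trials"]
        assert len(ds.trials) == n_expected

    def test_regeneration_is_byte_identical(self):
        cfg = SyntheticConfig(n_cells=2, u_range=(1.5, 2.5), v_range=(-0.3, 0.3), seed=9)
        a = generate_dataset(cfg, n_reps=1, seed=9)
        b = generate_dataset(cfg, n_reps=1, seed=9)
        assert a.trials.equals(b.trials)
        assert a.spikes.equals(b.spikes)
        assert a.cells.equals(b.cells)

    def test_manifest_records_conditions(self, small_dataset):
        cfg, ds = small_dataset
        m = ds.manifest
        assert m["generator"]["N0"] == cfg.N0
        assert m["generator"]["cv"] == cfg.cv
        assert m["seed"] == 5
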