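import io
import math

import numpy as np
import pytest
from scipy.stats import binom

from bsahmm.simulate import (
    SimulationConfig,
    cm_per_kb_to_rate,
    draw_marker_map,
    select_pool,
    sequence_pool,
    simulate_dataset,
    simulate_segregant,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_markers": 1},
            {"n_markers": 10**7},
            {"psc": 0.0},
            {"psc": 1.5},
            {"seq_error": 0.5},
            {"coverage_mode": "exact"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_cm_per_kb_conversion(self):
        assert cm_per_kb_to_rate(0.37) == pytest.approx(3.7e-6)


class TestMarkerMap:
    def test_saturated_map_is_every_position(self, rng):
        positions, ci = draw_marker_map(50, 50, rng)
        assert list(positions) == list(range(1, 51))
        assert 0 <= ci < 50

    def test_same_seed_same_map(self):
        p1, c1 = draw_marker_map(750_000, 2500, np.random.default_rng(5))
        p2, c2 = draw_marker_map(750_000, 2500, np.random.default_rng(5))
        np.testing.assert_array_equal(p1, p2)
        assert c1 == c2

    def test_causal_index_roughly_uniform(self, rng):
        # chi-square sanity over 10 bins of the causal index
        n_draws, n_markers = 10_000, 2500
        idx = np.array(
            [draw_marker_map(750_000, n_markers, rng)[1] for _ in range(n_draws)]
        )
        counts, _ = np.histogram(idx, bins=10, range=(0, n_markers))
        chi2 = ((counts - n_draws / 10) ** 2 / (n_draws / 10)).sum()
        assert chi2 < 27.88  # chi2(9) at p=0.001


class TestSegregant:
    def test_no_crossover_single_parent_block(self, rng):
        positions = np.array([1, 1000, 500_000])
        starts = [
            simulate_segregant(positions, 750_000, 0.0, rng)[0] for _ in range(500)
        ]
        for _ in range(20):
            seg = simulate_segregant(positions, 750_000, 0.0, rng)
            assert len(set(seg.tolist())) == 1
        assert 0.4 < np.mean(starts) < 0.6

    def test_mean_breakpoint_count_matches_poisson(self, rng):
        # discordance across the whole chromosome determines breakpoint parity;
        # count breakpoints directly through the origin changes at a dense map
        lam = 3.7e-6 * 750_000  # = 2.775
        positions = np.arange(1, 750_001, 500)
        n_reps = 4000
        switches = np.empty(n_reps)
        for i in range(n_reps):
            seg = simulate_segregant(positions, 750_000, 0.37, rng)
            switches[i] = np.sum(seg[1:] != seg[:-1])
        # observed switch count undercounts breakpoints (pairs within 500 bp
        # cancel), so compare against the parity-corrected expectation
        gap = 500
        p_odd = (1 - math.exp(-2 * 3.7e-6 * gap)) / 2
        expected = p_odd * (len(positions) - 1)
        se = math.sqrt(expected / n_reps) * 3  # generous 3-sigma band
        assert abs(switches.mean() - expected) < max(3 * switches.std() / math.sqrt(n_reps), se)
        assert abs(switches.mean() - lam) / lam < 0.05  # cancellation is tiny here

    @pytest.mark.parametrize("gap", [1_000, 20_000, 100_000])
    def test_discordance_matches_odd_crossover_formula(self, rng, gap):
        rho = 3.7e-6
        positions = np.array([1, 1 + gap])
        n_reps = 6000
        disc = np.empty(n_reps, dtype=bool)
        for i in range(n_reps):
            seg = simulate_segregant(positions, 750_000, 0.37, rng)
            disc[i] = seg[0] != seg[1]
        expected = (1 - math.exp(-2 * rho * gap)) / 2
        se = math.sqrt(expected * (1 - expected) / n_reps)
        assert abs(disc.mean() - expected) < 4 * se


class TestPoolSelection:
    def test_psc_one_gives_all_carriers(self, rng):
        cfg = SimulationConfig(n_segregants=50, psc=1.0, n_markers=100)
        positions, ci = draw_marker_map(cfg.chrom_length, cfg.n_markers, rng)
        origins, carrier = select_pool(cfg, positions, ci, rng)
        assert carrier.all()
        assert origins[:, ci].all()

    @pytest.mark.parametrize("psc", [0.5, 0.85])
    def test_carrier_fraction_within_binomial_ci(self, rng, psc):
        # acceptance with prior 1/2 makes E[pool carrier fraction] = PSC
        cfg = SimulationConfig(n_segregants=1000, psc=psc, n_markers=100)
        positions, ci = draw_marker_map(cfg.chrom_length, cfg.n_markers, rng)
        _, carrier = select_pool(cfg, positions, ci, rng)
        lo, hi = binom.ppf([0.005, 0.995], 1000, psc)
        assert lo <= carrier.sum() <= hi


class TestSequencing:
    def test_error_free_all_carrier_pool_saturates_causal_marker(self, rng):
        origins = np.ones((30, 10), dtype=bool)
        positions = np.arange(1, 11) * 1000
        track = sequence_pool(origins, 100, 0.0, "fixed", rng, positions)
        assert (track.superior == track.total).all()

    def test_fixed_mode_constant_totals(self, rng):
        origins = rng.random((30, 50)) < 0.5
        track = sequence_pool(origins, 77, 0.01, "fixed", rng, np.arange(1, 51) * 10)
        assert (track.total == 77).all()

    def test_expected_superior_fraction(self, rng):
        # f(1-e) + (1-f)e with f the pool superior fraction at the marker
        f, eps, c, n_markers = 0.7, 0.05, 200, 4000
        origins = np.zeros((10, n_markers), dtype=bool)
        origins[:7, :] = True
        track = sequence_pool(origins, c, eps, "fixed", rng, np.arange(1, n_markers + 1))
        expected = f * (1 - eps) + (1 - f) * eps
        mean_frac = (track.superior / track.total).mean()
        se = math.sqrt(expected * (1 - expected) / (c * n_markers))
        assert abs(mean_frac - expected) < 4 * se


class TestDataset:
    def test_same_seed_byte_identical_tsv(self):
        cfg = SimulationConfig(n_markers=200, seed=42)
        bufs = []
        for _ in range(2):
            pool = simulate_dataset(cfg)
            buf = io.StringIO()
            pool.write_counts(buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_causal_marker_frequency_near_psc(self):
        psc, eps = 0.95, 0.01
        fracs = []
        for seed in range(40):
            pool = simulate_dataset(
                SimulationConfig(n_markers=200, psc=psc, seed=seed, coverage=200)
            )
            s = pool.counts.sites[pool.causal_index]
            fracs.append(s.superior_count / s.total_count)
        expected = psc * (1 - eps) + (1 - psc) * eps
        assert np.mean(fracs) == pytest.approx(expected, abs=0.03)

    def test_linkage_decays_far_from_causal_site(self):
        # markers >= 300 kbp away are nearly unlinked: frequency ~ 0.5
        far_fracs = []
        for seed in range(40):
            pool = simulate_dataset(SimulationConfig(n_markers=500, psc=0.95, seed=seed))
            dist = np.abs(pool.positions - pool.causal_pos)
            far = dist >= 300_000
            if far.any():
                far_fracs.append(
                    float((pool.counts.superior[far] / pool.counts.total[far]).mean())
                )
        assert np.mean(far_fracs) == pytest.approx(0.5, abs=0.05)

    def test_frequency_gradient_peaks_at_causal_site(self):
        # mean superior frequency decays with distance from the causal marker
        bins = np.array([0, 25_000, 100_000, 300_000, 750_000])
        sums = np.zeros(len(bins) - 1)
        counts = np.zeros(len(bins) - 1)
        for seed in range(30):
            pool = simulate_dataset(SimulationConfig(n_markers=500, psc=0.95, seed=seed))
            dist = np.abs(pool.positions - pool.causal_pos)
            frac = pool.counts.superior / pool.counts.total
            which = np.digitize(dist, bins) - 1
            for b in range(len(bins) - 1):
                sel = which == b
                sums[b] += frac[sel].sum()
                counts[b] += sel.sum()
        means = sums / counts
        assert np.all(np.diff(means) < 0.02)  # non-increasing within noise
        assert means[0] > means[-1] + 0.2
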