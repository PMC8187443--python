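"""Simulator unit and property tests: genome fields, origin placement,
population kinetics, fibers and the density gradient."""

import numpy as np
import pytest
from scipy import stats

from rerepkit import simcore
from rerepkit.errors import EmptyInputError, InvalidConfigError


class TestBuildGenome:
    def test_length_and_range(self, genome):
        assert genome.length == 10_000_000
        assert genome.timing.min() >= 0.0 and genome.timing.max() <= 1.0

    def test_deterministic_for_seed(self):
        a = simcore.build_genome(500, 1000, seed=9)
        b = simcore.build_genome(500, 1000, seed=9)
        np.testing.assert_array_equal(a.timing, b.timing)
        np.testing.assert_array_equal(a.euchromatin, b.euchromatin)

    def test_full_coupling_anticorrelates_euchromatin_with_timing(self):
        g = simcore.build_genome(1000, 10_000, coupling=1.0, seed=5)
        rho = stats.spearmanr(g.timing, g.euchromatin).statistic
        assert rho < -0.8

    def test_zero_coupling_decouples_tracks(self):
        g = simcore.build_genome(2000, 10_000, coupling=0.0, seed=5)
        assert abs(np.corrcoef(g.timing, g.euchromatin)[0, 1]) < 0.1

    @pytest.mark.parametrize("n_bins,bin_width", [(0, 100), (100, 0), (-5, 10)])
    def test_invalid_config(self, n_bins, bin_width):
        with pytest.raises(InvalidConfigError):
            simcore.build_genome(n_bins, bin_width)


class TestPlaceOrigins:
    def test_positions_strictly_increasing_within_genome(self, genome, origins):
        assert np.all(np.diff(origins.positions) > 0)
        assert origins.positions[0] >= 0
        assert origins.positions[-1] < genome.length
        assert np.all(origins.licensing_weight >= 0)

    def test_unskewed_placement_is_spatially_uniform(self, genome):
        o = simcore.place_origins(genome, 10, skew=0.0, seed=11)
        early = genome.timing[genome.bin_of(o.positions)] < np.median(genome.timing)
        n = len(o)
        # binomial 95% band around 1/2 for one seeded draw
        band = 1.96 * np.sqrt(0.25 / n)
        assert abs(early.mean() - 0.5) < band + 0.05

    def test_skew_concentrates_origins_in_early_half(self, genome):
        fracs = []
        for seed in range(20):
            o = simcore.place_origins(genome, 10, skew=3.0, seed=seed)
            t = genome.timing[genome.bin_of(o.positions)]
            fracs.append(np.mean(t < np.median(genome.timing)))
        assert np.mean(fracs) > 0.70

    def test_zero_expected_count_returns_empty_set(self, genome):
        with pytest.warns(UserWarning):
            o = simcore.place_origins(genome, 1e-9, seed=1)
        assert len(o) == 0

    def test_dormant_fraction_flags(self, origins):
        frac = origins.is_dormant.mean()
        assert 0.05 < frac < 0.30


class TestSimulatePopulation:
    def test_normal_mode_copy_conservation(self, normal_pop):
        assert normal_pop.copy_min >= 1
        assert normal_pop.copy_max <= 2

    def test_normal_mode_no_hh_fragments(self, normal_pop):
        assert normal_pop.fragment_class_totals()["HH"] == 0

    def test_fragment_totals_conserve_cells_times_bins(self, genome, normal_pop):
        total = sum(normal_pop.fragment_class_totals().values())
        assert total == genome.n_bins * normal_pop.cells

    def test_forced_s_end_fully_duplicates(self, genome, origins, params):
        pop = simcore.simulate_population(genome, origins, params.with_(cells=1),
                                          "normal", s_progress=1.0)
        assert pop.copy_min == 2 and pop.copy_max == 2
        totals = pop.fragment_class_totals()
        assert totals["HL"] == genome.n_bins and totals["LL"] == totals["HH"] == 0

    def test_rereplication_exceeds_two_copies(self, rerep_pop):
        assert rerep_pop.copy_max > 2
        assert rerep_pop.fragment_class_totals()["HH"] > 0

    def test_hh_fraction_equals_rereplicated_share_by_recount(self, rerep_pop):
        totals = rerep_pop.fragment_class_totals()
        recount = totals["HH"] / sum(totals.values())
        assert rerep_pop.hh_template_fraction == pytest.approx(recount)

    def test_early_bias_in_rereplicated_copy(self, genome, uniform_origins, params):
        pop = simcore.simulate_population(genome, uniform_origins,
                                          params.with_(seed=8, rerep_bias=2.0),
                                          "rereplication")
        lo, hi = np.quantile(genome.timing, [0.1, 0.9])
        early = pop.copy_per_bin[genome.timing <= lo].mean()
        late = pop.copy_per_bin[genome.timing >= hi].mean()
        assert early > late

    def test_beta_monotone_in_early_late_ratio(self, genome, uniform_origins, params):
        lo, hi = np.quantile(genome.timing, [0.1, 0.9])
        ratios = []
        for beta in (0.0, 1.0, 2.0):
            pop = simcore.simulate_population(
                genome, uniform_origins, params.with_(seed=8, rerep_bias=beta),
                "rereplication")
            ratios.append(pop.copy_per_bin[genome.timing <= lo].mean()
                          / pop.copy_per_bin[genome.timing >= hi].mean())
        assert ratios[0] < ratios[1] < ratios[2]
        # beta=0 matches the completed-round baseline (ratio 1) within noise
        assert ratios[0] == pytest.approx(1.0, abs=0.1)

    def test_deterministic_per_seed(self, genome, origins, params):
        a = simcore.simulate_population(genome, origins, params, "rereplication")
        b = simcore.simulate_population(genome, origins, params, "rereplication")
        np.testing.assert_array_equal(a.copy_per_bin, b.copy_per_bin)
        np.testing.assert_array_equal(a.class_counts, b.class_counts)

    def test_unknown_mode_rejected(self, genome, origins, params):
        with pytest.raises(InvalidConfigError):
            simcore.simulate_population(genome, origins, params, "meiosis")


class TestNascentReads:
    def test_zero_firing_gives_zero_reads(self, origins, normal_pop):
        silent = normal_pop.__class__(
            mode="normal", cells=normal_pop.cells,
            copy_per_bin=normal_pop.copy_per_bin,
            firing_normal=np.zeros(len(origins), dtype=int),
            firing_re=np.zeros(len(origins), dtype=int),
            class_counts=normal_pop.class_counts,
            copy_min=1, copy_max=2)
        reads = simcore.simulate_nascent_reads(origins, silent, 500, seed=1)
        assert reads.sum() == 0

    def test_depth_doubling_doubles_mean_counts(self, origins, normal_pop):
        r1 = simcore.simulate_nascent_reads(origins, normal_pop, 250, seed=1)
        r2 = simcore.simulate_nascent_reads(origins, normal_pop, 500, seed=2)
        ratio = r2.mean() / r1.mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_hh_positive_origins_are_hl_positive(self, origins, rerep_pop):
        hl = simcore.simulate_nascent_reads(origins, rerep_pop, 500, 10)
        hh = simcore.simulate_nascent_reads(origins, rerep_pop, 500, 11,
                                            which_round="re")
        shared = np.mean(hl[hh > 0] > 0)
        assert shared >= 0.95

    def test_invalid_depth(self, origins, normal_pop):
        with pytest.raises(InvalidConfigError):
            simcore.simulate_nascent_reads(origins, normal_pop, 0.0)


class TestFiberSimulation:
    def test_no_stall_no_noise_gives_equal_full_forks(self, origins):
        p = simcore.SimParams(stall_prob=0.0, fiber_noise_cv=0.0,
                              fork_speed_kb_per_min=1.0)
        fs = simcore.simulate_fibers(origins, p, 50, seed=1)
        np.testing.assert_allclose(fs.records["left_kb"], 40.0)
        np.testing.assert_allclose(fs.records["right_kb"], 40.0)

    def test_zero_fibers_gives_empty_set(self, origins, params):
        assert len(simcore.simulate_fibers(origins, params, 0, seed=1)) == 0

    def test_stall_model_matches_monte_carlo_oracle(self, origins):
        p = simcore.SimParams(stall_prob=0.5, fiber_noise_cv=0.0)
        fs = simcore.simulate_fibers(origins, p, 2000, seed=1)
        left = fs.records["left_kb"].to_numpy()
        right = fs.records["right_kb"].to_numpy()
        frac = np.mean(np.abs(left - right) / np.maximum(left, right) > 0.30)
        oracle = simcore.stall_model_asymmetry_mc(0.5)
        sd = np.sqrt(oracle * (1 - oracle) / len(left))
        assert abs(frac - oracle) < 3 * sd

    def test_mean_inter_origin_gap_matches_exponential_mean(self, origins):
        p = simcore.SimParams(fiber_mean_iod_kb=100.0, fiber_extra_origins=1.5)
        fs = simcore.simulate_fibers(origins, p, 5000, seed=2)
        gaps = []
        for _, grp in fs.records.groupby("fiber_id"):
            pos = np.sort(grp["origin_pos_kb"].to_numpy())
            gaps.extend(np.diff(pos))
        assert np.mean(gaps) == pytest.approx(100.0, rel=0.05)


class TestGradient:
    def test_pure_hl_with_tiny_sd_occupies_single_fraction(self):
        prof = simcore.simulate_gradient({"HL": 1000}, sd=1e-9, seed=1)
        assert (prof["mass_total"] > 0).sum() == 1

    def test_total_mass_conserved(self):
        totals = {"LL": 123, "HL": 456, "HH": 78}
        prof = simcore.simulate_gradient(totals, seed=2)
        assert prof["mass_total"].sum() == sum(totals.values())

    def test_hh_window_recovers_mixture_fraction(self):
        n = 100_000
        prof = simcore.simulate_gradient(simcore.fragment_mixture(n, 0.30), seed=3)
        mass = simcore.class_window_mass(prof, "HH")
        assert abs(mass - 0.30) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            simcore.simulate_gradient({})

    def test_unordered_densities_rejected(self):
        with pytest.raises(InvalidConfigError):
            simcore.simulate_gradient({"HL": 10}, densities=(1.8, 1.75, 1.7))
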