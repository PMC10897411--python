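"""Simulator unit and property tests: division rules, WGD, stepping, traces."""

import dataclasses

import numpy as np
import pytest

from cinsim import (
    N_CHROM,
    SimulationConfig,
    attempt_wgd,
    divide,
    init_population,
    per_step_probability,
    run_replicates,
    run_simulation,
    step,
    update_division_prob,
)
from cinsim.abm import VIABLE_MAX, VIABLE_MIN, _segregation_delta, is_viable

NH1_SEED = [1] * N_CHROM  # near-haploid: disomic 14, 18, 21, X (total 27)
for _i in (13, 17, 20, 22):
    NH1_SEED[_i] = 2


def interior_parents(rng, n=1000):
    """Karyotypes whose daughters cannot hit the viability bounds."""
    return rng.integers(3, 5, size=(n, N_CHROM)).astype(np.int16)


class TestPerStepProbability:
    def test_per_day_to_two_hour_tick(self):
        assert per_step_probability(0.24, dt=2.0) == pytest.approx(0.02)

    def test_zero_and_saturation(self):
        assert per_step_probability(0.0, 2.0) == 0.0
        assert per_step_probability(24.0, 2.0) == 1.0  # clipped

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            per_step_probability(0.1, 0.0)
        with pytest.raises(ValueError):
            per_step_probability(-0.1, 2.0)


class TestConfig:
    def test_dt_must_divide_record_every(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=5.0, record_every=12.0).validate()

    def test_inviable_seed_karyotype_rejected(self):
        bad = [2] * N_CHROM
        bad[0] = 7
        with pytest.raises(ValueError):
            SimulationConfig(seed_karyotype=bad).validate()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(missegregation_mode="sometimes").validate()

    def test_from_file_round_trip(self, tmp_path):
        p = tmp_path / "run.cfg"
        p.write_text("p_cin: 0.1\nn_init: 50\ncarrying_capacity: 1000\nrng_seed: 9\n")
        cfg = SimulationConfig.from_file(str(p))
        assert (cfg.p_cin, cfg.n_init, cfg.carrying_capacity, cfg.rng_seed) == (0.1, 50, 1000, 9)
        p.write_text("p_cinn: 0.1\n")
        with pytest.raises(ValueError):
            SimulationConfig.from_file(str(p))


class TestDivide:
    def test_no_cin_identity(self, rng):
        parent = rng.integers(1, 7, size=N_CHROM)
        for _ in range(20):
            daughters = divide(parent, p_cin=0.0, rng=rng)
            assert len(daughters) == 2
            for d in daughters:
                np.testing.assert_array_equal(d, parent)

    def test_forced_missegregation_moves_one_reciprocal_copy(self, rng):
        parent = np.full(N_CHROM, 3)
        for _ in range(50):
            a, b = divide(parent, p_cin=1.0, rng=rng)
            np.testing.assert_array_equal(a + b, 2 * parent)
            diff = a - parent
            assert sorted(np.abs(diff))[-1] == 1 and np.abs(diff).sum() == 1

    def test_gaining_daughter_dies_at_six_copies(self, rng):
        parent = np.full(N_CHROM, 6)  # any gain -> 7 copies -> catastrophe
        daughters = divide(parent, p_cin=1.0, rng=rng)
        assert len(daughters) == 1
        assert daughters[0].max() == 6 and daughters[0].min() == 5

    def test_losing_daughter_dies_at_one_copy(self, rng):
        parent = np.full(N_CHROM, 1)  # any loss -> 0 copies -> catastrophe
        daughters = divide(parent, p_cin=1.0, rng=rng)
        assert len(daughters) == 1
        assert daughters[0].min() == 1 and daughters[0].max() == 2

    @pytest.mark.parametrize("mode", ["per_division", "per_chromosome"])
    def test_conservation_over_randomized_divisions(self, mode, rng):
        parents = interior_parents(rng, 10_000)
        delta = _segregation_delta(parents, 0.5, mode, rng)
        a, b = parents + delta, parents - delta
        np.testing.assert_array_equal(a + b, 2 * parents)  # per-slot conservation
        assert is_viable(a).all() and is_viable(b).all()
        if mode == "per_division":
            assert (np.abs(delta).sum(axis=1) <= 1).all()


class TestWGD:
    def test_euploid_total_never_doubles(self, rng):
        k = np.full(N_CHROM, 2)  # total 46 >= threshold
        np.testing.assert_array_equal(attempt_wgd(k, p_wgd_step=1.0, rng=rng), k)

    def test_near_haploid_doubles_every_slot(self, rng):
        doubled = attempt_wgd(NH1_SEED, p_wgd_step=1.0, rng=rng)
        np.testing.assert_array_equal(doubled, 2 * np.asarray(NH1_SEED))
        assert doubled.sum() == 54

    def test_zero_probability_is_identity(self, rng):
        np.testing.assert_array_equal(attempt_wgd(NH1_SEED, 0.0, rng), NH1_SEED)

    def test_overshooting_doubling_triggers_catastrophe_in_step(self, phi):
        # total 29 < 40 but one slot at 4: doubling makes 8 -> cell removed
        seed = [1] * N_CHROM
        seed[0], seed[1] = 4, 3
        cfg = SimulationConfig(
            n_init=200, seed_karyotype=seed, p_wgd=1e9, p_death=0.0, p_cin=0.0,
            carrying_capacity=10_000, t_total=5, rng_seed=0,
        )
        tr = run_simulation(cfg)
        # every divider attempts WGD, overshoots, and is removed: no growth
        assert tr.n_cells.max() <= 200
        assert tr.n_cells[-1] < 200


class TestDivisionProbUpdate:
    def test_constant_fitness_leaves_p_div_unchanged(self):
        assert update_division_prob(0.31, 1.0, 1.0) == pytest.approx(0.31)

    def test_rising_and_falling_fitness(self):
        assert update_division_prob(0.3, 1.10, 1.00) == pytest.approx(0.33)
        assert update_division_prob(0.3, 0.90, 1.00) == pytest.approx(0.27)

    def test_cap_and_floor(self):
        assert update_division_prob(10.0, 2.0, 1.0, cap=12.0) == 12.0
        with pytest.raises(ValueError):
            update_division_prob(0.3, 1.0, 0.0)


class TestInitPopulation:
    def test_degenerate_total_distribution(self, phi, rng):
        cfg = SimulationConfig(n_init=100, init_total_mean=46, init_total_sd=0.0)
        state = init_population(cfg.validate(), phi, rng)
        assert (state.total == 46).all()

    def test_patient_seed_population_is_clonal(self, phi, rng):
        cfg = SimulationConfig(n_init=64, seed_karyotype=NH1_SEED).validate()
        state = init_population(cfg, phi, rng)
        np.testing.assert_array_equal(state.copies, np.tile(NH1_SEED, (64, 1)))

    def test_default_population_size_and_p_div_interval(self, phi, rng):
        state = init_population(SimulationConfig().validate(), phi, rng)
        assert state.n_cells == 500
        assert ((state.p_div >= 0.2) & (state.p_div <= 0.4)).all()
        assert is_viable(state.copies).all()


class TestStep:
    def test_deterministic_doubling_limit(self, phi, rng):
        # division certain per tick, no death, no CIN, far below capacity
        cfg = SimulationConfig(
            n_init=16, p_div_low=12.0, p_div_high=12.0, p_death=0.0, p_cin=0.0,
            carrying_capacity=10_000, rng_seed=0,
        ).validate()
        state = init_population(cfg, phi, rng)
        for expected in (32, 64, 128, 256):
            step(state, cfg, phi, rng)
            assert state.n_cells == expected

    def test_capacity_blocks_growth(self, phi, rng):
        cfg = SimulationConfig(
            n_init=100, carrying_capacity=100, p_death=0.0, p_cin=0.0, rng_seed=0
        ).validate()
        state = init_population(cfg, phi, rng)
        for _ in range(5):
            step(state, cfg, phi, rng)
            assert state.n_cells == 100

    def test_certain_death_extinguishes_and_is_flagged(self):
        cfg = SimulationConfig(n_init=30, p_death=12.0, t_total=1, carrying_capacity=1000)
        tr = run_simulation(cfg)
        assert tr.extinct and tr.n_cells[-1] == 0

    def test_viability_bounds_hold_in_snapshots(self):
        cfg = SimulationConfig(
            n_init=100, p_cin=0.4, carrying_capacity=2000, t_total=20,
            snapshot_mode="counts", rng_seed=3,
        )
        tr = run_simulation(cfg)
        for _, kary, counts in tr.snapshots:
            assert kary.min() >= VIABLE_MIN and kary.max() <= VIABLE_MAX
            assert counts.sum() <= 2000


class TestRunSimulation:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_init=50, p_cin=0.2, carrying_capacity=3000, t_total=15)
        a = run_simulation(cfg, rng_seed=7)
        b = run_simulation(cfg, rng_seed=7)
        assert a.to_frame().equals(b.to_frame())
        assert a.time_to_capacity == b.time_to_capacity

    def test_no_cin_creates_no_novel_karyotypes(self):
        cfg = SimulationConfig(
            n_init=50, p_cin=0.0, p_wgd=0.0, seed_karyotype=[2] * N_CHROM,
            carrying_capacity=2000, t_total=15, snapshot_mode="counts", rng_seed=5,
        )
        tr = run_simulation(cfg)
        for _, kary, _ in tr.snapshots:
            assert kary.shape[0] == 1
            np.testing.assert_array_equal(kary[0], [2] * N_CHROM)

    def test_population_never_exceeds_capacity_and_monotone_without_death(self):
        cfg = SimulationConfig(
            n_init=100, p_death=0.0, p_cin=0.1, carrying_capacity=5000, t_total=30, rng_seed=2
        )
        tr = run_simulation(cfg)
        assert tr.n_cells.max() <= 5000
        until = int(np.argmax(tr.n_cells >= 5000)) or len(tr.n_cells)
        assert (np.diff(tr.n_cells[: until + 1]) >= 0).all()

    def test_no_cin_from_single_seed_has_zero_diversity(self):
        cfg = SimulationConfig(
            n_init=50, p_cin=0.0, p_wgd=0.0, seed_karyotype=[2] * N_CHROM,
            carrying_capacity=2000, t_total=10, rng_seed=5,
        )
        tr = run_simulation(cfg)
        np.testing.assert_allclose(tr.net_karyotype_sd, 0.0)


class TestRunReplicates:
    def test_single_replicate_equals_its_trace(self):
        cfg = SimulationConfig(n_init=40, carrying_capacity=1000, t_total=10)
        agg = run_replicates(cfg, n_reps=1, base_seed=3)
        tr = agg.traces[0]
        np.testing.assert_allclose(agg.summary["n_cells_mean"], tr.n_cells)
        np.testing.assert_allclose(agg.summary["n_cells_sem"], 0.0)

    def test_initial_mean_population_is_n_init(self):
        cfg = SimulationConfig(n_init=123, carrying_capacity=1000, t_total=5)
        agg = run_replicates(cfg, n_reps=3, base_seed=0)
        assert agg.summary["n_cells_mean"].iloc[0] == 123

    def test_disjoint_base_seeds_statistically_compatible(self):
        cfg = SimulationConfig(
            n_init=200, carrying_capacity=2000, t_total=40, stop_at_capacity=True
        )
        t_a = run_replicates(cfg, n_reps=4, base_seed=100).mean_time_to_capacity()
        t_b = run_replicates(cfg, n_reps=4, base_seed=20_000).mean_time_to_capacity()
        assert abs(t_a - t_b) / t_a < 0.25

    def test_patient_seeded_nh_run_enriches_doubled_totals(self):
        # near-haploid seed: doubling is accessible (<40 chromosomes) and the
        # doubled clone is robust to copy loss, so its share keeps growing
        cfg = SimulationConfig(
            n_init=300, seed_karyotype=NH1_SEED, p_cin=0.1, carrying_capacity=8000,
            t_total=60, snapshot_mode="counts", rng_seed=11,
        )
        tr = run_simulation(cfg)

        def doubled_fraction(idx):
            _, kary, counts = tr.snapshots[idx]
            totals = kary.sum(axis=1)
            return counts[totals >= 40].sum() / counts.sum()

        early, late = doubled_fraction(20), doubled_fraction(-1)  # day 10 vs 60
        assert doubled_fraction(0) == 0.0
        assert late > early
        assert late > 0.0
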