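"""Lattice state, placement, energies, and Metropolis dynamics."""

import numpy as np
import pytest

from condmix import _kernel
from condmix.config import MOVE_ORDER, SimulationConfig, Species
from condmix.lattice import init_state, total_energy
from condmix.models import InteractionModel, build_interaction_model
from condmix.simulate import (mc_sweep, metropolis_acceptance, run_protocol,
                              sample_schedule)


def _toy_model():
    aniso = np.zeros((3, 3))
    aniso[0, 1] = aniso[1, 0] = -2.0
    aniso[0, 2] = aniso[2, 0] = -2.0
    iso = np.zeros((3, 3))
    iso[1, 2] = iso[2, 1] = 0.4
    iso[0, 1] = iso[1, 0] = -0.1
    return InteractionModel(aniso, iso)


class TestInitState:
    def test_counts_and_empty_bonds(self):
        cfg = SimulationConfig(
            lattice_size=10, species=[Species("w", 3, "whi3")],
            molecule_counts=[1], t_EQ=10, t_total=20, f_data=10)
        st = init_state(cfg, seed=0)
        assert st.n_beads == 3
        assert (st.occ >= 0).sum() == 3
        assert np.all(st.bond == -1)
        st.validate()

    def test_ternary_reference_bead_count(self):
        # 5000 trimers + 1000 + 1000 octamers = 31000 beads
        cfg = SimulationConfig(
            lattice_size=100,
            species=[Species("w", 3, "whi3"), Species("a", 8, "rna1"),
                     Species("b", 8, "rna2")],
            molecule_counts=[5000, 1000, 1000],
            t_EQ=10, t_total=20, f_data=10)
        assert cfg.total_beads == 31000

    def test_deterministic_for_fixed_seed(self, small_ternary_config):
        s1 = init_state(small_ternary_config, seed=7)
        s2 = init_state(small_ternary_config, seed=7)
        assert np.array_equal(s1.pos, s2.pos)
        s3 = init_state(small_ternary_config, seed=8)
        assert not np.array_equal(s1.pos, s3.pos)

    def test_placement_succeeds_even_near_full_occupancy(self):
        cfg = SimulationConfig(
            lattice_size=5, species=[Species("a", 2, "rna1", linker_length=2)],
            molecule_counts=[62],  # 124 beads on 125 sites
            t_EQ=10, t_total=20, f_data=10)
        st = init_state(cfg, seed=0)
        st.validate()
        assert st.n_beads == 124

    def test_exhausted_retries_fail_cleanly(self):
        cfg = SimulationConfig(
            lattice_size=10, species=[Species("a", 2, "rna1")],
            molecule_counts=[4], t_EQ=10, t_total=20, f_data=10)
        with pytest.raises(RuntimeError, match="dense"):
            init_state(cfg, seed=0, max_restarts=0)

    def test_capacity_overflow_rejected_at_config_time(self):
        with pytest.raises(ValueError, match="capacity"):
            SimulationConfig(
                lattice_size=5, species=[Species("a", 2, "rna1")],
                molecule_counts=[70], t_EQ=10, t_total=20, f_data=10)


class TestEnergies:
    def test_empty_state_zero_interaction(self, small_ternary_config):
        st = init_state(small_ternary_config, seed=3)
        base = build_interaction_model("base")
        # no bonds and base has no isotropic terms
        assert total_energy(st, base) == 0.0

    def test_single_bond_energy_is_epsilon(self):
        cfg = SimulationConfig(
            lattice_size=10,
            species=[Species("w", 1, "whi3"), Species("a", 1, "rna1")],
            molecule_counts=[1, 1], t_EQ=10, t_total=20, f_data=10)
        st = init_state(cfg, seed=0)
        st.pos[0] = [5, 5, 5]
        st.pos[1] = [5, 5, 6]
        st.occ = st._build_occ()
        st.bond[0], st.bond[1] = 1, 0
        assert total_energy(st, build_interaction_model("base")) == -2.0

    def test_constraint_zero_inside_heaviside_radius(self):
        cfg = SimulationConfig(
            lattice_size=10, species=[Species("w", 1, "whi3")],
            molecule_counts=[1], t_EQ=10, t_total=20, f_data=10)
        st = init_state(cfg, seed=0)
        st.pos[0] = [5, 5, 5]  # at the geometric center
        st.occ = st._build_occ()
        e = total_energy(st, build_interaction_model("base"),
                         constraint_mode=_kernel.C_HEAVISIDE, T=10.0,
                         R_B=3.0)
        assert e == 0.0
        st.pos[0] = [0, 0, 0]  # corner, r = 5*sqrt(3) > R_B
        st.occ = st._build_occ()
        e = total_energy(st, build_interaction_model("base"),
                         constraint_mode=_kernel.C_HEAVISIDE, T=10.0,
                         R_B=3.0)
        assert e == pytest.approx(10.0 * 75.0)

    def test_metropolis_acceptance_closed_form(self):
        assert metropolis_acceptance(2.0, 1.0) == pytest.approx(np.exp(-2))
        assert metropolis_acceptance(-1.0, 1.0) == 1.0
        assert metropolis_acceptance(0.0, 1.0) == 1.0


class TestSweepInvariants:
    @pytest.mark.parametrize("move", MOVE_ORDER)
    def test_each_move_preserves_invariants_and_energy_bookkeeping(
            self, small_ternary_config, move):
        model = _toy_model()
        st = init_state(small_ternary_config, seed=1)
        E = total_energy(st, model)
        w = np.zeros(len(MOVE_ORDER))
        w[MOVE_ORDER.index(move)] = 1.0
        if move != "bond":
            w[MOVE_ORDER.index("bond")] = 0.5  # let bonds form too
        dE = mc_sweep(st, model, T=1.0, weights=w, rng_seed=99)
        for _ in range(150):
            dE += mc_sweep(st, model, T=1.0, weights=w)
        st.validate()
        assert E + dE == pytest.approx(total_energy(st, model), abs=1e-9)

    def test_combined_sweeps_track_energy_to_1e9(self, small_ternary_config):
        model = _toy_model()
        st = init_state(small_ternary_config, seed=2)
        E = total_energy(st, model)
        dE = mc_sweep(st, model, T=0.7, rng_seed=5)
        for _ in range(300):
            dE += mc_sweep(st, model, T=0.7)
        st.validate()
        assert E + dE == pytest.approx(total_energy(st, model), abs=1e-9)


class TestRunProtocol:
    def test_sample_count_and_window(self, small_ternary_config):
        model = build_interaction_model("base")
        samples = run_protocol(small_ternary_config, model)
        expected = sample_schedule(small_ternary_config)
        assert [s.mc_step for s in samples] == expected.tolist()
        assert all(s.mc_step > small_ternary_config.t_total // 2
                   for s in samples)

    def test_replicates_differ_but_are_reproducible(self, small_ternary_config):
        model = build_interaction_model("base")
        a = run_protocol(small_ternary_config, model, replicate=0)
        b = run_protocol(small_ternary_config, model, replicate=1)
        a2 = run_protocol(small_ternary_config, model, replicate=0)
        assert np.array_equal(a[-1].positions, a2[-1].positions)
        assert not np.array_equal(a[-1].positions, b[-1].positions)

    def test_final_state_invariants_hold(self, small_ternary_config):
        model = _toy_model()
        samples, state, E = run_protocol(small_ternary_config, model,
                                         return_state=True)
        state.validate()
        assert E == pytest.approx(total_energy(state, model), abs=1e-9)


class TestBoltzmannToySmall:
    def test_bond_occupancy_matches_exact_enumeration(self):
        """Short-run sanity check of the sampler against exact statistics.

        Uses the enumerable two-bead system and compares the marginal bond
        probability (a single robust statistic) with its closed form; the
        full chi-square test over all states runs in the acceptance suite.
        """
        from condmix.synth import gen_lattice_toy
        cfg, model = gen_lattice_toy("boltzmann_toy")
        L = cfg.lattice_size

        def mind(d):
            d = d % L
            return d - L if 2 * d > L else d

        w_b, w_u = 0.0, 0.0
        for dx in range(L):
            for dy in range(L):
                for dz in range(L):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    d2 = mind(dx) ** 2 + mind(dy) ** 2 + mind(dz) ** 2
                    iso = 0.3 if d2 <= 3 else 0.0
                    w_u += np.exp(-iso)
                    if d2 <= 3:
                        w_b += np.exp(-(iso - 2.0))
        p_bond = w_b / (w_b + w_u)
        samples = run_protocol(cfg, model)
        obs = np.mean([s.bonds[0] == 1 for s in samples])
        # binomial tolerance with a generous margin for autocorrelation
        se = np.sqrt(p_bond * (1 - p_bond) / len(samples))
        assert abs(obs - p_bond) < 6 * se
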