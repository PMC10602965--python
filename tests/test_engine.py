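import math

import numpy as np
import pytest

from npgsim.energy import EnergyParams, FLAT_GOLD
from npgsim.engine import (
    ACTIVE,
    ASSOCIATED,
    BOUND,
    ConfigurationError,
    INACTIVE,
    MembraneLattice,
    SimConfig,
    initialize,
    map_substrate_to_lattice,
    mc_step,
    run_steps,
    run_to_equilibrium,
)
from npgsim.substrate import SubstrateField, make_flat_gold


def small_config(**kw):
    defaults = dict(
        n_integrins=50,
        lattice=MembraneLattice(n_rows=20, n_cols=20),
        seed=3,
        pore_nm=75.0,
        max_steps=2000,
        equil_window=500,
        record_every=10,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestInitialize:
    def test_default_setup(self):
        st = initialize(SimConfig(seed=1))
        assert st.n_integrins == 1000
        assert np.all(st.state == INACTIVE)
        # no shared sites: every placed integrin is registered exactly once
        assert (st.occ >= 0).sum() == 1000
        assert np.array_equal(np.sort(st.occ[st.row, st.col]), np.arange(1000))

    def test_same_seed_same_placement(self):
        a, b = initialize(SimConfig(seed=9)), initialize(SimConfig(seed=9))
        assert np.array_equal(a.row, b.row) and np.array_equal(a.col, b.col)

    def test_full_lattice(self):
        cfg = SimConfig(n_integrins=16, lattice=MembraneLattice(n_rows=4, n_cols=4))
        st = initialize(cfg)
        assert (st.occ >= 0).all()

    def test_capacity_error(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_integrins=17, lattice=MembraneLattice(n_rows=4, n_cols=4))

    def test_too_large_dt_rejected(self):
        # at dt = 1 s the inactivation channel alone saturates the sweep
        with pytest.raises(ConfigurationError, match="dt"):
            initialize(small_config(), EnergyParams(dt=1.0, k_b_plus=500.0))


class TestMcStep:
    def test_all_rates_zero_only_diffusion(self):
        cfg = small_config(binding_enabled=False, association_enabled=False)
        st = initialize(cfg, EnergyParams(E_a=50.0, k_a_plus=1e-12))
        before = st.counts()
        positions = (st.row.copy(), st.col.copy())
        for _ in range(20):
            mc_step(st)
        assert st.counts() == before  # state counts unchanged
        assert not (
            np.array_equal(st.row, positions[0]) and np.array_equal(st.col, positions[1])
        )  # but integrins moved

    def test_integrin_conservation(self):
        st = initialize(small_config())
        for _ in range(50):
            mc_step(st)
            assert sum(st.counts()) == 50
            assert (st.occ >= 0).sum() == 50

    def test_state_ladder_legality(self):
        # adjacent-rung transitions only, audited step by step
        allowed = {
            INACTIVE: {INACTIVE, ACTIVE},
            ACTIVE: {INACTIVE, ACTIVE, BOUND},
            BOUND: {ACTIVE, BOUND, ASSOCIATED},
            ASSOCIATED: {BOUND, ASSOCIATED},
        }
        st = initialize(small_config(seed=11))
        prev = st.state.copy()
        for _ in range(400):
            mc_step(st)
            for s_old, s_new in zip(prev, st.state):
                assert s_new in allowed[int(s_old)]
            prev = st.state.copy()

    def test_associated_integrins_never_orphaned(self):
        st = initialize(small_config(seed=5))
        run_steps(st, 500)
        assoc = np.flatnonzero(st.state == ASSOCIATED)
        n_rows, n_cols = st.occ.shape
        for idx in assoc:
            r, c = st.row[idx], st.col[idx]
            nbrs = [
                st.occ[(r - 1) % n_rows, c], st.occ[(r + 1) % n_rows, c],
                st.occ[r, (c - 1) % n_cols], st.occ[r, (c + 1) % n_cols],
            ]
            assert any(nb >= 0 and st.state[nb] == ASSOCIATED for nb in nbrs)

    def test_single_integrin_two_state_fraction(self):
        # one integrin, activation only: active fraction = 1/(1+e^3)
        cfg = SimConfig(
            n_integrins=1, lattice=MembraneLattice(n_rows=4, n_cols=4), seed=2,
            binding_enabled=False, association_enabled=False,
            max_steps=10**6, equil_window=10,
        )
        st = initialize(cfg)
        rec = run_steps(st, 200_000, record_every=1)
        active = rec[:, 1].astype(float)
        blocks = active.reshape(100, -1).mean(axis=1)
        f = blocks.mean()
        se = blocks.std(ddof=1) / math.sqrt(len(blocks))
        assert abs(f - 1.0 / (1.0 + math.e**3)) <= 3 * se


class TestDeterminism:
    def test_identical_config_identical_trajectory(self):
        a = run_to_equilibrium(small_config(seed=21))
        b = run_to_equilibrium(small_config(seed=21))
        assert np.array_equal(a.n_associated, b.n_associated)
        assert np.array_equal(a.final_state.state, b.final_state.state)
        assert np.array_equal(a.final_state.row, b.final_state.row)

    def test_different_seeds_differ(self):
        a = run_to_equilibrium(small_config(seed=1))
        b = run_to_equilibrium(small_config(seed=2))
        assert not np.array_equal(a.final_state.row, b.final_state.row)


class TestRunToEquilibrium:
    def test_checkpoint_counts_sum_to_total(self):
        traj = run_to_equilibrium(small_config())
        totals = traj.n_inactive + traj.n_active + traj.n_bound + traj.n_associated
        assert np.all(totals == 50)

    def test_zero_integrins_immediate_equilibrium(self):
        traj = run_to_equilibrium(small_config(n_integrins=0))
        assert traj.equilibrated and len(traj.steps) == 0

    def test_non_convergence_is_flagged(self):
        cfg = small_config(equil_tolerance=0.0, max_steps=1500)
        traj = run_to_equilibrium(cfg)
        assert not traj.equilibrated
        assert traj.equil_step == 1500

    def test_min_steps_defers_equilibrium(self):
        cfg = small_config(
            binding_enabled=False, association_enabled=False,
            min_steps=1800, max_steps=2000,
        )
        traj = run_to_equilibrium(cfg)
        assert traj.equil_step >= 1800

    def test_dt_robustness_of_equilibrium(self):
        # halving dt does not move the activation equilibrium
        fracs = []
        for dt in (0.010, 0.005):
            cfg = SimConfig(
                n_integrins=400, lattice=MembraneLattice(30, 30), seed=8,
                binding_enabled=False, association_enabled=False,
                max_steps=30_000, equil_window=1000, record_every=10,
            )
            st = initialize(cfg, EnergyParams(dt=dt))
            rec = run_steps(st, 20_000, record_every=10)
            tail = rec[rec[:, 0] > 2_000]
            fracs.append(tail[:, 1].mean() / 400)
        assert fracs[0] == pytest.approx(fracs[1], abs=0.004)
        assert fracs[0] == pytest.approx(1.0 / (1.0 + math.e**3), abs=0.004)


class TestSubstrateMapping:
    def test_flat_gold_all_ones(self):
        site_c = map_substrate_to_lattice(make_flat_gold(100), 100, 100, 60.0)
        assert np.all(site_c == 1.0)

    def test_stripe_field_tracks_pattern(self):
        # vertical stripes, 120 nm gold / 120 nm pore at 30 nm/px, aligned
        # with the 60 nm site grid: site columns alternate 1,1,0,0,...
        n_px = 240  # 7200 nm > 6000 nm membrane
        stripe = (np.arange(n_px) // 4) % 2 == 0
        conc = np.tile(stripe.astype(float), (n_px, 1))
        fld = SubstrateField(conc, pixel_size=30.0)
        site_c = map_substrate_to_lattice(fld, 100, 100, 60.0)
        expected_cols = ((np.arange(100) // 2) % 2 == 0).astype(float)
        assert np.allclose(site_c, np.tile(expected_cols, (100, 1)))

    def test_mean_preserved_under_averaging(self, npg_field_20nm):
        fld = npg_field_20nm
        site_c = map_substrate_to_lattice(fld, 100, 100, 60.0)
        assert site_c.mean() == pytest.approx(
            np.clip(fld.concentration, 0, 1).mean(), abs=0.02
        )

    def test_undersized_field_without_tiling_rejected(self, npg_field_20nm):
        with pytest.raises(ConfigurationError):
            map_substrate_to_lattice(npg_field_20nm, 100, 100, 60.0, tile=False)

    def test_field_mode_runs(self, npg_field_20nm):
        cfg = small_config(c_mode="field", substrate=npg_field_20nm, pore_nm=20.0)
        traj = run_to_equilibrium(cfg)
        assert sum(traj.final_state.counts()) == 50
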