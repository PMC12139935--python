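"""Langevin engine: forces, minimization, dynamics, initialization."""
import numpy as np
import pandas as pd
import pytest

from qzipper.cg_simulator import (
    KB,
    NonbondedTables,
    SimConfig,
    SystemState,
    box_side_from_concentration,
    compile_nonbonded,
    energy_forces,
    excluded_volume_tables,
    initialize_system,
    minimize,
    polyq_bead_topology,
    run,
)
from qzipper.contact_model import MultiStatePotential


def toy_potential(epsilon=0.4):
    pairs = pd.DataFrame(
        [
            dict(scope="intra", res_i=1, res_j=5, **{"class": "native"},
                 probability=0.8, sigma_nm=0.5, source="monomer"),
            dict(scope="inter", res_i=2, res_j=7, **{"class": "native"},
                 probability=0.6, sigma_nm=0.45, source="fibril"),
        ]
    )
    return MultiStatePotential(pairs=pairs, epsilon=epsilon)


def chain_grid_state(topo, n_chains, n_res, rng, spacing=1.2, box=8.0):
    pos = np.zeros((topo.n_beads, 3))
    for c in range(n_chains):
        for r in range(n_res):
            bb = c * 2 * n_res + 2 * r
            pos[bb] = (0.36 * r, c * spacing, 0.0)
            pos[bb + 1] = (0.36 * r, c * spacing + 0.25, 0.0)
    pos += rng.normal(scale=0.02, size=pos.shape)
    vel = rng.standard_normal(pos.shape) * np.sqrt(KB * 300 / topo.masses)[:, None]
    return SystemState(
        positions=pos, velocities=vel, box=np.full(3, box),
        periodic=np.ones(3, dtype=bool),
    )


class TestBoxFromConcentration:
    def test_thousand_chains_at_ten_millimolar(self):
        assert box_side_from_concentration(1000, 0.010) == pytest.approx(55.0, abs=0.1)

    def test_single_chain_molar(self):
        """One chain at 1 mol/L occupies 1/N_A liters: a 1.18 nm box."""
        assert box_side_from_concentration(1, 1.0) == pytest.approx(1.18, abs=0.01)

    def test_inverse_for_dense_phase_box(self):
        """170 chains in a 13 nm box corresponds to ~128.5 mM."""
        conc = 170 / (6.02214076e23 * (13e-8) ** 3)
        assert conc * 1000 == pytest.approx(128.5, abs=0.5)
        assert box_side_from_concentration(170, conc) == pytest.approx(13.0, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            box_side_from_concentration(0, 0.01)
        with pytest.raises(ValueError):
            box_side_from_concentration(10, -1.0)


class TestForces:
    def test_bonded_pair_at_rest_length(self):
        topo, _ = polyq_bead_topology(1, 2)
        nb = excluded_volume_tables()
        pos = np.zeros((4, 3))
        pos[1] = (0.0, 0.255, 0.0)  # SC at rest
        pos[2] = (0.381, 0.0, 0.0)  # next CA at rest
        pos[3] = (0.381, 0.255, 0.0)
        st = SystemState(positions=pos, velocities=np.zeros_like(pos),
                         box=np.full(3, 10.0), periodic=np.zeros(3, bool))
        _, terms, forces = energy_forces(st, topo, nb)
        assert terms["bond"] == pytest.approx(0.0, abs=1e-20)

    def test_gradient_consistency(self, rng):
        """Central-difference check on relaxed random configurations:
        max relative force error < 1e-5."""
        topo, _ = polyq_bead_topology(3, 8)
        nb = compile_nonbonded(toy_potential(), topo)
        worst = 0.0
        for _ in range(2):
            st = chain_grid_state(topo, 3, 8, rng, box=6.0)
            st = minimize(st, topo, nb, fmax=50.0, max_steps=2000)
            _, _, f = energy_forces(st, topo, nb)
            h = 1e-5
            pos = st.positions
            for _k in range(25):
                i = int(rng.integers(topo.n_beads))
                k = int(rng.integers(3))
                pp = pos.copy(); pp[i, k] += h
                pm = pos.copy(); pm[i, k] -= h
                ep, _, _ = energy_forces(
                    SystemState(positions=pp, velocities=pos * 0, box=st.box,
                                periodic=st.periodic), topo, nb)
                em, _, _ = energy_forces(
                    SystemState(positions=pm, velocities=pos * 0, box=st.box,
                                periodic=st.periodic), topo, nb)
                fd = -(ep - em) / (2 * h)
                worst = max(worst, abs(fd - f[i, k]) / max(1.0, abs(fd)))
        assert worst < 1e-5

    def test_nonbonded_zero_beyond_cutoff(self):
        """Two isolated native beads beyond 1.45 nm feel nothing."""
        topo, _ = polyq_bead_topology(2, 1)
        nb = NonbondedTables(
            native_pairs=np.array([[0, 2]]), native_eps=np.array([1.0]),
            native_sigma=np.array([0.5]),
        )
        pos = np.array([[0, 0, 0], [0, 0.255, 0], [1.46, 0, 0], [1.46, 0.255, 0.0]])
        st = SystemState(positions=pos, velocities=pos * 0,
                         box=np.full(3, 20.0), periodic=np.zeros(3, bool))
        _, terms, _ = energy_forces(st, topo, nb)
        assert terms["native"] == 0.0


class TestMinimize:
    def test_clashed_dimer_relaxes(self, rng):
        topo, _ = polyq_bead_topology(2, 4)
        nb = excluded_volume_tables(sigma_rep=0.35)
        pos = np.zeros((topo.n_beads, 3))
        for c in range(2):
            for r in range(4):
                bb = c * 8 + 2 * r
                pos[bb] = (0.36 * r, c * 0.12, 0.0)  # chains overlapping
                pos[bb + 1] = (0.36 * r, c * 0.12 + 0.25, 0.0)
        st = SystemState(positions=pos, velocities=pos * 0,
                         box=np.full(3, 10.0), periodic=np.zeros(3, bool))
        e0, _, _ = energy_forces(st, topo, nb)
        out = minimize(st, topo, nb, fmax=1000.0)
        ef, _, ff = energy_forces(out, topo, nb)
        assert out.converged
        assert np.abs(ff).max() < 1000.0
        assert ef < e0

    def test_already_minimized_returned_quickly(self, rng):
        topo, _ = polyq_bead_topology(1, 4)
        nb = excluded_volume_tables()
        st = chain_grid_state(topo, 1, 4, rng)
        st = minimize(st, topo, nb, fmax=100.0)
        again = minimize(st, topo, nb, fmax=100.0, max_steps=1)
        np.testing.assert_array_equal(st.positions, again.positions)

    def test_infinite_fmax_is_vacuous(self, rng):
        topo, _ = polyq_bead_topology(1, 4)
        nb = excluded_volume_tables()
        st = chain_grid_state(topo, 1, 4, rng)
        out = minimize(st, topo, nb, fmax=np.inf)
        np.testing.assert_array_equal(st.positions, out.positions)


class TestInitialization:
    def test_determinism_and_min_distance(self):
        topo, _ = polyq_bead_topology(12, 16)
        pool_rng = np.random.default_rng(0)
        pool = [
            np.cumsum(pool_rng.normal(scale=0.2, size=(32, 3)), axis=0)
            for _ in range(4)
        ]
        s1 = initialize_system(12, 0.01, pool, topo, seed=1)
        s2 = initialize_system(12, 0.01, pool, topo, seed=1)
        np.testing.assert_array_equal(s1.positions, s2.positions)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)
        # brute-force interchain min distance (minimum image)
        per = 32
        box = s1.box
        worst = np.inf
        for a in range(12):
            for b in range(a + 1, 12):
                d = s1.positions[a * per:(a + 1) * per, None, :] - \
                    s1.positions[None, b * per:(b + 1) * per, :]
                d -= box * np.rint(d / box)
                worst = min(worst, float(np.sqrt((d ** 2).sum(-1)).min()))
        assert worst >= 0.4

    def test_overdense_packing_fails(self):
        topo, _ = polyq_bead_topology(2, 16)
        pool = [np.zeros((32, 3)) + np.linspace(0, 5, 32)[:, None]]
        with pytest.raises(RuntimeError):
            initialize_system(2, 1.0, pool, topo, seed=0, max_attempts=5)


class TestDynamics:
    def test_kinetic_temperature(self, rng):
        """Time-averaged kinetic temperature within 3% of target."""
        topo, _ = polyq_bead_topology(4, 16)
        nb = excluded_volume_tables()
        st = chain_grid_state(topo, 4, 16, rng)
        st = minimize(st, topo, nb, fmax=100.0)
        for friction in (0.5, 1.0, 2.0):
            cfg = SimConfig(timestep=0.01, friction=friction, temperature=300,
                            seed=2, report_interval=100)
            res = run(st, topo, nb, cfg, 15000)
            mean_t = float(res.temperatures[30:].mean())
            assert abs(mean_t - 300.0) / 300.0 < 0.03

    def test_seed_determinism(self, rng):
        topo, _ = polyq_bead_topology(2, 8)
        nb = excluded_volume_tables()
        st = chain_grid_state(topo, 2, 8, rng)
        cfg = SimConfig(seed=7, report_interval=500)
        r1 = run(st, topo, nb, cfg, 2000)
        r2 = run(st, topo, nb, cfg, 2000)
        np.testing.assert_array_equal(r1.final_state.positions, r2.final_state.positions)

    def test_energy_conservation_at_zero_friction(self, rng):
        """Symplectic limit: total-energy drift below 0.01 kT per bead."""
        topo, _ = polyq_bead_topology(2, 8)
        nb = excluded_volume_tables()
        st = chain_grid_state(topo, 2, 8, rng)
        st = minimize(st, topo, nb, fmax=50.0)
        cfg = SimConfig(timestep=0.002, friction=0.0, seed=3, report_interval=1000)
        e0, _, _ = energy_forces(st, topo, nb)
        ke0 = 0.5 * float(np.sum(topo.masses[:, None] * st.velocities ** 2))
        res = run(st, topo, nb, cfg, 10000)
        ef, _, _ = energy_forces(res.final_state, topo, nb)
        kef = 0.5 * float(np.sum(topo.masses[:, None] * res.final_state.velocities ** 2))
        drift = abs((ef + kef) - (e0 + ke0)) / (topo.n_beads * KB * 300.0)
        assert drift < 0.01


class TestTwoChainBinding:
    """Engine-level analogue of aggregation vs non-aggregation."""

    def _dimer(self, potential, rng, seed):
        topo, template = polyq_bead_topology(2, 16)
        nb = compile_nonbonded(potential, topo)
        pos = np.zeros((topo.n_beads, 3))
        for c in range(2):
            for r in range(16):
                bb = c * 32 + 2 * r
                pos[bb] = (0.36 * r, 1.8 * c, 0.0)
                pos[bb + 1] = (0.36 * r, 1.8 * c + 0.25, 0.0)
        pos += rng.normal(scale=0.01, size=pos.shape)
        vel = rng.standard_normal(pos.shape) * np.sqrt(KB * 300 / topo.masses)[:, None]
        st = SystemState(positions=pos, velocities=vel, box=np.full(3, 4.5),
                         periodic=np.ones(3, dtype=bool))
        st = minimize(st, topo, nb, fmax=500.0)
        cfg = SimConfig(seed=seed, friction=0.1, report_interval=500)
        return run(st, topo, nb, cfg, 60000), topo, nb

    @staticmethod
    def _native_contact_fraction(positions, nb, box):
        if len(nb.native_pairs) == 0:
            return 0.0
        d = positions[nb.native_pairs[:, 0]] - positions[nb.native_pairs[:, 1]]
        d -= box * np.rint(d / box)
        r = np.sqrt((d ** 2).sum(1))
        return float((r < 1.2 * nb.native_sigma * 2 ** (1 / 6)).mean())

    def test_native_pair_binds_repulsive_pair_does_not(self, q16_potential, rng):
        res, topo, nb = self._dimer(q16_potential, rng, seed=11)
        mask = (
            topo.chain_of[nb.native_pairs[:, 0]]
            != topo.chain_of[nb.native_pairs[:, 1]]
        )
        nb_inter = NonbondedTables(
            native_pairs=nb.native_pairs[mask],
            native_eps=nb.native_eps[mask],
            native_sigma=nb.native_sigma[mask],
        )
        formed = max(
            self._native_contact_fraction(f, nb_inter, np.full(3, 4.5))
            for f in res.frames[len(res.frames) // 2:]
        )
        assert formed >= 0.5

        # all-repulsive variant: no interchain contact below sigma_rep at
        # equilibrium sampling
        import dataclasses

        rep_pot = dataclasses.replace(
            q16_potential,
            pairs=q16_potential.pairs[q16_potential.pairs.scope == "intra"],
        )
        res2, topo2, nb2 = self._dimer(rep_pot, rng, seed=12)
        per = 32
        min_d = []
        for f in res2.frames[len(res2.frames) // 2:]:
            d = f[:per, None, :] - f[None, per:, :]
            d -= 4.5 * np.rint(d / 4.5)
            min_d.append(np.sqrt((d ** 2).sum(-1)).min())
        # chains meet transiently but never interpenetrate the excluded volume
        assert min(min_d) > 0.7 * nb2.rep_sigma
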