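"""Physics checks of the coarse-grained Langevin simulator."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from synsplice import cg_sim, ensemble_analysis as ea
from synsplice.cg_sim import KB, SimProtocol


def toy_params(sigma=0.5, lam=0.0, charge=0.0, mass=100.0):
    """Uniform single-type parameter table for toy chains (poly-A)."""
    return pd.DataFrame({"sigma": [sigma], "lambda_": [lam],
                         "charge": [charge], "mass": [mass]}, index=["A"])


def harmonic_bond_msq(b, k, T):
    """⟨r²⟩ of a harmonic bond with radial measure, by quadrature."""
    beta = 1.0 / (KB * T)
    w = lambda r: r**2 * math.exp(-0.5 * beta * k * (r - b) ** 2)
    num = quad(lambda r: r**2 * w(r), 0, b + 10 / math.sqrt(beta * k))[0]
    den = quad(w, 0, b + 10 / math.sqrt(beta * k))[0]
    return num / den


class TestDebyeLength:
    def test_value_at_100mM_298K(self):
        assert cg_sim.debye_length(100.0, 298.0) == pytest.approx(0.96,
                                                                  abs=0.01)

    def test_square_root_law(self):
        assert cg_sim.debye_length(400.0, 298.0) == pytest.approx(
            cg_sim.debye_length(100.0, 298.0) / 2.0)

    def test_monotone_decreasing(self):
        ld = [cg_sim.debye_length(i, 310.0) for i in (10, 50, 150, 450)]
        assert all(a > b for a, b in zip(ld, ld[1:]))

    def test_zero_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            cg_sim.debye_length(0.0)


class TestPairEnergy:
    def test_zero_beyond_cutoffs_for_uncharged(self):
        assert cg_sim.pair_energy(2.5, 0.6, 0.5, 0.0, 0.6, 0.5, 0.0, 1.0) == 0.0

    def test_full_stickiness_is_truncated_shifted_lj(self):
        s, eps, rc = 0.6, cg_sim.EPS_AH, cg_sim.CUTOFF_AH
        for r in (0.55, 0.7, 1.2, 1.9):
            lj = 4 * eps * ((s / r) ** 12 - (s / r) ** 6)
            shift = 4 * eps * ((s / rc) ** 12 - (s / rc) ** 6)
            got = cg_sim.pair_energy(r, s, 1.0, 0.0, s, 1.0, 0.0, 1.0)
            assert got == pytest.approx(lj - shift, rel=1e-12)

    def test_hand_evaluated_ashbaugh_hatch(self):
        # r = sigma, mean stickiness 0.5: the LJ term vanishes, leaving
        # (1-lambda)*eps minus the lambda-scaled cutoff shift
        s, eps, rc = 0.6, cg_sim.EPS_AH, cg_sim.CUTOFF_AH
        expected = (1 - 0.5) * eps - 0.5 * 4 * eps * ((s / rc) ** 12
                                                      - (s / rc) ** 6)
        got = cg_sim.pair_energy(s, s, 0.2, 0.0, s, 0.8, 0.0, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_debye_huckel_term(self):
        r, ld, T = 1.0, 0.8, 310.0
        eps_r = cg_sim.water_dielectric(T)
        expected = (-1.0) * cg_sim._COULOMB / eps_r * math.exp(-r / ld) / r
        got = cg_sim.pair_energy(r, 0.4, 0.0, 1.0, 0.4, 0.0, -1.0, ld,
                                 eps=0.0, temperature_K=T)
        assert got == pytest.approx(expected, rel=1e-12)


class TestChainParameters:
    def test_his_fractional_charge(self):
        q = cg_sim.his_charge(7.4)
        assert 0.03 < q < 0.05

    def test_terminal_adjustments(self, variants):
        proto = SimProtocol()
        sig, lam, q, mass = cg_sim.chain_parameters(
            variants["FL"].sequence, proto)
        base = cg_sim.default_parameters()
        assert q[0] == pytest.approx(base.loc["M", "charge"] + 1.0)
        assert q[-1] == pytest.approx(base.loc["A", "charge"] - 1.0)
        assert mass[0] == pytest.approx(base.loc["M", "mass"] + 2.0)
        assert mass[-1] == pytest.approx(base.loc["A", "mass"] + 16.0)

    def test_net_charge_sign(self, variants):
        # the acidic C-terminal region makes full-length strongly negative;
        # removing exon 5 brings the net charge close to neutral
        proto = SimProtocol()
        q_fl = cg_sim.chain_parameters(variants["FL"].sequence, proto)[2].sum()
        q_d5 = cg_sim.chain_parameters(variants["d5"].sequence, proto)[2].sum()
        assert q_fl < -7
        assert abs(q_d5) < 2.5


class TestDynamics:
    def test_seed_determinism(self):
        proto = SimProtocol(ionic_strength_mM=150, production_ns=0.05,
                            equilibration_ps=10, frame_interval_ps=5)
        t1 = cg_sim.run_simulation("A" * 30, proto, toy_params(charge=0.2),
                                   seed=7)
        t2 = cg_sim.run_simulation("A" * 30, proto, toy_params(charge=0.2),
                                   seed=7)
        t3 = cg_sim.run_simulation("A" * 30, proto, toy_params(charge=0.2),
                                   seed=8)
        assert np.array_equal(t1.frames, t2.frames)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_kinetic_temperature(self):
        """Mean kinetic temperature equals the thermostat target within 2%.

        Friction is raised well above the production default so that
        successive frames carry independent kinetic-energy samples.
        """
        proto = SimProtocol(temperature_K=310.0, friction_ps=1.0,
                            production_ns=2.0, equilibration_ps=100,
                            frame_interval_ps=10, charges_on=False)
        traj = cg_sim.run_simulation("A" * 40, proto, toy_params(lam=0.5),
                                     seed=3)
        temps = [cg_sim.kinetic_temperature(v, traj.masses)
                 for v in traj.frame_velocities]
        assert np.mean(temps) == pytest.approx(310.0, rel=0.02)

    def test_ideal_chain_end_to_end(self):
        """With all nonbonded terms off, ⟨R_ee²⟩ matches the freely jointed
        closed form (N−1)·b_eff², with b_eff from the harmonic-bond
        equilibrium distribution."""
        n = 40
        proto = SimProtocol(production_ns=60.0, equilibration_ps=500,
                            frame_interval_ps=20, friction_ps=0.05,
                            eps_ah=0.0, charges_on=False)
        traj = cg_sim.run_simulation("A" * n, proto, toy_params(), seed=11)
        ree2 = ((traj.frames[:, -1] - traj.frames[:, 0]) ** 2).sum(1).mean()
        expected = (n - 1) * harmonic_bond_msq(proto.bond_length,
                                               proto.bond_k, 310.0)
        assert ree2 == pytest.approx(expected, rel=0.05)

    def test_repulsive_chain_is_swollen(self):
        """Purely repulsive beads (stickiness 0, no charges) behave like a
        self-avoiding walk: fitted Flory exponent in [0.55, 0.63]."""
        proto = SimProtocol(production_ns=12.0, equilibration_ps=500,
                            frame_interval_ps=20, charges_on=False)
        traj = cg_sim.run_simulation("A" * 60, proto, toy_params(lam=0.0),
                                     seed=13)
        nu, err, _ = ea.flory_exponent(traj.frames)
        assert 0.55 <= nu <= 0.63

    def test_energy_conservation_without_thermostat(self):
        """Zero friction at dt/10 is symplectic velocity Verlet: total energy
        drifts by <0.1% over 1e5 steps."""
        n = 20
        proto = SimProtocol(dt_ps=0.001, friction_ps=0.0,
                            production_ns=1e5 * 0.001 / 1000.0,
                            equilibration_ps=0.0, frame_interval_ps=1.0,
                            charges_on=False)
        traj = cg_sim.run_simulation("A" * n, proto, toy_params(lam=0.6),
                                     seed=5)
        energies = []
        for f, v in zip(traj.frames, traj.frame_velocities):
            ke = 0.5 * float(np.sum(traj.masses[:, None] * v**2))
            pe = cg_sim.potential_energy(f, "A" * n, proto, toy_params(lam=0.6))
            energies.append(ke + pe)
        energies = np.array(energies)
        scale = max(abs(energies.mean()), 1.5 * n * KB * 310.0)
        assert np.ptp(energies) / scale < 1e-3

    def test_bond_lengths_stay_near_equilibrium(self):
        proto = SimProtocol(production_ns=0.5, equilibration_ps=100,
                            frame_interval_ps=10, charges_on=False)
        traj = cg_sim.run_simulation("A" * 30, proto, toy_params(lam=0.3),
                                     seed=2)
        bonds = np.sqrt(((traj.frames[:, 1:] - traj.frames[:, :-1]) ** 2)
                        .sum(-1))
        sigma_bond = math.sqrt(KB * 310.0 / proto.bond_k)
        assert np.all(np.abs(bonds - proto.bond_length) < 5.5 * sigma_bond)


class TestTrajectoryIO:
    def test_xyz_round_trip(self, tmp_path):
        proto = SimProtocol(production_ns=0.02, equilibration_ps=5,
                            frame_interval_ps=5, charges_on=False)
        traj = cg_sim.run_simulation("ACDEFGHIKLMNPQRSTVWY", proto, seed=1)
        path = tmp_path / "traj.xyz"
        traj.to_xyz(path)
        back = cg_sim.Trajectory.from_xyz(path)
        assert back.sequence == traj.sequence
        assert np.allclose(back.frames, traj.frames, atol=1e-5)
        assert back.seed == traj.seed
        assert back.protocol.ionic_strength_mM == proto.ionic_strength_mM
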