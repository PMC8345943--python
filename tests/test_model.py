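import math

import numpy as np
import pytest

import dnatorsion as dt
from dnatorsion.model import AS_PRINTED, POTENTIAL_CONSISTENT
from dnatorsion.params import BaseParams, ParamTable


class TestParamTable:
    def test_default_pair_stiffness_seen_from_either_chain(self, table):
        assert table.k12_for("A") == table.k12_for("T") == 6.20e-2
        assert table.k12_for("G") == table.k12_for("C") == 9.60e-2

    def test_yaml_roundtrip(self, table, tmp_path):
        p = tmp_path / "params.yaml"
        table.to_yaml(p)
        back = ParamTable.from_yaml(p)
        for b in "ACGT":
            assert back[b] == table[b]
        assert back.k12 == table.k12

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            BaseParams(I=-1e-44, R=5e-10, K=2e-18, beta=1e-34)
        with pytest.raises(ValueError):
            BaseParams(I=1e-44, R=5e-10, K=2e-18, beta=-1e-34)
        # beta = 0 is the conservative limit and is allowed
        BaseParams(I=1e-44, R=5e-10, K=2e-18, beta=0.0)

    def test_incomplete_table_rejected(self, table):
        with pytest.raises(ValueError, match="missing bases"):
            ParamTable(bases={b: table[b] for b in "ACG"}, k12=dict(table.k12))


class TestBuildSystem:
    def test_coefficient_arrays_follow_base_identity(self, table):
        sys_ = dt.build_system(dt.NucleotideSequence("AG"), params=table)
        assert sys_.chain2.symbols == "TC"
        np.testing.assert_allclose(sys_.I1, [7.61e-44, 8.22e-44], rtol=0)
        np.testing.assert_allclose(sys_.I2, [4.86e-44, 4.11e-44], rtol=0)
        np.testing.assert_allclose(sys_.k12, [6.20e-2, 9.60e-2], rtol=0)
        np.testing.assert_allclose(sys_.R1, [5.80e-10, 5.70e-10], rtol=0)
        np.testing.assert_allclose(sys_.R2, [4.80e-10, 4.70e-10], rtol=0)

    def test_array_shapes_at_gene_scale(self, table):
        seq = dt.random_sequence(980, 0.5, 1)
        sys_ = dt.build_system(seq, params=table)
        for arr in (sys_.I1, sys_.I2, sys_.K1, sys_.K2, sys_.beta1, sys_.beta2, sys_.k12):
            assert arr.shape == (980,)

    def test_homopolymer_gives_constant_arrays(self, table):
        sys_ = dt.build_system(dt.NucleotideSequence("AAAA"), params=table)
        for arr in (sys_.I1, sys_.I2, sys_.K1, sys_.k12):
            assert np.ptp(arr) == 0.0

    def test_complement_build_swaps_chain_arrays(self, table):
        """Poly-A and poly-T duplexes are the same pairs seen from the other chain."""
        a = dt.build_system(dt.NucleotideSequence("A" * 6), params=table)
        t = dt.build_system(dt.NucleotideSequence("T" * 6), params=table)
        for x, y in [("I1", "I2"), ("R1", "R2"), ("K1", "K2"), ("beta1", "beta2")]:
            np.testing.assert_array_equal(getattr(a, x), getattr(t, y))
            np.testing.assert_array_equal(getattr(a, y), getattr(t, x))
        np.testing.assert_array_equal(a.k12, t.k12)

    def test_unknown_variant_rejected(self, table):
        with pytest.raises(ValueError):
            dt.build_system(dt.NucleotideSequence("ACGT"), params=table, variant="bogus")


class TestExternalTorque:
    def test_cosine_drive_at_zero_and_half_period(self):
        force = dt.ForceSpec(F0=0.5e-22, omega=2.0e9)
        assert dt.external_torque(0.0, 0.0, 1e-34, force) == 0.5e-22
        t_half = math.pi / force.omega
        assert dt.external_torque(t_half, 0.0, 1e-34, force) == pytest.approx(
            -0.5e-22, rel=1e-12
        )

    def test_pure_damping(self):
        force = dt.ForceSpec(F0=0.0, omega=0.0)
        assert dt.external_torque(0.0, 1.0, 4.25e-34, force) == -4.25e-34

    def test_omega_zero_is_constant_force(self):
        force = dt.ForceSpec(F0=2e-23, omega=0.0)
        for t in (0.0, 1e-9, 5e-9):
            assert dt.external_torque(t, 0.0, 1e-34, force) == 2e-23


class TestEquilibrium:
    def test_state_values(self):
        st = dt.equilibrium_state(3)
        np.testing.assert_array_equal(st.phi1, np.zeros(3))
        np.testing.assert_array_equal(st.phi2, np.full(3, np.pi))
        np.testing.assert_array_equal(st.v1, np.zeros(3))
        np.testing.assert_array_equal(st.v2, np.zeros(3))
        assert st.t == 0.0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            dt.equilibrium_state(0)

    @pytest.mark.parametrize("variant", [AS_PRINTED, POTENTIAL_CONSISTENT])
    def test_rhs_exactly_zero_without_drive(self, table, variant):
        sys_ = dt.build_system(dt.NucleotideSequence("ACGTAC"), params=table, variant=variant)
        d = dt.rhs(dt.equilibrium_state(6), sys_)
        assert np.all(d.dv1 == 0.0)
        assert np.all(d.dv2 == 0.0)

    @pytest.mark.parametrize("variant", [AS_PRINTED, POTENTIAL_CONSISTENT])
    def test_drive_alone_gives_f0_over_inertia(self, table, variant):
        force = dt.ForceSpec(F0=0.5e-22, omega=1e10)
        sys_ = dt.build_system(
            dt.NucleotideSequence("ACGT"), params=table, force=force, variant=variant
        )
        d = dt.rhs(dt.equilibrium_state(4), sys_)
        np.testing.assert_allclose(d.dv1, 0.5e-22 / sys_.I1, rtol=1e-15)
        np.testing.assert_allclose(d.dv2, 0.5e-22 / sys_.I2, rtol=1e-15)


class TestRhs:
    def test_single_pair_closed_form(self, table):
        """n=1 A·T pair: acceleration equals the closed-form torque / inertia."""
        sys_ = dt.build_system(dt.NucleotideSequence("A"), params=table)
        st = dt.State(0.0, np.array([0.1]), np.array([np.pi]), np.zeros(1), np.zeros(1))
        d = dt.rhs(st, sys_)
        k12, R1, R2, I1 = 6.20e-2, 5.80e-10, 4.80e-10, 7.61e-44
        expected = (
            -k12 * R1 * (R1 + R2) * math.sin(0.1) - k12 * R1 * R2 * math.sin(0.1 - math.pi)
        ) / I1
        assert d.dv1[0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("variant", [AS_PRINTED, POTENTIAL_CONSISTENT])
    def test_matches_independent_scalar_implementation(self, table, variant, scalar_rhs_oracle):
        rng = np.random.default_rng(42)
        seq = "GATTACAGC"
        n = len(seq)
        phi1 = rng.normal(0, 0.3, n)
        phi2 = np.pi + rng.normal(0, 0.3, n)
        v1 = rng.normal(0, 1e8, n)
        v2 = rng.normal(0, 1e8, n)
        force = dt.ForceSpec(F0=0.5e-22, omega=1e10)
        sys_ = dt.build_system(
            dt.NucleotideSequence(seq), params=table, force=force, variant=variant
        )
        t = 3.7e-12
        d = dt.rhs(dt.State(t, phi1, phi2, v1, v2), sys_)
        a1, a2 = scalar_rhs_oracle(seq, phi1, phi2, v1, v2, t=t, F0=0.5e-22, omega=1e10,
                                   variant=variant)
        np.testing.assert_allclose(d.dv1, a1, rtol=1e-10)
        np.testing.assert_allclose(d.dv2, a2, rtol=1e-10)

    def test_shape_mismatch_rejected(self, table):
        sys_ = dt.build_system(dt.NucleotideSequence("ACGT"), params=table)
        with pytest.raises(ValueError):
            dt.rhs(dt.equilibrium_state(3), sys_)

    def test_nonfinite_state_rejected(self, table):
        sys_ = dt.build_system(dt.NucleotideSequence("ACGT"), params=table)
        st = dt.equilibrium_state(4)
        st.phi1[2] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            dt.rhs(st, sys_)


class TestTotalEnergy:
    def test_equilibrium_energy_closed_form(self, undamped_table):
        """At (0, π) only the chain-2 on-site and cross pair terms contribute."""
        n = 5
        sys_ = dt.build_system(
            dt.NucleotideSequence("A" * n), params=undamped_table,
            variant=POTENTIAL_CONSISTENT,
        )
        e = dt.total_energy(dt.equilibrium_state(n), sys_)
        k12, R1, R2 = 6.20e-2, 5.80e-10, 4.80e-10
        expected = n * k12 * (R2 * (R1 + R2) * 2.0 + R1 * R2 * 2.0)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_rejected_for_printed_variant_and_heteropolymer(self, table):
        sys_ = dt.build_system(dt.NucleotideSequence("AAAA"), params=table, variant=AS_PRINTED)
        with pytest.raises(ValueError, match="potential_consistent"):
            dt.total_energy(dt.equilibrium_state(4), sys_)
        het = dt.build_system(
            dt.NucleotideSequence("ACGT"), params=table, variant=POTENTIAL_CONSISTENT
        )
        with pytest.raises(ValueError, match="homopolymer"):
            dt.total_energy(dt.equilibrium_state(4), het)

    def test_accelerations_equal_negative_energy_gradient(self, undamped_table):
        """Central finite differences of E reproduce the conservative torques."""
        n = 3
        sys_ = dt.build_system(
            dt.NucleotideSequence("A" * n), params=undamped_table,
            variant=POTENTIAL_CONSISTENT,
        )
        rng = np.random.default_rng(7)
        st = dt.State(
            0.0,
            rng.normal(0, 0.2, n),
            np.pi + rng.normal(0, 0.2, n),
            np.zeros(n),
            np.zeros(n),
        )
        d = dt.rhs(st, sys_)
        h = 1e-7

        def energy_at(phi1, phi2):
            return dt.total_energy(dt.State(0.0, phi1, phi2, np.zeros(n), np.zeros(n)), sys_)

        for i in range(n):
            for which, inertia, acc in (("phi1", sys_.I1, d.dv1), ("phi2", sys_.I2, d.dv2)):
                p1, p2 = st.phi1.copy(), st.phi2.copy()
                arr = p1 if which == "phi1" else p2
                arr[i] += h
                e_plus = energy_at(p1, p2)
                arr[i] -= 2 * h
                e_minus = energy_at(p1, p2)
                grad = (e_plus - e_minus) / (2 * h)
                assert acc[i] == pytest.approx(-grad / inertia[i], rel=1e-6, abs=1e-3)

    def test_zero_configuration_is_global_minimum(self, undamped_table):
        """Numerical minimization lands at the all-zero angles with E = 0."""
        from scipy.optimize import minimize

        n = 3
        sys_ = dt.build_system(
            dt.NucleotideSequence("A" * n), params=undamped_table,
            variant=POTENTIAL_CONSISTENT,
        )

        def e(x):
            return dt.total_energy(
                dt.State(0.0, x[:n], x[n:], np.zeros(n), np.zeros(n)), sys_
            )

        zero = np.zeros(2 * n)
        assert e(zero) == 0.0
        rng = np.random.default_rng(3)
        res = minimize(e, rng.normal(0, 0.5, 2 * n), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-30, "maxiter": 20000})
        assert res.fun >= -1e-25
        assert res.fun < 1e-22  # reaches (a copy of) the zero-energy floor

    def test_dissipation_makes_energy_nonincreasing(self, table):
        """With β > 0 and no drive, E(t) decreases along the trajectory."""
        n = 8
        sys_ = dt.build_system(
            dt.NucleotideSequence("A" * n), params=table, variant=POTENTIAL_CONSISTENT
        )
        idx = np.arange(n)
        st = dt.State(
            0.0,
            1e-2 * np.sin(np.pi * (idx + 0.5) / n),
            np.full(n, np.pi),
            np.zeros(n),
            np.zeros(n),
        )
        traj = dt.integrate(sys_, st, dt.IntegrationSettings(t_end=2e-11, record_stride=20))
        energies = np.array(
            [dt.total_energy(traj.state_at(k), sys_) for k in range(traj.n_records)]
        )
        assert np.all(np.diff(energies) <= 1e-12 * abs(energies[0]))
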