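"""Debye-Hueckel, Go and bonded terms: identities, oracles, kernel agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgdock import _kernels
from cgdock.energy import (
    COULOMB_KCAL,
    EnergyParams,
    build_pair_tables,
    debye_huckel_energy,
    debye_length,
    forces,
    go_energy,
    total_energy,
)
from cgdock.cg import coarse_grain
from cgdock.synthetic import helix_structure


def _point_beads(positions, charges):
    return np.asarray(positions, float), np.asarray(charges, float)


class TestDebyeHuckel:
    def test_debye_length_at_10mM(self):
        # lambda_D = 3.04 / sqrt(I); 10 mM gives the weak-screening regime
        assert debye_length(0.010) == pytest.approx(30.4)

    def test_zero_charges_zero_energy(self):
        p = EnergyParams()
        a = _point_beads([[0, 0, 0], [3, 0, 0]], [0, 0])
        b = _point_beads([[10, 0, 0]], [1])
        assert debye_huckel_energy(*a, *b, p) == 0.0

    def test_symmetry(self):
        p = EnergyParams()
        rng = np.random.default_rng(1)
        ca, qa = rng.uniform(-5, 5, (4, 3)), np.array([1, -1, 0, 1])
        cb, qb = rng.uniform(10, 15, (3, 3)), np.array([-1, 1, 1])
        assert debye_huckel_energy(ca, qa, cb, qb, p) == pytest.approx(
            debye_huckel_energy(cb, qb, ca, qa, p), rel=1e-12)

    def test_closed_form_value(self):
        # two +1 charges at r = lambda_D = 30.4 A in water: C/eps_r * e^-1 / r
        p = EnergyParams(epsilon_r=80.0, ionic_strength=0.010)
        a = _point_beads([[0, 0, 0]], [1])
        b = _point_beads([[30.4, 0, 0]], [1])
        expected = (COULOMB_KCAL / 80.0) * np.exp(-1.0) / 30.4
        assert debye_huckel_energy(*a, *b, p) == pytest.approx(expected, rel=1e-10)

    @given(st.floats(2.0, 80.0), st.floats(2.0, 80.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_magnitude_decays_with_distance(self, r1, r2):
        p = EnergyParams()
        rs, rl = sorted((r1, r2))
        if rl - rs < 1e-6:
            return
        u = lambda r: debye_huckel_energy(*_point_beads([[0, 0, 0]], [1]),
                                          *_point_beads([[r, 0, 0]], [-1]), p)
        assert abs(u(rs)) > abs(u(rl))
        assert abs(u(500.0)) < 1e-9

    def test_weaker_screening_strengthens_attraction(self):
        r = 12.0
        a = _point_beads([[0, 0, 0]], [1])
        b = _point_beads([[r, 0, 0]], [-1])
        u1 = debye_huckel_energy(*a, *b, EnergyParams(ionic_strength=0.010))
        u2 = debye_huckel_energy(*a, *b, EnergyParams(ionic_strength=0.010 / 4))  # doubles lambda_D
        assert abs(u1) < abs(u2)

    def test_coincident_charges_error(self):
        p = EnergyParams()
        a = _point_beads([[1, 2, 3]], [1])
        with pytest.raises(ValueError):
            debye_huckel_energy(*a, *a, p)


class TestGoEnergy:
    def test_native_is_minimum_value(self, patch_cg):
        _, _, system = patch_cg
        p = EnergyParams()
        assert go_energy(system, system.positions, p) == pytest.approx(
            -p.eps_go * len(system.contact_r0), rel=1e-12)

    def test_stretched_contact_closed_form(self):
        s = helix_structure("AAAAAAA")
        cg = coarse_grain(s)
        cg.contacts = np.array([[0, 12]])
        r0 = float(np.linalg.norm(cg.positions[0] - cg.positions[12]))
        cg.contact_r0 = np.array([r0])
        stretched = cg.positions.copy()
        d = stretched[12] - stretched[0]
        stretched[12] = stretched[0] + 2.0 * d    # r = 2 r0
        expected = 1.0 * (5.0 / 2.0**12 - 6.0 / 2.0**10)
        assert go_energy(cg, stretched) == pytest.approx(expected, rel=1e-12)

    def test_empty_contact_list(self):
        cg = coarse_grain(helix_structure("AAA"))
        assert go_energy(cg, cg.positions) == 0.0

    def test_native_stationary_point(self, patch_cg):
        # Go + bonded gradient vanishes at the native geometry
        _, _, system = patch_cg
        p = EnergyParams()
        f = forces(system, system.positions, p, terms=("bonded", "go"))
        assert np.abs(f).max() < 1e-6


class TestTotalEnergy:
    def test_breakdown_sums(self, patch_cg):
        _, _, system = patch_cg
        p = EnergyParams()
        eb = total_energy(system, system.positions, p)
        assert eb.total == pytest.approx(
            eb.bonded + eb.go + eb.repulsion + eb.electrostatic, rel=1e-9)

    def test_per_residue_sums_to_intermolecular(self, patch_cg):
        _, _, system = patch_cg
        eb = total_energy(system, system.positions, EnergyParams())
        assert sum(eb.per_residue.values()) == pytest.approx(eb.electrostatic, rel=1e-9, abs=1e-12)

    def test_cationic_residues_dominate_binding(self, patch_complex, patch_cg):
        # brute-force expectation: in the native pose the most favorable
        # peptide-side contributions belong to the lysines facing the patch
        _, _, system = patch_cg
        eb = total_energy(system, system.positions, EnergyParams())
        pep_contrib = {r: e for (mol, r), e in eb.per_residue.items() if mol == 1}
        best = sorted(pep_contrib, key=pep_contrib.get)[:len(patch_complex.peptide_charged)]
        assert set(best) == set(patch_complex.peptide_charged)
        assert all(pep_contrib[r] < 0 for r in best)


class TestKernelConsistency:
    def test_kernel_forces_match_numpy(self, patch_cg):
        _, _, system = patch_cg
        p = EnergyParams()
        tables = build_pair_tables(system, p)
        rng = np.random.default_rng(3)
        pos = system.positions + rng.normal(0, 0.3, system.positions.shape)
        fk = np.zeros_like(pos)
        active = np.empty(len(tables.rep_pairs), dtype=np.int64)
        na = _kernels._rebuild_rep_list(pos, tables.rep_pairs, 1e12, active)
        _kernels.compute_forces(
            pos, fk, tables.bonds, tables.bond_r0, tables.bond_k,
            tables.contacts, tables.contact_r0, p.eps_go, True,
            tables.rep_pairs, active, na, p.sigma_rep, p.eps_rep,
            tables.elec_pairs, tables.elec_coeff, p.debye_len,
            np.zeros(3), 1e9, 0.0)
        fn = forces(system, pos, p, tables)
        np.testing.assert_allclose(fk, fn, atol=1e-10)

    def test_forces_are_negative_gradient(self, patch_cg):
        # central finite difference on a random coordinate
        _, _, system = patch_cg
        p = EnergyParams()
        tables = build_pair_tables(system, p)
        rng = np.random.default_rng(5)
        pos = system.positions + rng.normal(0, 0.2, system.positions.shape)
        f = forces(system, pos, p, tables)
        h = 1e-6
        for bead, dim in [(0, 0), (37, 1), (system.n_beads - 1, 2)]:
            pp = pos.copy(); pp[bead, dim] += h
            pm = pos.copy(); pm[bead, dim] -= h
            up = total_energy(system, pp, p, tables).total
            um = total_energy(system, pm, p, tables).total
            assert f[bead, dim] == pytest.approx(-(up - um) / (2 * h), rel=1e-4, abs=1e-6)
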