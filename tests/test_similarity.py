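"""Interface-similarity statistic D, the (D1,D2) landscape and native-like calls."""

import numpy as np
import pytest

from cgdock.similarity import (
    DEFAULT_PEPTIDE_INTERFACE,
    DEFAULT_PROTEIN_INTERFACE,
    Landscape,
    ReferenceInterface,
    SimilarityResult,
    build_landscape,
    build_reference,
    compute_D,
    native_like_fraction,
    reference_from_cg,
    score_frames,
    tau_scan,
)
from cgdock.structures import AtomicStructure, StructureError
from cgdock.synthetic import build_cg_complex


def brute_force_D(frame, ip, jp, r0, split):
    """Independent double-loop oracle for D, D1, D2."""
    n_p, n_j = len(ip), len(jp)
    tot = tot1 = tot2 = 0.0
    for a in range(n_p):
        for b in range(n_j):
            r = np.sqrt(np.sum((frame[ip[a]] - frame[jp[b]]) ** 2))
            d = r - r0[a, b]
            tot += d
            if b < split:
                tot1 += d
            else:
                tot2 += d
    return (tot / (n_p * n_j), tot1 / (n_p * split), tot2 / (n_p * (n_j - split)))


def _mock_dimer():
    """Dimer with CB atoms at all default interface residue numbers."""
    rng = np.random.default_rng(0)
    records = []
    for c, r in DEFAULT_PROTEIN_INTERFACE:
        x = rng.uniform(0, 10, 3)
        records.append(("CA", "C", "ASP", r, c, *x))
        records.append(("CB", "C", "ASP", r, c, *(x + [1.5, 0, 0])))
    for p in DEFAULT_PEPTIDE_INTERFACE:
        x = rng.uniform(12, 20, 3)
        records.append(("CA", "C", "LYS", p + 15, "B", *x))
        records.append(("CB", "C", "LYS", p + 15, "B", *(x + [1.5, 0, 0])))
    return AtomicStructure.from_records(records)


class TestBuildReference:
    def test_default_lists_give_40_pairs(self):
        ref = build_reference(_mock_dimer())
        assert ref.r0.shape == (8, 5)
        assert ref.n_protein * ref.n_peptide == 40
        assert ref.split == 2    # {Lys6, Lys7} | {Lys9, Ile10, Lys11}

    def test_distances_match_hand_computation(self):
        dimer = _mock_dimer()
        ref = build_reference(dimer)
        a = dimer.atom_coord("A", 6, "CB")
        b = dimer.atom_coord("B", 21, "CB")
        assert ref.r0[0, 0] == pytest.approx(np.linalg.norm(a - b), rel=1e-12)

    def test_empty_peptide_list_errors(self):
        with pytest.raises((StructureError, ValueError)):
            ReferenceInterface(protein_ids=[("A", 6)], peptide_ids=[], r0=np.zeros((1, 0)))

    def test_missing_residue_errors(self):
        dimer = _mock_dimer()
        with pytest.raises(StructureError):
            build_reference(dimer, protein_residues=[("A", 999)])


class TestComputeD:
    def _toy(self):
        # reference: two protein beads, two peptide beads, all r0 = 4
        prot = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        y = np.sqrt(16 - 0.25)
        pep0 = np.array([[0.5, y, 0.0], [0.5, -y, 0.0]])
        ref = ReferenceInterface(protein_ids=[1, 2], peptide_ids=[1, 2],
                                 r0=np.full((2, 2), 4.0), split=1)
        return prot, pep0, ref

    def test_reference_pose_gives_zero(self):
        prot, pep, ref = self._toy()
        frame = np.vstack([prot, pep])
        d, d1, d2 = compute_D(frame, ref, (np.array([0, 1]), np.array([2, 3])))
        assert d == pytest.approx(0.0, abs=1e-12)
        assert d1 == pytest.approx(0.0, abs=1e-12)
        assert d2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_2x2(self):
        # distances {5,6} and {7,8} against r0 = 4 -> D = 2.5
        prot, _, ref = self._toy()
        j1 = np.array([-5.0, 0, 0])      # |j1|=5, |j1-(1,0,0)|=6
        j2 = np.array([-7.0, 0, 0])      # |j2|=7, |j2-(1,0,0)|=8
        frame = np.vstack([prot, [j1, j2]])
        d, d1, d2 = compute_D(frame, ref, (np.array([0, 1]), np.array([2, 3])))
        assert d == pytest.approx(2.5, rel=1e-12)
        assert d1 == pytest.approx((1 + 2) / 2, rel=1e-12)
        assert d2 == pytest.approx((3 + 4) / 2, rel=1e-12)

    def test_uniform_radial_inflation(self):
        # single protein bead: pushing every peptide bead radially out by
        # delta inflates every pair distance by exactly delta -> D = delta
        ref = ReferenceInterface(protein_ids=[1], peptide_ids=[1, 2, 3],
                                 r0=np.array([[5.0, 6.0, 7.0]]), split=1)
        dirs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        delta = 3.0
        frame = np.vstack([[0.0, 0, 0], dirs * (np.array([5.0, 6.0, 7.0]) + delta)[:, None]])
        d, _, _ = compute_D(frame, ref, (np.array([0]), np.array([1, 2, 3])))
        assert d == pytest.approx(delta, rel=1e-12)

    def test_matches_brute_force_on_random_frames(self, patch_complex, patch_cg):
        _, _, system = patch_cg
        ref = reference_from_cg(system, patch_complex.patch_residues,
                                patch_complex.peptide_charged)
        ip, jp = ref.indices_in(system)
        rng = np.random.default_rng(12)
        frames = system.positions[None] + rng.normal(0, 4.0, (100, system.n_beads, 3))
        res = score_frames(frames, ref, indices=(ip, jp))
        for k in range(100):
            d, d1, d2 = brute_force_D(frames[k], ip, jp, ref.r0, ref.split)
            assert res.D[k] == pytest.approx(d, rel=1e-10, abs=1e-12)
            assert res.D1[k] == pytest.approx(d1, rel=1e-10, abs=1e-12)
            assert res.D2[k] == pytest.approx(d2, rel=1e-10, abs=1e-12)

    def test_directionality_in_halves(self):
        # Reversing the peptide residue order must change the answer for an
        # asymmetric pose.  The aggregate D is a sum over all pairs and is
        # therefore permutation-invariant by construction; the direction
        # sensitivity lives in the half statistics D1/D2, whose group
        # membership follows the residue order.
        prot, _, ref = self._toy()
        frame = np.vstack([prot, [[-5.0, 0, 0], [9.0, 0, 0]]])
        fwd = compute_D(frame, ref, (np.array([0, 1]), np.array([2, 3])))
        rev = compute_D(frame, ref, (np.array([0, 1]), np.array([3, 2])))
        assert fwd[0] == pytest.approx(rev[0])            # D: invariant
        assert fwd[1] != pytest.approx(rev[1])            # D1: direction-sensitive
        assert fwd[2] != pytest.approx(rev[2])


class TestLandscape:
    def test_single_occupied_bin(self):
        res = SimilarityResult(D=np.ones(5), D1=np.ones(5), D2=np.ones(5), split=2)
        ls = build_landscape(res, kT=0.5, bins=4, extent=[[0, 2], [0, 2]])
        occupied = ~np.isnan(ls.free_energy)
        assert occupied.sum() == 1
        assert ls.free_energy[occupied][0] == 0.0

    def test_tied_bins_both_zero(self):
        d1 = np.array([0.25, 0.25, 1.75, 1.75])
        res = SimilarityResult(D=d1, D1=d1, D2=np.full(4, 0.5), split=2)
        ls = build_landscape(res, kT=0.7, bins=2, extent=[[0, 2], [0, 2]])
        vals = ls.free_energy[~np.isnan(ls.free_energy)]
        assert np.allclose(vals, 0.0)

    def test_counts_421_closed_form(self):
        kT = 0.5
        d1 = np.array([0.1] * 4 + [1.1] * 2 + [2.1])
        res = SimilarityResult(D=d1, D1=d1, D2=np.full(7, 0.5), split=2)
        ls = build_landscape(res, kT=kT, bins=3, extent=[[0, 3], [0, 3]])
        vals = sorted(ls.free_energy[~np.isnan(ls.free_energy)])
        assert vals[0] == pytest.approx(0.0)
        assert vals[1] == pytest.approx(kT * np.log(2))
        assert vals[2] == pytest.approx(kT * np.log(4))

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(4)
        d1, d2 = rng.uniform(0, 5, 200), rng.uniform(0, 5, 200)
        mk = lambda a, b: SimilarityResult(D=(a + b) / 2, D1=a, D2=b, split=2)
        ext = [[0, 5], [0, 5]]
        base = build_landscape(mk(d1, d2), bins=10, extent=ext)
        perm = rng.permutation(200)
        shuffled = build_landscape(mk(d1[perm], d2[perm]), bins=10, extent=ext)
        doubled = build_landscape(mk(np.tile(d1, 2), np.tile(d2, 2)), bins=10, extent=ext)
        np.testing.assert_allclose(base.free_energy, shuffled.free_energy)
        np.testing.assert_allclose(base.free_energy, doubled.free_energy)

    def test_zero_frames_errors(self):
        res = SimilarityResult(D=np.zeros(0), D1=np.zeros(0), D2=np.zeros(0), split=2)
        with pytest.raises(ValueError):
            build_landscape(res)


class TestNativeLikeFraction:
    def test_all_reference_frames(self):
        res = SimilarityResult(D=np.zeros(6), D1=np.zeros(6), D2=np.zeros(6), split=2)
        assert native_like_fraction(res, 0.1) == 1.0

    def test_none_below_threshold(self):
        res = SimilarityResult(D=np.full(6, 9.0), D1=np.full(6, 9.0), D2=np.full(6, 9.0), split=2)
        assert native_like_fraction(res, 3.0) == 0.0

    def test_mixture_3_of_10(self):
        d = np.array([1.0] * 3 + [8.0] * 7)
        res = SimilarityResult(D=d, D1=d, D2=d, split=2)
        assert native_like_fraction(res, 3.0) == pytest.approx(0.3)

    def test_overlap_guard_rejects_compressed_poses(self):
        d = np.array([-9.0, 0.5])
        res = SimilarityResult(D=d, D1=d, D2=d, split=2)
        assert native_like_fraction(res, 3.0) == pytest.approx(0.5)

    def test_invalid_threshold(self):
        res = SimilarityResult(D=np.zeros(1), D1=np.zeros(1), D2=np.zeros(1), split=2)
        with pytest.raises(ValueError):
            native_like_fraction(res, -1.0)

    def test_tau_scan_monotone(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0, 10, 500)
        res = SimilarityResult(D=d, D1=d, D2=d + rng.uniform(0, 1, 500), split=2)
        table = tau_scan(res)
        fr = table["native_like_fraction"].to_numpy()
        assert (np.diff(fr) >= 0).all()
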