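"""Docking protocol bookkeeping, placements, Langevin sampling diagnostics."""

import numpy as np
import pytest

from cgdock.docking import (
    DockingProtocol,
    generate_start_positions,
    peptide_centers,
    run_campaign,
    run_replica,
    _fibonacci_directions,
)
from cgdock.energy import EnergyParams, build_pair_tables


class TestProtocol:
    def test_default_bookkeeping(self):
        p = DockingProtocol()
        assert p.n_start_positions == 10
        assert p.replicas_per_position == 10
        assert p.steps_per_replica == 10_000_000
        assert p.save_stride == 1000
        assert p.frames_kept_per_replica == 2000
        assert p.n_replicas == 100
        assert p.planned_kept_frames == 200_000

    def test_scaled_arithmetic(self):
        p = DockingProtocol().scaled(n_start_positions=2, replicas_per_position=2,
                                     steps_per_replica=100_000,
                                     frames_kept_per_replica=50)
        assert p.planned_kept_frames == 200

    def test_kept_frames_cannot_exceed_saves(self):
        with pytest.raises(ValueError):
            DockingProtocol(steps_per_replica=10_000, save_stride=1000,
                            frames_kept_per_replica=11)

    def test_placement_distance_positive(self):
        with pytest.raises(ValueError):
            DockingProtocol(placement_distance=-1.0)


def _surface_center_distance(rec_cg, placement):
    center = placement.mean(axis=0)
    return np.linalg.norm(rec_cg.positions - center, axis=1).min()


class TestPlacements:
    def test_default_ten_placements_at_35(self, patch_cg):
        rec, pep, _ = patch_cg
        protocol = DockingProtocol(seed=5)
        placements = generate_start_positions(rec, pep, protocol)
        assert len(placements) == 10
        for p in placements:
            assert 34.0 <= _surface_center_distance(rec, p) <= 36.0

    def test_seed_determinism(self, patch_cg):
        rec, pep, _ = patch_cg
        protocol = DockingProtocol(seed=5)
        a = generate_start_positions(rec, pep, protocol, np.random.default_rng(9))
        b = generate_start_positions(rec, pep, protocol, np.random.default_rng(9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_single_position(self, patch_cg):
        rec, pep, _ = patch_cg
        placements = generate_start_positions(rec, pep, DockingProtocol(n_start_positions=1))
        assert len(placements) == 1

    def test_directions_well_spread(self, patch_cg):
        # pairwise angular separation of the spiral directions stays large
        dirs = _fibonacci_directions(10)
        cosmax = max(float(dirs[i] @ dirs[j])
                     for i in range(10) for j in range(i + 1, 10))
        assert cosmax < 0.85

    def test_peptide_larger_than_shell_errors(self, patch_cg):
        rec, pep, _ = patch_cg
        with pytest.raises(ValueError):
            generate_start_positions(rec, pep, DockingProtocol(placement_distance=5.0))


class TestReplica:
    def test_zero_step_run_empty(self, patch_cg):
        rec, pep, system = patch_cg
        protocol = DockingProtocol(steps_per_replica=0, frames_kept_per_replica=0,
                                   placement_distance=25.0)
        placement = generate_start_positions(rec, pep, protocol)[0]
        traj, ke, diag = run_replica(system, placement, protocol, seed=1)
        assert traj.n_frames == 0

    def test_replica_seed_determinism(self, patch_cg):
        rec, pep, system = patch_cg
        protocol = DockingProtocol(n_start_positions=1, steps_per_replica=20_000,
                                   save_stride=1000, frames_kept_per_replica=10,
                                   placement_distance=25.0)
        placement = generate_start_positions(rec, pep, protocol,
                                             np.random.default_rng(3))
        t1, _, _ = run_replica(system, placement[0], protocol, seed=77)
        t2, _, _ = run_replica(system, placement[0], protocol, seed=77)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        t3, _, _ = run_replica(system, placement[0], protocol, seed=78)
        assert not np.allclose(t1.coords, t3.coords)

    def test_placement_roster_mismatch(self, patch_cg):
        _, _, system = patch_cg
        with pytest.raises(ValueError):
            run_replica(system, np.zeros((3, 3)), DockingProtocol(), seed=1)


class TestCampaign:
    def test_kept_frame_counts(self, short_campaign):
        result, protocol = short_campaign
        assert result.n_kept == protocol.planned_kept_frames
        for t in result.trajectories:
            assert t.n_frames == protocol.frames_kept_per_replica

    def test_campaign_determinism(self, patch_cg):
        rec, pep, _ = patch_cg
        protocol = DockingProtocol(n_start_positions=1, replicas_per_position=2,
                                   steps_per_replica=20_000, save_stride=1000,
                                   frames_kept_per_replica=10,
                                   placement_distance=25.0, seed=13)
        r1 = run_campaign(rec, pep, protocol)
        r2 = run_campaign(rec, pep, protocol)
        np.testing.assert_array_equal(r1.kept_frames, r2.kept_frames)

    def test_thermostat_within_5_percent(self, short_campaign, patch_cg):
        _, _, system = patch_cg
        result, protocol = short_campaign
        ke = np.concatenate(result.kinetic)
        per_dof = ke.mean() / (3 * system.n_beads)
        assert per_dof == pytest.approx(protocol.temperature / 2, rel=0.05)

    def test_molecules_stay_folded(self, short_campaign):
        result, protocol = short_campaign
        for diag in result.flags:
            assert not diag["unfolded"]
            assert diag["rmsd_receptor"] < protocol.unfold_rmsd_guard

    def test_energies_finite(self, patch_cg):
        rec, pep, _ = patch_cg
        protocol = DockingProtocol(n_start_positions=1, replicas_per_position=1,
                                   steps_per_replica=10_000, save_stride=1000,
                                   frames_kept_per_replica=5,
                                   placement_distance=25.0, seed=2)
        result = run_campaign(rec, pep, protocol, compute_energies=True)
        assert np.isfinite(result.energies[0]).all()


class TestSamplingBehavior:
    def test_attraction_pulls_peptide_inward(self, patch_cg):
        # majority of replicas end nearer the patch than they started
        from cgdock.docking import _replica_seed
        rec, pep, system = patch_cg
        protocol = DockingProtocol(n_start_positions=5, replicas_per_position=1,
                                   steps_per_replica=100_000, save_stride=1000,
                                   frames_kept_per_replica=10,
                                   placement_distance=25.0, wall_radius_factor=1.6,
                                   seed=21)
        placements = generate_start_positions(rec, pep, protocol,
                                              np.random.default_rng(21))
        rec_centroid = rec.positions.mean(axis=0)
        closer = 0
        for k, pl in enumerate(placements):
            traj, _, _ = run_replica(system, pl, protocol, seed=1000 + k)
            start = np.linalg.norm(pl.mean(axis=0) - rec_centroid)
            end = np.linalg.norm(peptide_centers(system, traj.coords[-1:])[0] - rec_centroid)
            closer += end < start
        assert closer >= 3

    def test_high_temperature_removes_enrichment(self, patch_complex, patch_cg):
        # at kT well above the electrostatic binding strength per pair the
        # peptide's direction around the receptor approaches the uniform
        # solid-angle null instead of concentrating toward the patch
        rec, pep, system = patch_cg
        hot = DockingProtocol(n_start_positions=4, replicas_per_position=1,
                              steps_per_replica=100_000, save_stride=1000,
                              frames_kept_per_replica=50, placement_distance=25.0,
                              wall_radius_factor=1.6, temperature=2.5,
                              timestep=0.005, seed=33)
        result = run_campaign(rec, pep, hot)
        rec_centroid = rec.positions.mean(axis=0)
        u_patch = patch_complex.patch_centroid - rec_centroid
        u_patch = u_patch / np.linalg.norm(u_patch)
        centers = peptide_centers(system, result.kept_frames)
        v = centers - rec_centroid
        cosang = (v @ u_patch) / np.linalg.norm(v, axis=1)
        in_cone = (cosang > np.cos(np.deg2rad(45.0))).mean()
        null = 0.5 * (1.0 - np.cos(np.deg2rad(45.0)))   # cone solid-angle fraction
        assert in_cone < null + 0.25
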