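"""Langevin docking campaigns: dispersed placements, replicas, frame retention.

The default protocol mirrors the published sampling recipe: the unbound
peptide is placed at 10 positions distributed around the receptor, about
35 A from the protein surface (surface-to-peptide-center), 10 replicas are
run per position for 1e7 steps each, coordinates are saved every 1000 steps
and only the last 2000 saved conformations per replica are analysed —
2 x 10^5 kept conformations in total.

Both molecules stay flexible under their Go + bonded terms and fluctuate
around their native states at a low reduced temperature; a soft spherical
wall (radius 2x the placement distance) keeps the peptide from escaping to
infinity so that finite campaigns converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cgdock.cg import CGSystem, combine
from cgdock.energy import EnergyParams, PairTables, build_pair_tables, total_energy
from cgdock.structures import Trajectory
from cgdock import _kernels


@dataclass
class DockingProtocol:
    """Sampling configuration; defaults are the published campaign."""

    n_start_positions: int = 10
    replicas_per_position: int = 10
    steps_per_replica: int = 10_000_000
    save_stride: int = 1000
    frames_kept_per_replica: int = 2000
    placement_distance: float = 35.0     # A, receptor surface to peptide center
    temperature: float = 0.5             # kT / eps_go; "relatively low"
    timestep: float = 0.01               # reduced, bond-stiffness limited
    friction: float = 0.2                # Langevin gamma, reduced (low: faster search)
    wall_radius_factor: float = 2.0      # confining wall at factor * placement distance
    wall_k: float = 5.0
    unfold_rmsd_guard: float = 5.0       # A; replicas drifting beyond are flagged
    seed: int = 0

    def __post_init__(self):
        if self.placement_distance <= 0:
            raise ValueError("placement distance must be positive")
        if self.frames_kept_per_replica > self.steps_per_replica // self.save_stride:
            raise ValueError("frames_kept_per_replica exceeds saved frames")

    @property
    def n_replicas(self) -> int:
        return self.n_start_positions * self.replicas_per_position

    @property
    def planned_kept_frames(self) -> int:
        return self.n_replicas * self.frames_kept_per_replica

    def scaled(self, **overrides) -> "DockingProtocol":
        return replace(self, **overrides)


@dataclass
class DockingResult:
    """Kept frames, energies and provenance of one campaign."""

    trajectories: list                    # Trajectory per replica, campaign order
    energies: list                        # per-replica array of per-frame total energies
    kinetic: list                         # per-replica array of per-frame kinetic energies
    flags: list                           # per-replica diagnostics dicts
    protocol: DockingProtocol
    provenance: dict = field(default_factory=dict)

    @property
    def kept_frames(self) -> np.ndarray:
        return np.concatenate([t.coords for t in self.trajectories if t.n_frames], axis=0)

    @property
    def n_kept(self) -> int:
        return sum(t.n_frames for t in self.trajectories)


class ReplicaFailure(RuntimeError):
    pass


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic spiral-on-sphere unit vectors (max pairwise separation)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def generate_start_positions(receptor_cg: CGSystem, peptide_cg: CGSystem,
                             protocol: DockingProtocol,
                             rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Peptide coordinate sets dispersed around the receptor.

    Directions follow a deterministic Fibonacci spiral, rigidly rotated by
    the rng so repeated campaigns sample different orientations while the
    pairwise angular spread stays near-maximal.  Along each direction the
    peptide center is positioned so that the distance from the nearest
    receptor bead to the peptide geometric center equals the protocol's
    placement distance; the peptide orientation is random.
    """
    rng = rng or np.random.default_rng(protocol.seed)
    pep = peptide_cg.positions - peptide_cg.positions.mean(axis=0)
    pep_radius = float(np.linalg.norm(pep, axis=1).max())
    if pep_radius >= protocol.placement_distance:
        raise ValueError("peptide larger than the placement shell")
    rec = receptor_cg.positions
    centroid = rec.mean(axis=0)
    dirs = _fibonacci_directions(protocol.n_start_positions) @ _random_rotation(rng).T

    placements = []
    for u in dirs:
        # bisection on t: min-bead distance grows monotonically past the surface
        lo, hi = 0.0, protocol.placement_distance + float(np.linalg.norm(rec - centroid, axis=1).max()) + 10.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            d = np.linalg.norm(rec - (centroid + mid * u), axis=1).min()
            if d < protocol.placement_distance:
                lo = mid
            else:
                hi = mid
        center = centroid + 0.5 * (lo + hi) * u
        placements.append(pep @ _random_rotation(rng).T + center)
    return placements


def _replica_seed(master_seed: int, pos_idx: int, rep_idx: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(pos_idx), int(rep_idx)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return float(np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1))))


def run_replica(system: CGSystem, placement: np.ndarray, protocol: DockingProtocol,
                seed: int, params: EnergyParams | None = None,
                tables: PairTables | None = None) -> tuple[Trajectory, np.ndarray, dict]:
    """One Langevin trajectory from a placed start; returns kept frames.

    The returned kinetic-energy series and internal-RMSD guard flags are in
    the diagnostics dict.  Numerical blow-up raises :class:`ReplicaFailure`.
    """
    params = params or EnergyParams(temperature=protocol.temperature)
    tables = tables if tables is not None else build_pair_tables(system, params)
    pep = system.molecule_slice(1)
    if len(pep) != len(placement):
        raise ValueError("placement does not match peptide roster")
    pos = system.positions.copy()
    pos[pep] = placement
    vel = np.random.default_rng(seed).normal(0.0, np.sqrt(protocol.temperature), pos.shape)

    n_keep = min(protocol.frames_kept_per_replica,
                 protocol.steps_per_replica // protocol.save_stride) if protocol.steps_per_replica else 0
    frames = np.zeros((n_keep, system.n_beads, 3))
    ke = np.zeros(n_keep)
    if protocol.steps_per_replica:
        rec_centroid = system.positions[system.molecule_slice(0)].mean(axis=0)
        status = _kernels.integrate_baoab(
            pos, vel, protocol.steps_per_replica, protocol.save_stride, n_keep,
            protocol.timestep, protocol.friction, protocol.temperature, seed,
            tables.bonds, tables.bond_r0, tables.bond_k,
            tables.contacts, tables.contact_r0, params.eps_go, params.lj_form == "12-10",
            tables.rep_pairs, params.sigma_rep, params.eps_rep,
            tables.elec_pairs, tables.elec_coeff, params.debye_len,
            rec_centroid, protocol.wall_radius_factor * protocol.placement_distance,
            protocol.wall_k, frames, ke)
        if status != 0:
            raise ReplicaFailure(f"non-finite coordinates (seed {seed})")

    diag = {"seed": seed, "kinetic": ke, "unfolded": False}
    if n_keep:
        last = frames[-1]
        rmsd_rec = _kabsch_rmsd(last[system.molecule_slice(0)], system.positions[system.molecule_slice(0)])
        rmsd_pep = _kabsch_rmsd(last[pep], system.positions[pep])
        diag["rmsd_receptor"] = rmsd_rec
        diag["rmsd_peptide"] = rmsd_pep
        diag["unfolded"] = max(rmsd_rec, rmsd_pep) > protocol.unfold_rmsd_guard
    return Trajectory(frames, stride=protocol.save_stride), ke, diag


def run_campaign(receptor_cg: CGSystem, peptide_cg: CGSystem, protocol: DockingProtocol,
                 params: EnergyParams | None = None,
                 compute_energies: bool = False) -> DockingResult:
    """Full campaign: every placement x replica, deterministic per-replica seeds.

    Replica RNG streams derive from (protocol.seed, position, replica), so
    results are independent of execution order.  Failed replicas are logged
    and skipped; the campaign continues.
    """
    params = params or EnergyParams(temperature=protocol.temperature)
    system = combine(receptor_cg, peptide_cg)
    tables = build_pair_tables(system, params)
    placements = generate_start_positions(
        receptor_cg, peptide_cg, protocol,
        np.random.default_rng(np.random.SeedSequence([protocol.seed, 0xD0C])))

    trajectories, energies, kinetic, flags = [], [], [], []
    for p_idx, placement in enumerate(placements):
        for r_idx in range(protocol.replicas_per_position):
            seed = _replica_seed(protocol.seed, p_idx, r_idx)
            try:
                traj, ke, diag = run_replica(system, placement, protocol, seed, params, tables)
            except ReplicaFailure as exc:
                flags.append({"position": p_idx, "replica": r_idx, "failed": str(exc)})
                continue
            diag.update({"position": p_idx, "replica": r_idx})
            trajectories.append(traj)
            kinetic.append(ke)
            flags.append(diag)
            if compute_energies:
                energies.append(np.array([total_energy(system, f, params, tables).total
                                          for f in traj.coords]))
            else:
                energies.append(np.zeros(0))
    return DockingResult(
        trajectories=trajectories, energies=energies, kinetic=kinetic, flags=flags,
        protocol=protocol,
        provenance={"seed": protocol.seed, "n_beads": system.n_beads,
                    "n_replicas": protocol.n_replicas},
    )


def peptide_centers(system_or_peptide_cg: CGSystem, frames: np.ndarray,
                    mol_id: int = 1) -> np.ndarray:
    """Geometric center of the peptide beads in each frame."""
    idx = system_or_peptide_cg.molecule_slice(mol_id)
    if len(idx) == 0:   # single-molecule system: use everything
        idx = np.arange(frames.shape[1])
    return frames[:, idx, :].mean(axis=1)
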