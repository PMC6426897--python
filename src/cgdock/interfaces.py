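"""Interface characterisation: buried SASA, residue charge classes, probe grids.

Solvent-accessible surface areas use an internal Shrake-Rupley rollout
(deterministic golden-spiral sphere points, NACCESS-style united-atom radii,
1.4 A water probe).  Buried area on complexation is

    buried_total = SASA(A) + SASA(B) - SASA(AB)
    buried_side  = SASA(part alone) - SASA(part within the complex)

The probe-occupancy stage mirrors benzene-mapping post-processing: probe
atoms from an aligned trajectory are binned into 1 A^3 cells, the bulk
threshold is the highest count seen far from the receptor, and hotspot
cells exceed a multiple (default 5x) of that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from cgdock.structures import AtomicStructure, ChainSelection, StructureError, extract_selection
from cgdock.structures import Trajectory

# united-atom style van der Waals radii (A), keyed by element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}
PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960

NEGATIVE_RES = {"ASP", "GLU"}
POSITIVE_RES = {"LYS", "ARG", "HIS"}
HYDROPHOBIC_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}


def residue_charge_class(resname: str) -> str:
    if resname in NEGATIVE_RES:
        return "negative"
    if resname in POSITIVE_RES:
        return "positive"
    if resname in HYDROPHOBIC_RES:
        return "hydrophobic"
    return "other"


def _sphere_points(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def sasa(struct: AtomicStructure, probe_radius: float = PROBE_RADIUS,
         n_points: int = DEFAULT_N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    Deterministic for a fixed sphere-point count.  Raises on elements with
    no tabulated radius.
    """
    if struct.n_atoms == 0:
        return np.zeros(0)
    radii = np.empty(struct.n_atoms)
    for i, el in enumerate(struct.elements):
        el = str(el).upper()
        if el not in VDW_RADII:
            raise StructureError(f"no radius for element {el!r}")
        radii[i] = VDW_RADII[el]
    ext = radii + probe_radius
    pts = _sphere_points(n_points)
    tree = cKDTree(struct.coords)
    out = np.zeros(struct.n_atoms)
    max_ext = ext.max()
    for i in range(struct.n_atoms):
        surface = struct.coords[i] + ext[i] * pts
        neighbors = [j for j in tree.query_ball_point(struct.coords[i], ext[i] + max_ext) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((surface - struct.coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        out[i] = accessible.mean() * 4.0 * np.pi * ext[i] ** 2
    return out


def _per_residue(struct: AtomicStructure, atom_areas: np.ndarray) -> dict:
    acc: dict[tuple[str, int], float] = {}
    for (c, r), a in zip(zip(struct.chains, struct.resnums), atom_areas):
        key = (str(c), int(r))
        acc[key] = acc.get(key, 0.0) + float(a)
    return acc


@dataclass
class InterfaceReport:
    """Buried areas and interface residue classification for a two-part complex."""

    buried_a: float                  # A^2, side A: SASA(alone) - SASA(in complex)
    buried_b: float
    interface_residues_a: list       # (chain, resnum, resname, class, buried A^2)
    interface_residues_b: list
    per_residue_buried_a: dict = field(default_factory=dict)
    per_residue_buried_b: dict = field(default_factory=dict)

    @property
    def buried_total(self) -> float:
        return self.buried_a + self.buried_b

    @property
    def buried_per_side_mean(self) -> float:
        return 0.5 * self.buried_total


def _concat(a: AtomicStructure, b: AtomicStructure) -> AtomicStructure:
    return AtomicStructure(
        names=np.concatenate([a.names, b.names]),
        elements=np.concatenate([a.elements, b.elements]),
        resnames=np.concatenate([a.resnames, b.resnames]),
        resnums=np.concatenate([a.resnums, b.resnums]),
        chains=np.concatenate([a.chains, b.chains]),
        coords=np.vstack([a.coords, b.coords]),
    )


def buried_area(complex_struct: AtomicStructure,
                part_a: ChainSelection | AtomicStructure,
                part_b: ChainSelection | AtomicStructure,
                probe_radius: float = PROBE_RADIUS,
                n_points: int = DEFAULT_N_SPHERE_POINTS,
                min_buried: float = 0.1) -> InterfaceReport:
    """Buried-area report for the interface between two parts of a complex.

    Interface residues are those burying more than ``min_buried`` A^2;
    each carries a charge class (D/E negative, K/R/H positive,
    A/V/L/I/M/F/W/P hydrophobic, else other).
    """
    sa = part_a if isinstance(part_a, AtomicStructure) else extract_selection(complex_struct, part_a)
    sb = part_b if isinstance(part_b, AtomicStructure) else extract_selection(complex_struct, part_b)
    keys_a = {(str(c), int(r)) for c, r in zip(sa.chains, sa.resnums)}
    keys_b = {(str(c), int(r)) for c, r in zip(sb.chains, sb.resnums)}
    if keys_a & keys_b:
        raise StructureError("overlapping part selections")

    both = _concat(sa, sb)
    area_ab = sasa(both, probe_radius, n_points)
    area_a_alone = sasa(sa, probe_radius, n_points)
    area_b_alone = sasa(sb, probe_radius, n_points)
    na = sa.n_atoms
    res_alone_a = _per_residue(sa, area_a_alone)
    res_alone_b = _per_residue(sb, area_b_alone)
    res_cplx_a = _per_residue(sa, area_ab[:na])
    res_cplx_b = _per_residue(sb, area_ab[na:])

    def side(struct, alone, cplx):
        buried = {k: alone[k] - cplx[k] for k in alone}
        rows = []
        for (c, r) in struct.residues():
            b = buried[(c, r)]
            if b > min_buried:
                name = struct.residue_name(c, r)
                rows.append((c, r, name, residue_charge_class(name), b))
        return sum(buried.values()), rows, buried

    ba, rows_a, all_a = side(sa, res_alone_a, res_cplx_a)
    bb, rows_b, all_b = side(sb, res_alone_b, res_cplx_b)
    return InterfaceReport(buried_a=ba, buried_b=bb,
                           interface_residues_a=rows_a, interface_residues_b=rows_b,
                           per_residue_buried_a=all_a, per_residue_buried_b=all_b)


@dataclass
class OccupancyGrid:
    """Probe-atom counts on a regular 3D grid (default 1 A cells)."""

    origin: np.ndarray
    cell_size: float
    counts: np.ndarray               # (nx, ny, nz) int
    n_frames: int
    bulk_threshold: float | None = None

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def cell_centers(self, cells: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(cells) + 0.5) * self.cell_size

    def to_opendx(self, path) -> None:
        """OpenDX volumetric export for visualisation tools."""
        nx, ny, nz = self.counts.shape
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {self.origin[0]:.3f} {self.origin[1]:.3f} {self.origin[2]:.3f}\n")
            fh.write(f"delta {self.cell_size:.3f} 0 0\ndelta 0 {self.cell_size:.3f} 0\n")
            fh.write(f"delta 0 0 {self.cell_size:.3f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
            flat = self.counts.ravel(order="C").astype(float)
            for k in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.1f}" for v in flat[k:k + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\nobject "density" class field\n')


def occupancy_grid(traj: Trajectory, probe_atoms: np.ndarray,
                   cell_size: float = 1.0, padding: float = 1.0,
                   origin=None) -> OccupancyGrid:
    """Bin selected probe atoms of every frame into cubic cells.

    The trajectory must already be aligned to a common receptor frame (the
    alignment is the caller's responsibility and is recorded as metadata).
    Grid bounds cover all probe positions, so total counts equal
    probes x frames.  Pass an explicit ``origin`` to pin the cell lattice
    (e.g. to align with an external map); by default the grid is placed
    around the data with ``padding``.
    """
    probe_atoms = np.asarray(probe_atoms, dtype=int)
    if probe_atoms.size == 0:
        raise StructureError("empty probe selection")
    if traj.n_frames == 0:
        return OccupancyGrid(origin=np.zeros(3), cell_size=cell_size,
                             counts=np.zeros((1, 1, 1), dtype=int), n_frames=0)
    pos = traj.coords[:, probe_atoms, :].reshape(-1, 3)
    if origin is None:
        origin = pos.min(axis=0) - padding
    else:
        origin = np.asarray(origin, dtype=float)
        if (pos < origin).any():
            raise StructureError("explicit grid origin does not cover all probes")
    extent = pos.max(axis=0) + padding - origin
    shape = np.maximum(1, np.ceil(extent / cell_size).astype(int))
    idx = np.floor((pos - origin) / cell_size).astype(int)
    idx = np.clip(idx, 0, shape - 1)
    counts = np.zeros(tuple(shape), dtype=int)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return OccupancyGrid(origin=origin, cell_size=cell_size, counts=counts,
                         n_frames=traj.n_frames)


def hotspot_cells(grid: OccupancyGrid, receptor_coords: np.ndarray,
                  bulk_multiplier: float = 5.0, bulk_distance: float = 8.0) -> np.ndarray:
    """Cells whose occupancy reaches bulk_multiplier x the bulk threshold.

    The bulk threshold is the highest count among cells whose centers lie
    farther than ``bulk_distance`` from every receptor atom (the highest
    isovalue at which probes are still seen in bulk solvent); the published
    analysis contours at five times that value.
    """
    occupied = np.argwhere(grid.counts >= 0)
    centers = grid.cell_centers(occupied)
    tree = cKDTree(np.asarray(receptor_coords, dtype=float))
    dmin, _ = tree.query(centers)
    bulk_mask = dmin > bulk_distance
    if not bulk_mask.any():
        raise StructureError("no bulk cells beyond the receptor margin")
    bulk_threshold = float(grid.counts[tuple(occupied[bulk_mask].T)].max())
    grid.bulk_threshold = bulk_threshold
    cutoff = bulk_multiplier * bulk_threshold
    hot = occupied[(grid.counts[tuple(occupied.T)] >= cutoff) & (grid.counts[tuple(occupied.T)] > 0)]
    if bulk_multiplier > 1.0:
        # bulk-level occupancy is by construction not a hotspot
        keep = grid.counts[tuple(hot.T)] > bulk_threshold
        hot = hot[keep]
    return hot
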