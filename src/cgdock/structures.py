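"""Atomic structures, chain selections and bead trajectories.

Structures are held in a light columnar container (``AtomicStructure``) built
on numpy arrays; PDB files are parsed through Bio.PDB.  Residue numbering is
kept exactly as authored in the source file (1-based author numbering), since
every residue reference downstream (Asp6, Glu13, Asp48, ...) resolves against
author numbering.

Trajectories of coarse-grained beads use a plain-text columnar format of our
own (``frame  bead  x  y  z``) because CG bead rosters do not map 1:1 onto
PDB atoms; an optional multi-model PDB export is provided for visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


@dataclass(frozen=True)
class ChainSelection:
    """A chain id plus an inclusive, 1-based residue-number range."""

    chain: str
    first: int
    last: int

    def __post_init__(self):
        if self.last < self.first:
            raise StructureError(f"empty selection: {self.first}..{self.last}")


@dataclass
class AtomicStructure:
    """Columnar atom container.

    All arrays share one length (the atom count).  ``resnums`` follow the
    source file's author numbering; coordinates are in Angstrom.
    """

    names: np.ndarray          # atom names, dtype object/str
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray        # int
    chains: np.ndarray
    coords: np.ndarray         # (n_atoms, 3) float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.resnums = np.asarray(self.resnums, dtype=int)
        for arr in (self.names, self.elements, self.resnames, self.chains):
            if len(arr) != len(self.coords):
                raise StructureError("column length mismatch")
        if len(self.coords) and not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residues(self) -> list[tuple[str, int]]:
        """(chain, resnum) keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chains, self.resnums):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residues())

    def residue_mask(self, chain: str, resnum: int) -> np.ndarray:
        return (self.chains == chain) & (self.resnums == resnum)

    def residue_name(self, chain: str, resnum: int) -> str:
        m = self.residue_mask(chain, resnum)
        if not m.any():
            raise StructureError(f"no residue {chain}:{resnum}")
        return str(self.resnames[m][0])

    def atom_coord(self, chain: str, resnum: int, name: str) -> np.ndarray:
        m = self.residue_mask(chain, resnum) & (self.names == name)
        if not m.any():
            raise StructureError(f"no atom {name} in {chain}:{resnum}")
        return self.coords[m][0]

    def sequence(self, chain: str | None = None) -> str:
        out = []
        for c, r in self.residues():
            if chain is not None and c != chain:
                continue
            out.append(THREE_TO_ONE.get(self.residue_name(c, r), "X"))
        return "".join(out)

    def subset(self, mask: np.ndarray) -> "AtomicStructure":
        return AtomicStructure(
            names=self.names[mask], elements=self.elements[mask],
            resnames=self.resnames[mask], resnums=self.resnums[mask],
            chains=self.chains[mask], coords=self.coords[mask],
            metadata=dict(self.metadata),
        )

    @classmethod
    def from_records(cls, records, metadata=None) -> "AtomicStructure":
        """Build from an iterable of (name, element, resname, resnum, chain, x, y, z)."""
        rec = list(records)
        if not rec:
            return cls(np.array([], dtype=object), np.array([], dtype=object),
                       np.array([], dtype=object), np.array([], dtype=int),
                       np.array([], dtype=object), np.zeros((0, 3)), metadata or {})
        cols = list(zip(*rec))
        return cls(
            names=np.array(cols[0], dtype=object),
            elements=np.array(cols[1], dtype=object),
            resnames=np.array(cols[2], dtype=object),
            resnums=np.array(cols[3], dtype=int),
            chains=np.array(cols[4], dtype=object),
            coords=np.array(cols[5:8], dtype=float).T,
            metadata=metadata or {},
        )


def read_pdb(path, model: int = 0, skip_hetero: bool = True) -> AtomicStructure:
    """Parse ATOM records of one model of a PDB file.

    HETATM records and waters are skipped by default.  For disordered atoms
    the highest-occupancy conformer is kept.  A standard residue lacking a
    Calpha is flagged with a warning and recorded in
    ``metadata['missing_ca']``.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except Exception as exc:
        raise StructureError(f"unreadable PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"no ATOM records in {path}")
    mod = models[model]

    records = []
    missing_ca = []
    for chain in mod:
        for res in chain:
            hetflag = res.id[0]
            if skip_hetero and hetflag != " ":
                continue
            atom_names = set()
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                x, y, z = atom.get_coord()
                records.append((atom.get_name(), (atom.element or "C").strip().upper() or "C",
                                res.get_resname(), res.id[1], chain.id, float(x), float(y), float(z)))
                atom_names.add(atom.get_name())
            if res.get_resname() in THREE_TO_ONE and "CA" not in atom_names:
                missing_ca.append((chain.id, res.id[1]))
    if not records:
        raise StructureError(f"no ATOM records in {path}")
    if missing_ca:
        warnings.warn(f"residues missing CA: {missing_ca}")
    meta = {"source": str(path), "model": model}
    if missing_ca:
        meta["missing_ca"] = missing_ca
    return AtomicStructure.from_records(records, metadata=meta)


def extract_selection(struct: AtomicStructure, sel: ChainSelection) -> AtomicStructure:
    """Extract one chain/residue-range; original author numbering is preserved."""
    present = {r for c, r in struct.residues() if c == sel.chain}
    wanted = set(range(sel.first, sel.last + 1))
    missing = sorted(wanted - present)
    if missing:
        raise StructureError(f"residues absent from chain {sel.chain}: {missing}")
    mask = (struct.chains == sel.chain) & (struct.resnums >= sel.first) & (struct.resnums <= sel.last)
    out = struct.subset(mask)
    out.metadata["selection"] = (sel.chain, sel.first, sel.last)
    return out


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a fixed bead/atom roster."""

    coords: np.ndarray            # (n_frames, n_beads, 3)
    stride: int = 1               # simulation steps between saved frames
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:  # single frame
            self.coords = self.coords[None]
        if self.coords.size and self.coords.ndim != 3:
            raise StructureError("trajectory coords must be (n_frames, n_beads, 3)")

    @property
    def n_frames(self) -> int:
        return 0 if self.coords.size == 0 else self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return 0 if self.coords.size == 0 else self.coords.shape[1]

    def append(self, frame: np.ndarray) -> None:
        frame = np.asarray(frame, dtype=float)
        if self.n_frames and frame.shape != self.coords.shape[1:]:
            raise StructureError(f"roster mismatch: frame {frame.shape} vs {self.coords.shape[1:]}")
        self.coords = frame[None] if self.coords.size == 0 else np.concatenate([self.coords, frame[None]])


_TRAJ_PRECISION = "%.4f"   # 1e-4 A, well inside the declared 1e-3 A round-trip bound


def write_trajectory(traj: Trajectory, path) -> None:
    n_beads = traj.n_beads if traj.n_frames else int(traj.metadata.get("n_beads", 0))
    with open(path, "w") as fh:
        fh.write("# cgdock trajectory v1\n")
        fh.write(f"# n_frames {traj.n_frames} n_beads {n_beads} stride {traj.stride}\n")
        fh.write("# frame bead x y z\n")
        for f in range(traj.n_frames):
            for b in range(n_beads):
                x, y, z = traj.coords[f, b]
                fh.write(f"{f} {b} {_TRAJ_PRECISION % x} {_TRAJ_PRECISION % y} {_TRAJ_PRECISION % z}\n")


def read_trajectory(path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline()
        if "cgdock trajectory" not in header:
            raise StructureError(f"not a cgdock trajectory file: {path}")
        dims = fh.readline().split()
        n_frames, n_beads, stride = int(dims[2]), int(dims[4]), int(dims[6])
        fh.readline()
        data = np.loadtxt(fh, ndmin=2) if n_frames else np.zeros((0, 5))
    coords = np.zeros((n_frames, n_beads, 3))
    if n_frames:
        if len(data) != n_frames * n_beads:
            raise StructureError("truncated trajectory file")
        coords = data[:, 2:5].reshape(n_frames, n_beads, 3)
    return Trajectory(coords=coords, stride=stride, metadata={"n_beads": n_beads})


def export_beads_pdb(coords_frames: np.ndarray, names, resnums, chains, path) -> None:
    """Write CG bead frames as a multi-model PDB for visualisation."""
    frames = np.asarray(coords_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (xyz, nm, rn, ch) in enumerate(zip(frame, names, resnums, chains), start=1):
                fh.write(
                    f"ATOM  {i:5d} {nm:^4s} ALA {ch:1s}{rn:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
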