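"""Two-bead-per-residue coarse graining and native (Go) topology.

Each residue is represented by a bead at the Calpha position and, for
non-glycine residues, a second bead at the Cbeta position.  Charged residues
(K, R, H: +1; D, E: -1) carry their charge on the Cbeta bead.  Native
topology is encoded as a list of intramolecular contacts, each stored with
its reference bead-bead distance so that a Lennard-Jones well placed at that
distance makes the native geometry the energy minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from cgdock.structures import AtomicStructure, StructureError, THREE_TO_ONE

# the paper's charged-residue set: K, R, H positive; D, E negative
DEFAULT_CHARGE_TABLE = {"K": 1, "R": 1, "H": 1, "D": -1, "E": -1}

DEFAULT_CONTACT_CUTOFF = 4.5   # A, any-heavy-atom residue contact criterion
DEFAULT_MIN_SEQ_SEP = 3        # residues
DEFAULT_BOND_K = 50.0          # eps_go / A^2, harmonic pseudo-bond stiffness
STAPLE_K = 10.0                # softer restraint standing in for the hydrocarbon staple

SITE_ALPHA = 0
SITE_BETA = 1

# trRosetta-style ideal Cbeta from backbone N, CA, C
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def ideal_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca + _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * cc


@dataclass
class CGSystem:
    """Bead roster plus bonded and native-contact topology.

    ``resindex`` is the 1-based residue index within each molecule, ``site``
    distinguishes alpha/beta beads, and ``mol`` is 0 for the receptor and 1
    for the peptide (a single-molecule system uses 0 only).  ``positions``
    are the native (reference) coordinates.
    """

    positions: np.ndarray              # (n_beads, 3)
    resindex: np.ndarray               # (n_beads,) int, 1-based per molecule
    site: np.ndarray                   # (n_beads,) int, SITE_ALPHA/SITE_BETA
    charges: np.ndarray                # (n_beads,) int in {-1, 0, +1}
    mol: np.ndarray                    # (n_beads,) int molecule id
    sequence: list = field(default_factory=list)        # 1-letter codes per residue, in bead-residue order
    source_keys: list = field(default_factory=list)     # (chain, author resnum) per residue
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    contacts: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    contact_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=int)
        bad = (self.charges != 0) & (self.site != SITE_BETA)
        if bad.any():
            raise StructureError("charges allowed on beta sites only")
        if len(self.bond_r0) and (self.bond_r0 <= 0).any():
            raise StructureError("bond reference lengths must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def net_charge(self) -> int:
        return int(self.charges.sum())

    def molecule_slice(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.mol == mol_id)

    def alpha_index(self, mol_id: int = 0) -> np.ndarray:
        """Bead index of the alpha bead of each residue of one molecule."""
        m = (self.mol == mol_id) & (self.site == SITE_ALPHA)
        return np.flatnonzero(m)

    def beta_index_map(self, mol_id: int = 0) -> dict[int, int]:
        """residue index -> beta bead index for one molecule."""
        m = (self.mol == mol_id) & (self.site == SITE_BETA)
        return {int(self.resindex[i]): int(i) for i in np.flatnonzero(m)}

    def add_bond(self, i: int, j: int, r0: float | None = None, k: float = DEFAULT_BOND_K) -> None:
        if r0 is None:
            r0 = float(np.linalg.norm(self.positions[i] - self.positions[j]))
        if r0 <= 0:
            raise StructureError("bond reference length must be positive")
        self.bonds = np.vstack([self.bonds, [i, j]]).astype(int)
        self.bond_r0 = np.append(self.bond_r0, r0)
        self.bond_k = np.append(self.bond_k, k)


def write_cg_system(cg: CGSystem, path) -> None:
    """Serialize a CG system to a YAML text document (lossless round-trip)."""
    import yaml

    doc = {
        "positions": cg.positions.tolist(), "resindex": cg.resindex.tolist(),
        "site": cg.site.tolist(), "charges": cg.charges.tolist(),
        "mol": cg.mol.tolist(), "sequence": list(cg.sequence),
        "source_keys": [[c, int(r)] for c, r in cg.source_keys],
        "bonds": cg.bonds.tolist(), "bond_r0": cg.bond_r0.tolist(),
        "bond_k": cg.bond_k.tolist(),
        "contacts": cg.contacts.reshape(-1, 2).tolist(),
        "contact_r0": cg.contact_r0.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def read_cg_system(path) -> CGSystem:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CGSystem(
        positions=np.array(doc["positions"], dtype=float),
        resindex=np.array(doc["resindex"], dtype=int),
        site=np.array(doc["site"], dtype=int),
        charges=np.array(doc["charges"], dtype=int),
        mol=np.array(doc["mol"], dtype=int),
        sequence=list(doc["sequence"]),
        source_keys=[(c, int(r)) for c, r in doc["source_keys"]],
        bonds=np.array(doc["bonds"], dtype=int).reshape(-1, 2),
        bond_r0=np.array(doc["bond_r0"], dtype=float),
        bond_k=np.array(doc["bond_k"], dtype=float),
        contacts=np.array(doc["contacts"], dtype=int).reshape(-1, 2),
        contact_r0=np.array(doc["contact_r0"], dtype=float),
    )


def coarse_grain(struct: AtomicStructure, charge_table: dict | None = None,
                 mol_id: int = 0) -> CGSystem:
    """Map an atomic structure onto the two-bead model.

    One alpha bead per residue at the Calpha coordinate; one beta bead per
    non-glycine residue at the Cbeta coordinate (reconstructed from ideal
    backbone geometry, with a warning, if the source lacks one).  Bonds:
    consecutive Calpha-Calpha and intra-residue Calpha-Cbeta harmonics at
    their source lengths.
    """
    table = dict(DEFAULT_CHARGE_TABLE if charge_table is None else charge_table)
    residues = struct.residues()
    if not residues:
        raise StructureError("empty structure")

    positions, resindex, site, charges = [], [], [], []
    sequence, source_keys = [], []
    alpha_of, beta_of = {}, {}
    for ridx, (chain, resnum) in enumerate(residues, start=1):
        resname = struct.residue_name(chain, resnum)
        one = THREE_TO_ONE.get(resname, "X")
        try:
            ca = struct.atom_coord(chain, resnum, "CA")
        except StructureError as exc:
            raise StructureError(f"residue {chain}:{resnum} lacks CA") from exc
        alpha_of[ridx] = len(positions)
        positions.append(ca)
        resindex.append(ridx)
        site.append(SITE_ALPHA)
        charges.append(0)
        sequence.append(one)
        source_keys.append((chain, resnum))
        if one == "G":
            continue
        try:
            cb = struct.atom_coord(chain, resnum, "CB")
        except StructureError:
            try:
                n = struct.atom_coord(chain, resnum, "N")
                c = struct.atom_coord(chain, resnum, "C")
                cb = ideal_cbeta(n, ca, c)
                warnings.warn(f"reconstructed ideal CB for {chain}:{resnum} {resname}")
            except StructureError as exc:
                raise StructureError(
                    f"residue {chain}:{resnum} lacks CB and backbone atoms for reconstruction"
                ) from exc
        beta_of[ridx] = len(positions)
        positions.append(cb)
        resindex.append(ridx)
        site.append(SITE_BETA)
        charges.append(int(table.get(one, 0)))

    cg = CGSystem(
        positions=np.array(positions), resindex=np.array(resindex, dtype=int),
        site=np.array(site, dtype=int), charges=np.array(charges, dtype=int),
        mol=np.full(len(positions), mol_id, dtype=int),
        sequence=sequence, source_keys=source_keys,
        metadata={"source": struct.metadata.get("source", "memory")},
    )
    for ridx in range(1, len(residues)):
        cg.add_bond(alpha_of[ridx], alpha_of[ridx + 1])
    for ridx, b in beta_of.items():
        cg.add_bond(alpha_of[ridx], b)
    return cg


def build_native_contacts(cg: CGSystem, source: AtomicStructure,
                          cutoff: float = DEFAULT_CONTACT_CUTOFF,
                          min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> CGSystem:
    """Attach the Go contact list derived from the source structure.

    Two residues are in native contact when any pair of their heavy atoms
    lies within ``cutoff`` and their sequence separation is at least
    ``min_seq_sep``.  Each contacting residue pair contributes an
    alpha-alpha bead contact and, where both residues have beta beads, a
    beta-beta contact; reference distances come from the bead geometry.
    Contacts are intramolecular only (the source is one molecule).
    """
    if cutoff <= 0:
        raise StructureError("contact cutoff must be positive")
    key_to_ridx = {key: i + 1 for i, key in enumerate(cg.source_keys)}
    heavy = np.array([e != "H" for e in source.elements], dtype=bool)
    coords = source.coords[heavy]
    atom_ridx = np.array(
        [key_to_ridx[(str(c), int(r))] for c, r in zip(source.chains[heavy], source.resnums[heavy])],
        dtype=int,
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    res_pairs = set()
    for a, b in pairs:
        ri, rj = int(atom_ridx[a]), int(atom_ridx[b])
        if abs(ri - rj) >= min_seq_sep:
            res_pairs.add((min(ri, rj), max(ri, rj)))

    alpha = {int(cg.resindex[i]): int(i)
             for i in np.flatnonzero(cg.site == SITE_ALPHA)}
    beta = cg.beta_index_map(int(cg.mol[0]))
    clist, cr0 = [], []
    for ri, rj in sorted(res_pairs):
        for bi, bj in ((alpha[ri], alpha[rj]),
                       (beta.get(ri), beta.get(rj))):
            if bi is None or bj is None:
                continue
            r0 = float(np.linalg.norm(cg.positions[bi] - cg.positions[bj]))
            clist.append((bi, bj))
            cr0.append(r0)
    cg.contacts = np.array(clist, dtype=int).reshape(-1, 2)
    cg.contact_r0 = np.array(cr0)
    cg.metadata.update({"contact_cutoff": cutoff, "min_seq_sep": min_seq_sep})
    return cg


def add_staple_restraint(cg: CGSystem, res_i: int, res_j: int,
                         mol_id: int = 0, k: float = STAPLE_K) -> CGSystem:
    """Harmonic restraint between the beta beads of the two staple positions.

    The CG model has no hydrocarbon-linker beads; a soft harmonic between
    the two stapled side-chain beads at their model distance preserves the
    staple's helix-rigidifying role.
    """
    beta = cg.beta_index_map(mol_id)
    if res_i not in beta or res_j not in beta:
        raise StructureError(f"staple positions {res_i},{res_j} lack beta beads")
    cg.add_bond(beta[res_i], beta[res_j], k=k)
    cg.metadata.setdefault("staples", []).append((res_i, res_j))
    return cg


def combine(receptor: CGSystem, peptide: CGSystem) -> CGSystem:
    """Merge receptor (mol 0) and peptide (mol 1) into one docking system."""
    off = receptor.n_beads
    return CGSystem(
        positions=np.vstack([receptor.positions, peptide.positions]),
        resindex=np.concatenate([receptor.resindex, peptide.resindex]),
        site=np.concatenate([receptor.site, peptide.site]),
        charges=np.concatenate([receptor.charges, peptide.charges]),
        mol=np.concatenate([np.zeros(receptor.n_beads, dtype=int),
                            np.ones(peptide.n_beads, dtype=int)]),
        sequence=list(receptor.sequence) + list(peptide.sequence),
        source_keys=list(receptor.source_keys) + list(peptide.source_keys),
        bonds=np.vstack([receptor.bonds, peptide.bonds + off]).astype(int),
        bond_r0=np.concatenate([receptor.bond_r0, peptide.bond_r0]),
        bond_k=np.concatenate([receptor.bond_k, peptide.bond_k]),
        contacts=np.vstack([receptor.contacts.reshape(-1, 2),
                            peptide.contacts.reshape(-1, 2) + off]).astype(int),
        contact_r0=np.concatenate([receptor.contact_r0, peptide.contact_r0]),
        metadata={"receptor": receptor.metadata, "peptide": peptide.metadata},
    )
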