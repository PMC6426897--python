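"""CG potential: bonded terms, intramolecular Go wells, Debye-Hueckel electrostatics.

Units are reduced: the Go well depth eps_go is the energy unit (= 1 by
default), lengths are Angstrom, masses 1, and temperature is quoted as kT in
units of eps_go.  The only dimensional anchor is the electrostatic coupling
``coulomb_coupling``, which defaults to 332.0637 / eps_r — i.e. the aqueous
Coulomb constant (kcal mol^-1 A e^-2) read in units of eps_go ~ 1 kcal/mol.
It is the single scalar that sets the electrostatic-to-Go weight.

The screened electrostatic pair term is

    u(r) = C q_i q_j exp(-r / lambda_D) / r,      C = 332.0637 / eps_r,

acting between charged Cbeta beads of *different* molecules only; the Debye
length is derived from the ionic strength via lambda_D = 3.04 / sqrt(I[M])
Angstrom at 298 K (about 30.4 A at the default 10 mM).  Note that because CG
bead separations exceed the corresponding all-atom distances, a nominal
10 mM behaves like roughly 30 mM of effective screening; this is a property
of the model, not corrected for automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cgdock.cg import CGSystem

COULOMB_KCAL = 332.0637  # kcal mol^-1 A e^-2
DEBYE_PREFACTOR = 3.04   # A * sqrt(M), aqueous solvent at 298 K


def debye_length(ionic_strength: float) -> float:
    """Debye screening length (A) from ionic strength (mol/L) at 298 K."""
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    return DEBYE_PREFACTOR / np.sqrt(ionic_strength)


@dataclass
class EnergyParams:
    """Force-field parameters in reduced units (see module docstring)."""

    epsilon_r: float = 80.0          # solvent dielectric
    ionic_strength: float = 0.010    # mol/L; the protocol keeps salt low
    temperature: float = 0.5         # kT in eps_go units ("relatively low": eps_go/kT = 2)
    eps_go: float = 1.0              # Go well depth, the energy unit
    lj_form: str = "12-10"           # or "12-6"
    bond_k: float = 50.0             # eps_go / A^2
    sigma_rep: float = 3.8           # A, excluded-volume diameter
    eps_rep: float = 1.0             # eps_go, repulsion strength
    coulomb_coupling: float | None = None  # eps_go * A / e^2; default COULOMB_KCAL/epsilon_r

    def __post_init__(self):
        if self.coulomb_coupling is None:
            self.coulomb_coupling = COULOMB_KCAL / self.epsilon_r
        if self.eps_go <= 0:
            raise ValueError("eps_go must be positive")
        if self.lj_form not in ("12-10", "12-6"):
            raise ValueError(f"unknown LJ form {self.lj_form!r}")
        self.debye_len = debye_length(self.ionic_strength)


@dataclass
class EnergyBreakdown:
    """Component-wise energy with a per-residue intermolecular decomposition.

    ``per_residue`` maps (molecule id, residue index) to that residue's share
    of the intermolecular (Debye-Hueckel) energy; each pair term is split
    half-and-half between its two residues, so the shares sum to
    ``electrostatic``.
    """

    bonded: float
    go: float
    repulsion: float
    electrostatic: float
    per_residue: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.bonded + self.go + self.repulsion + self.electrostatic


def debye_huckel_energy(coords_a: np.ndarray, charges_a: np.ndarray,
                        coords_b: np.ndarray, charges_b: np.ndarray,
                        params: EnergyParams) -> float:
    """Screened Coulomb energy between the beads of two distinct molecules."""
    qa = np.asarray(charges_a, dtype=float)
    qb = np.asarray(charges_b, dtype=float)
    ia = np.flatnonzero(qa != 0)
    ib = np.flatnonzero(qb != 0)
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    diff = np.asarray(coords_a)[ia, None, :] - np.asarray(coords_b)[None, ib, :]
    r = np.linalg.norm(diff, axis=-1)
    if (r == 0).any():
        raise ValueError("coincident charged beads (r = 0)")
    qq = qa[ia, None] * qb[None, ib]
    return float(params.coulomb_coupling * np.sum(qq * np.exp(-r / params.debye_len) / r))


def _go_pair_energy(r: np.ndarray, r0: np.ndarray, eps: float, form: str) -> np.ndarray:
    if form == "12-10":
        x = r0 / r
        return eps * (5.0 * x**12 - 6.0 * x**10)
    sigma = r0 / 2.0 ** (1.0 / 6.0)
    x = sigma / r
    return 4.0 * eps * (x**12 - x**6)


@dataclass
class PairTables:
    """Precomputed interaction pair lists for one docking system."""

    bonds: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    contacts: np.ndarray
    contact_r0: np.ndarray
    rep_pairs: np.ndarray            # excluded-volume pairs (i < j)
    elec_pairs: np.ndarray           # intermolecular charged bead pairs
    elec_coeff: np.ndarray           # coulomb_coupling * q_i * q_j per pair


def build_pair_tables(cg: CGSystem, params: EnergyParams,
                      rep_prune_distance: float = 12.0) -> PairTables:
    """Enumerate bonded, Go, excluded-volume and electrostatic pair lists.

    Excluded volume applies to every bead pair that is not bonded, not a
    native contact, and not within one residue along the same chain;
    electrostatics applies to intermolecular charged-bead pairs only.
    Intramolecular pairs whose native separation exceeds
    ``rep_prune_distance`` are dropped from the excluded-volume list: the Go
    web restrains them far outside the repulsive core, so the term can never
    fire while the molecule stays folded (set to ``inf`` to disable).
    """
    n = cg.n_beads
    excluded = set(map(tuple, np.sort(cg.bonds, axis=1)))
    excluded |= set(map(tuple, np.sort(cg.contacts.reshape(-1, 2), axis=1)))
    iu, ju = np.triu_indices(n, k=1)
    same_mol = cg.mol[iu] == cg.mol[ju]
    near_seq = same_mol & (np.abs(cg.resindex[iu] - cg.resindex[ju]) <= 1)
    native_d = np.linalg.norm(cg.positions[iu] - cg.positions[ju], axis=1)
    prunable = same_mol & (native_d > rep_prune_distance)
    rep = []
    for i, j, skip in zip(iu, ju, near_seq | prunable):
        if skip or (int(i), int(j)) in excluded:
            continue
        rep.append((int(i), int(j)))
    qi = cg.charges[iu].astype(float)
    qj = cg.charges[ju].astype(float)
    emask = (~same_mol) & (qi != 0) & (qj != 0)
    elec_pairs = np.stack([iu[emask], ju[emask]], axis=1).astype(int)
    elec_coeff = params.coulomb_coupling * qi[emask] * qj[emask]
    return PairTables(
        bonds=cg.bonds.astype(int), bond_r0=cg.bond_r0.copy(), bond_k=cg.bond_k.copy(),
        contacts=cg.contacts.reshape(-1, 2).astype(int), contact_r0=cg.contact_r0.copy(),
        rep_pairs=np.array(rep, dtype=int).reshape(-1, 2),
        elec_pairs=elec_pairs, elec_coeff=elec_coeff,
    )


def go_energy(cg: CGSystem, coords: np.ndarray, params: EnergyParams | None = None) -> float:
    """Sum of native-contact LJ wells; the minimum of each well sits at r0."""
    params = params or EnergyParams()
    if len(cg.contact_r0) == 0:
        return 0.0
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != cg.n_beads:
        raise ValueError("coords do not match bead roster")
    c = cg.contacts.reshape(-1, 2)
    r = np.linalg.norm(coords[c[:, 0]] - coords[c[:, 1]], axis=1)
    return float(_go_pair_energy(r, cg.contact_r0, params.eps_go, params.lj_form).sum())


def bonded_energy(cg: CGSystem, coords: np.ndarray) -> float:
    if len(cg.bond_r0) == 0:
        return 0.0
    r = np.linalg.norm(coords[cg.bonds[:, 0]] - coords[cg.bonds[:, 1]], axis=1)
    return float(np.sum(cg.bond_k * (r - cg.bond_r0) ** 2))


def repulsion_energy(tables: PairTables, coords: np.ndarray, params: EnergyParams) -> float:
    """Truncated-and-shifted r^-12 core, zero at and beyond sigma_rep."""
    p = tables.rep_pairs
    if len(p) == 0:
        return 0.0
    r = np.linalg.norm(coords[p[:, 0]] - coords[p[:, 1]], axis=1)
    inside = r < params.sigma_rep
    if not inside.any():
        return 0.0
    x = params.sigma_rep / r[inside]
    return float(params.eps_rep * np.sum(x**12 - 1.0))


def total_energy(cg: CGSystem, coords: np.ndarray, params: EnergyParams | None = None,
                 tables: PairTables | None = None) -> EnergyBreakdown:
    """Full breakdown at one configuration, with per-residue DH shares."""
    params = params or EnergyParams()
    tables = tables or build_pair_tables(cg, params)
    coords = np.asarray(coords, dtype=float)

    per_res: dict[tuple[int, int], float] = {}
    elec = 0.0
    ep = tables.elec_pairs
    if len(ep):
        r = np.linalg.norm(coords[ep[:, 0]] - coords[ep[:, 1]], axis=1)
        if (r == 0).any():
            raise ValueError("coincident charged beads (r = 0)")
        terms = tables.elec_coeff * np.exp(-r / params.debye_len) / r
        elec = float(terms.sum())
        for (i, j), u in zip(ep, terms):
            for b in (i, j):
                key = (int(cg.mol[b]), int(cg.resindex[b]))
                per_res[key] = per_res.get(key, 0.0) + 0.5 * float(u)

    return EnergyBreakdown(
        bonded=bonded_energy(cg, coords),
        go=go_energy(cg, coords, params),
        repulsion=repulsion_energy(tables, coords, params),
        electrostatic=elec,
        per_residue=per_res,
    )


def forces(cg: CGSystem, coords: np.ndarray, params: EnergyParams | None = None,
           tables: PairTables | None = None,
           terms: tuple = ("bonded", "go", "rep", "elec")) -> np.ndarray:
    """Analytic forces (-grad U), pure-numpy reference implementation.

    The docking engine uses an equivalent numba kernel; this path backs the
    stationarity tests and serves as the cross-check for that kernel.
    """
    params = params or EnergyParams()
    tables = tables or build_pair_tables(cg, params)
    coords = np.asarray(coords, dtype=float)
    f = np.zeros_like(coords)

    def accumulate(pairs, dudr_over_r):
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        fv = -dudr_over_r[:, None] * d        # force on i; dudr_over_r = (dU/dr)/r
        np.add.at(f, pairs[:, 0], fv)
        np.add.at(f, pairs[:, 1], -fv)

    if "bonded" in terms and len(tables.bonds):
        d = coords[tables.bonds[:, 0]] - coords[tables.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        accumulate(tables.bonds, 2.0 * tables.bond_k * (r - tables.bond_r0) / r)
    if "go" in terms and len(tables.contacts):
        d = coords[tables.contacts[:, 0]] - coords[tables.contacts[:, 1]]
        r = np.linalg.norm(d, axis=1)
        r0 = tables.contact_r0
        if params.lj_form == "12-10":
            x = r0 / r
            dudr = params.eps_go * (-60.0 * x**12 + 60.0 * x**10) / r
        else:
            sigma = r0 / 2.0 ** (1.0 / 6.0)
            x = sigma / r
            dudr = 4.0 * params.eps_go * (-12.0 * x**12 + 6.0 * x**6) / r
        accumulate(tables.contacts, dudr / r)
    if "rep" in terms and len(tables.rep_pairs):
        d = coords[tables.rep_pairs[:, 0]] - coords[tables.rep_pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        x = params.sigma_rep / r
        dudr = np.where(r < params.sigma_rep, -12.0 * params.eps_rep * x**12 / r, 0.0)
        accumulate(tables.rep_pairs, dudr / r)
    if "elec" in terms and len(tables.elec_pairs):
        d = coords[tables.elec_pairs[:, 0]] - coords[tables.elec_pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        u = tables.elec_coeff * np.exp(-r / params.debye_len) / r
        dudr = -u * (1.0 / r + 1.0 / params.debye_len)
        accumulate(tables.elec_pairs, dudr / r)
    return f
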