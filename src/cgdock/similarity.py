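"""Interface-similarity statistic D, its halves D1/D2, and the (D1, D2) landscape.

D compares a simulated protein-peptide pose against the experimental type-I
interface through the interfacial Cbeta-Cbeta distance table:

    D = (1 / (N_protein * N_peptide)) * sum_i sum_j (r_ij - r0_ij)

where i runs over the protein interface residues (for the pyrin-domain
target: Asp6, Leu9, Asp10, Glu13, Asp48, Leu50, Asp51, Asp54) and j over the
peptide interface residues (Lys6, Lys7, Lys9, Ile10, Lys11 in the 15-mer
numbering), r_ij is the simulated Cbeta bead distance and r0_ij its value in
the reference structure.  Peptide direction matters: residue j is matched to
reference residue j, never to the best of both orientations.  Splitting the
peptide residues into two spatial halves and applying the same formula per
half gives D1 and D2; a pose is called native-like when both halves are
within a cutoff tau of the reference.

D is signed as defined: poses with systematically shorter distances than the
reference give negative D, and the native-like test guards against counting
such overlap poses (D >= -tau) while requiring max(D1, D2) <= tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cgdock.cg import CGSystem, SITE_BETA
from cgdock.structures import AtomicStructure, StructureError

# interface residue defaults for the pyrin-domain type-Ia surface (chain A of
# the type-I dimer) and the helix-2 peptide (15-mer numbering)
DEFAULT_PROTEIN_INTERFACE = [("A", 6), ("A", 9), ("A", 10), ("A", 13),
                             ("A", 48), ("A", 50), ("A", 51), ("A", 54)]
DEFAULT_PEPTIDE_INTERFACE = [6, 7, 9, 10, 11]
DEFAULT_NATIVE_TAU = 3.0  # A


@dataclass
class ReferenceInterface:
    """Reference pairwise Cbeta distance table r0 for the native interface.

    ``protein_ids`` entries are (chain, author-resnum) tuples or plain
    1-based residue indices of the receptor molecule; ``peptide_ids`` are
    1-based peptide positions.  ``split`` is the index at which the peptide
    residue list divides into the two spatial halves (default: midpoint).
    """

    protein_ids: list
    peptide_ids: list
    r0: np.ndarray                      # (n_protein, n_peptide)
    split: int = -1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r0 = np.asarray(self.r0, dtype=float)
        if not self.protein_ids or not self.peptide_ids:
            raise StructureError("interface residue lists must be non-empty")
        if self.r0.shape != (len(self.protein_ids), len(self.peptide_ids)):
            raise StructureError("r0 shape does not match residue lists")
        if (self.r0 <= 0).any():
            raise StructureError("reference distances must be positive")
        if self.split < 0:
            self.split = len(self.peptide_ids) // 2

    @property
    def n_protein(self) -> int:
        return len(self.protein_ids)

    @property
    def n_peptide(self) -> int:
        return len(self.peptide_ids)

    def indices_in(self, system: CGSystem) -> tuple[np.ndarray, np.ndarray]:
        """Beta-bead indices of the interface residues in a docking system."""
        def beta_bead(mol, ident):
            for b in np.flatnonzero((system.mol == mol) & (system.site == SITE_BETA)):
                ridx = int(system.resindex[b])
                key = system.source_keys[ridx - 1 + _mol_res_offset(system, mol)]
                if isinstance(ident, tuple):
                    if key == (ident[0], int(ident[1])):
                        return int(b)
                elif ridx == int(ident):
                    return int(b)
            raise StructureError(f"interface residue {ident} has no beta bead in molecule {mol}")

        ip = np.array([beta_bead(0, pid) for pid in self.protein_ids], dtype=int)
        jp = np.array([beta_bead(1, pid) for pid in self.peptide_ids], dtype=int)
        return ip, jp


def _mol_res_offset(system: CGSystem, mol: int) -> int:
    if mol == 0:
        return 0
    alpha0 = system.alpha_index(0)
    return len(alpha0)


def build_reference(dimer: AtomicStructure, protein_residues=None, peptide_residues=None,
                    peptide_positions=None, split: int = -1) -> ReferenceInterface:
    """Record r0 from an experimental (or synthetic) dimer structure.

    ``protein_residues`` and ``peptide_residues`` are (chain, resnum) lists
    resolved against the structure; ``peptide_positions`` relabels the
    peptide residues into peptide numbering (default 15-mer helix-2 labels).
    """
    protein_residues = protein_residues or DEFAULT_PROTEIN_INTERFACE
    if peptide_residues is None:
        # helix-2 residues 21, 22, 24, 25, 26 of chain B <-> peptide 6,7,9,10,11
        peptide_residues = [("B", p + 15) for p in DEFAULT_PEPTIDE_INTERFACE]
    if peptide_positions is None:
        peptide_positions = list(DEFAULT_PEPTIDE_INTERFACE) \
            if len(peptide_residues) == len(DEFAULT_PEPTIDE_INTERFACE) \
            else list(range(1, len(peptide_residues) + 1))

    def cbeta(chain, resnum):
        name = dimer.residue_name(chain, resnum)
        atom = "CA" if name == "GLY" else "CB"
        return dimer.atom_coord(chain, resnum, atom)

    prot = np.array([cbeta(c, r) for c, r in protein_residues])
    pep = np.array([cbeta(c, r) for c, r in peptide_residues])
    r0 = np.linalg.norm(prot[:, None, :] - pep[None, :, :], axis=-1)
    return ReferenceInterface(
        protein_ids=[(c, int(r)) for c, r in protein_residues],
        peptide_ids=list(peptide_positions), r0=r0, split=split,
        metadata={"source": dimer.metadata.get("source", "memory")},
    )


def reference_from_cg(system: CGSystem, protein_resindices, peptide_resindices,
                      split: int = -1) -> ReferenceInterface:
    """Reference built from a CG system's native pose (synthetic workflows)."""
    ref = ReferenceInterface(
        protein_ids=list(map(int, protein_resindices)),
        peptide_ids=list(map(int, peptide_resindices)),
        r0=np.ones((len(protein_resindices), len(peptide_resindices))),
        split=split,
    )
    ip, jp = ref.indices_in(system)
    ref.r0 = np.linalg.norm(system.positions[ip][:, None, :]
                            - system.positions[jp][None, :, :], axis=-1)
    ref.metadata["bead_indices"] = (ip, jp)
    return ref


@dataclass
class SimilarityResult:
    """Per-frame D, D1, D2 (A) for one set of conformations."""

    D: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    split: int

    def __post_init__(self):
        for a in (self.D, self.D1, self.D2):
            if not np.isfinite(a).all():
                raise ValueError("non-finite similarity values")


def compute_D(frame: np.ndarray, ref: ReferenceInterface,
              indices: tuple[np.ndarray, np.ndarray]) -> tuple[float, float, float]:
    """D, D1, D2 for one frame of bead coordinates.

    ``indices`` are the protein/peptide beta-bead index arrays, ordered
    exactly as the reference residue lists (directional matching).
    """
    ip, jp = indices
    if len(ip) != ref.n_protein or len(jp) != ref.n_peptide:
        raise ValueError("bead index arrays do not match the reference roster")
    r = np.linalg.norm(frame[ip][:, None, :] - frame[jp][None, :, :], axis=-1)
    diff = r - ref.r0
    d = float(diff.mean())
    s = ref.split
    d1 = float(diff[:, :s].mean())
    d2 = float(diff[:, s:].mean())
    return d, d1, d2


def score_frames(frames: np.ndarray, ref: ReferenceInterface,
                 system: CGSystem | None = None,
                 indices: tuple | None = None) -> SimilarityResult:
    """Vectorised D/D1/D2 over a stack of frames."""
    if indices is None:
        if system is None:
            raise ValueError("need a CG system or explicit bead indices")
        indices = ref.indices_in(system)
    ip, jp = indices
    r = np.linalg.norm(frames[:, ip, None, :] - frames[:, jp, :][:, None, :, :], axis=-1)
    diff = r - ref.r0[None]
    s = ref.split
    return SimilarityResult(
        D=diff.mean(axis=(1, 2)),
        D1=diff[:, :, :s].mean(axis=(1, 2)),
        D2=diff[:, :, s:].mean(axis=(1, 2)),
        split=s,
    )


@dataclass
class Landscape:
    """Free-energy surface F = -kT ln(P / P_max) over (D1, D2) bins."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray          # nan where unoccupied
    kT: float
    n_frames: int

    def plot(self, ax=None, cmap="viridis"):
        """Render F(D1, D2); masked (unoccupied) bins stay blank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        masked = np.ma.masked_invalid(self.free_energy)
        mesh = ax.pcolormesh(self.x_edges, self.y_edges, masked.T, cmap=cmap)
        ax.set_xlabel(r"$D_1$ ($\mathrm{\AA}$)")
        ax.set_ylabel(r"$D_2$ ($\mathrm{\AA}$)")
        cbar = ax.figure.colorbar(mesh, ax=ax)
        cbar.set_label(f"free energy (kT = {self.kT:g})")
        return ax

    def to_dataframe(self):
        import pandas as pd
        xi, yi = np.meshgrid(np.arange(self.counts.shape[0]),
                             np.arange(self.counts.shape[1]), indexing="ij")
        return pd.DataFrame({
            "d1_lo": self.x_edges[xi.ravel()], "d1_hi": self.x_edges[xi.ravel() + 1],
            "d2_lo": self.y_edges[yi.ravel()], "d2_hi": self.y_edges[yi.ravel() + 1],
            "count": self.counts.ravel().astype(int),
            "free_energy": self.free_energy.ravel(),
        })


def build_landscape(result: SimilarityResult, kT: float = 0.5, bins: int = 50,
                    extent=None) -> Landscape:
    """Histogram (D1, D2) and convert occupancy to free energy.

    The most populated bin defines F = 0; unoccupied bins are nan (masked).
    """
    if len(result.D1) == 0:
        raise ValueError("no frames to histogram")
    counts, xe, ye = np.histogram2d(result.D1, result.D2, bins=bins, range=extent)
    cmax = counts.max()
    with np.errstate(divide="ignore"):
        fe = np.where(counts > 0, -kT * np.log(counts / cmax), np.nan)
    return Landscape(counts=counts, x_edges=xe, y_edges=ye, free_energy=fe,
                     kT=kT, n_frames=len(result.D1))


def native_like_fraction(result: SimilarityResult, threshold: float = DEFAULT_NATIVE_TAU) -> float:
    """Fraction of frames with both halves within tau of the reference.

    Classified native-like when max(D1, D2) <= tau and D >= -tau (the lower
    guard rejects steric-overlap poses whose distances undershoot r0).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(result.D) == 0:
        return 0.0
    ok = (np.maximum(result.D1, result.D2) <= threshold) & (result.D >= -threshold)
    return float(ok.mean())


def tau_scan(result: SimilarityResult, taus=None):
    """Native-like fraction across a range of cutoffs (reported, not asserted:
    the published 28%/38% comparison used an unstated cutoff)."""
    import pandas as pd
    taus = np.asarray(taus if taus is not None else np.arange(0.5, 10.5, 0.5))
    return pd.DataFrame({
        "tau": taus,
        "native_like_fraction": [native_like_fraction(result, float(t)) for t in taus],
    })
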