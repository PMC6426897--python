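"""Shared fixtures: hand-written PDB snippets and cached synthetic systems."""

import numpy as np
import pytest

from cgdock.cg import build_native_contacts, coarse_grain, combine
from cgdock.synthetic import SYNTHETIC_CONTACT_CUTOFF, make_patch_system

# Ala-Lys-Asp tripeptide with full backbone, idealized coordinates (A).
TRIPEPTIDE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   LYS A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  LYS A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   LYS A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   LYS A   2       6.030   1.581   0.000  1.00  0.00           O
ATOM     10  CB  LYS A   2       3.580   3.653   1.235  1.00  0.00           C
ATOM     11  N   ASP A   3       6.213   3.816   0.000  1.00  0.00           N
ATOM     12  CA  ASP A   3       7.671   3.814   0.000  1.00  0.00           C
ATOM     13  C   ASP A   3       8.222   5.234   0.000  1.00  0.00           C
ATOM     14  O   ASP A   3       7.464   6.204   0.000  1.00  0.00           O
ATOM     15  CB  ASP A   3       8.201   3.041  -1.199  1.00  0.00           C
END
"""


@pytest.fixture()
def tripeptide_pdb(tmp_path):
    path = tmp_path / "tripeptide.pdb"
    path.write_text(TRIPEPTIDE_PDB)
    return path


@pytest.fixture(scope="session")
def patch_complex():
    return make_patch_system(seed=7)


@pytest.fixture(scope="session")
def patch_cg(patch_complex):
    """(receptor_cg, peptide_cg, combined) for the session patch system."""
    rec = coarse_grain(patch_complex.receptor)
    rec = build_native_contacts(rec, patch_complex.receptor, cutoff=SYNTHETIC_CONTACT_CUTOFF)
    pep = coarse_grain(patch_complex.peptide, mol_id=1)
    pep = build_native_contacts(pep, patch_complex.peptide, cutoff=SYNTHETIC_CONTACT_CUTOFF)
    return rec, pep, combine(rec, pep)


@pytest.fixture(scope="session")
def short_campaign(patch_cg):
    """One small shared campaign used by several diagnostics tests."""
    from cgdock.docking import DockingProtocol, run_campaign

    rec, pep, _ = patch_cg
    protocol = DockingProtocol(
        n_start_positions=2, replicas_per_position=1, steps_per_replica=100_000,
        save_stride=1000, frames_kept_per_replica=50, placement_distance=25.0,
        wall_radius_factor=1.6, seed=42)
    return run_campaign(rec, pep, protocol), protocol
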