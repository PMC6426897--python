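"""Stapled-peptide design bookkeeping: templates, mutations, staples, audits.

The design space is anchored on two helix-2 templates (the adaptor-protein
pyrin-domain helix 2, residues 16-30, TAEELKKFKLKLLSV; and the NLRP3
pyrin-domain helix 2, residues 20-32, VDLKKFKMHLEDY).  Designed variants add
an i,i+7 hydrocarbon staple ('*' positions) and up to six point mutations.
Staple chemistry ((R)-2-(7'octenyl)alanine / (S)-2-(4'pentenyl)alanine) is
metadata only; downstream CG modelling treats '*' positions as alanine-like
beads plus a harmonic beta-beta restraint.  All peptides are N-acetylated
and C-amidated, so termini carry no charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from cgdock.cg import DEFAULT_CHARGE_TABLE
from cgdock.structures import AtomicStructure, ChainSelection, StructureError, extract_selection

STAPLE_SPAN = 7  # i, i+7


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideSpec:
    """One designed peptide: sequence with staple marks plus provenance.

    ``mutations`` maps 1-based position -> (original, new); ``staple`` is
    (i, i+7) or None.  13-mers relate to 15-mer numbering through
    ``long_position_offset`` (short position k corresponds to long k+2), so
    interface residue lists quoted in long numbering resolve for both.
    """

    name: str
    sequence: str
    template: str = ""
    mutations: dict = field(default_factory=dict)
    staple: tuple | None = None
    staple_original: tuple | None = None
    termini: tuple = ("ACE", "NHE")

    def __post_init__(self):
        stars = [i + 1 for i, c in enumerate(self.sequence) if c == "*"]
        if len(stars) not in (0, 2):
            raise DesignError(f"{self.name}: '*' count must be 0 or 2")
        if stars:
            if self.staple is None:
                object.__setattr__(self, "staple", tuple(stars))
            if stars[1] - stars[0] != STAPLE_SPAN:
                raise DesignError(f"{self.name}: staple positions must be i, i+{STAPLE_SPAN}")
        allowed = set("ACDEFGHIKLMNPQRSTVWY*")
        if not set(self.sequence) <= allowed:
            raise DesignError(f"{self.name}: non-standard residue in {self.sequence}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def long_position_offset(self) -> int:
        return 2 if self.length == 13 else 0

    def to_long_position(self, short_pos: int) -> int:
        return short_pos + self.long_position_offset

    def from_long_position(self, long_pos: int) -> int:
        return long_pos - self.long_position_offset


def template_from_structure(struct: AtomicStructure, sel: ChainSelection,
                            name: str = "template") -> PeptideSpec:
    """Read a template sequence straight off a structure selection."""
    frag = extract_selection(struct, sel)
    seq = frag.sequence(sel.chain)
    if "X" in seq:
        raise DesignError(f"non-standard residue in template range {sel}")
    return PeptideSpec(name=name, sequence=seq, template=f"{sel.chain}:{sel.first}-{sel.last}")


def apply_staple(spec: PeptideSpec, i: int) -> PeptideSpec:
    """Mark positions i and i+7 as staple sites."""
    j = i + STAPLE_SPAN
    if spec.staple is not None:
        raise DesignError(f"{spec.name} already stapled at {spec.staple}")
    if i < 1 or j > spec.length:
        raise DesignError(f"staple {i},{j} outside 1..{spec.length}")
    seq = list(spec.sequence)
    original = (seq[i - 1], seq[j - 1])
    seq[i - 1] = seq[j - 1] = "*"
    return replace(spec, sequence="".join(seq), staple=(i, j), staple_original=original)


def _parse_mutation(value) -> tuple[str | None, str]:
    if isinstance(value, (tuple, list)):
        return str(value[0]), str(value[1])
    value = str(value)
    if ">" in value:
        orig, new = value.split(">")
        return orig.strip(), new.strip()
    return None, value.strip()


def apply_mutations(spec: PeptideSpec, mutations: dict) -> PeptideSpec:
    """Apply point mutations {position: "orig>new"} (or {position: new})."""
    seq = list(spec.sequence)
    log = dict(spec.mutations)
    for pos, value in sorted(mutations.items()):
        pos = int(pos)
        orig, new = _parse_mutation(value)
        if pos < 1 or pos > spec.length:
            raise DesignError(f"mutation position {pos} outside 1..{spec.length}")
        if seq[pos - 1] == "*":
            raise DesignError(f"cannot mutate staple position {pos}")
        if orig is not None and seq[pos - 1] != orig:
            raise DesignError(f"position {pos} is {seq[pos - 1]}, not {orig}")
        log[pos] = (seq[pos - 1], new)
        seq[pos - 1] = new
    return replace(spec, sequence="".join(seq), mutations=log)


def audit(spec: PeptideSpec, charge_table: dict | None = None) -> dict:
    """Sequence-level report: charges, cationic positions, length, staple.

    '*' positions count as neutral (alanine-like); capped termini add no
    charge.
    """
    table = dict(DEFAULT_CHARGE_TABLE if charge_table is None else charge_table)
    charges = {pos: table.get(aa, 0) for pos, aa in enumerate(spec.sequence, start=1) if aa != "*"}
    positive = [p for p, q in charges.items() if q > 0]
    negative = [p for p, q in charges.items() if q < 0]
    return {
        "name": spec.name,
        "length": spec.length,
        "net_charge": sum(charges.values()),
        "n_positive": len(positive),
        "positive_positions": positive,
        "negative_positions": negative,
        "staple": spec.staple,
        "termini": spec.termini,
    }


def _load_registry_file() -> dict:
    with resources.files("cgdock.data").joinpath("table_peptides.yaml").open() as fh:
        return yaml.safe_load(fh)


def registry() -> dict[str, PeptideSpec]:
    """The ten shipped peptide rows, as immutable specs."""
    raw = _load_registry_file()
    out = {}
    for row in raw["peptides"]:
        out[row["name"]] = PeptideSpec(
            name=row["name"], sequence=row["sequence"], template=row["template"],
            mutations={int(k): _parse_mutation(v) for k, v in (row.get("mutations") or {}).items()},
        )
    return out


def templates() -> dict[str, str]:
    return dict(_load_registry_file()["templates"])


def reconstruct(name: str) -> PeptideSpec:
    """Rebuild a registry entry from its template via the design operations.

    Stapling precedes mutation for rows whose mutation positions are quoted
    against the stapled sequence; for rows with no staple the mutations are
    applied directly.  Used to check registry fidelity.
    """
    raw = _load_registry_file()
    row = next(r for r in raw["peptides"] if r["name"] == name)
    spec = PeptideSpec(name=name, sequence=raw["templates"][row["template"]],
                       template=row["template"])
    mutations = row.get("mutations") or {}
    if row.get("staple") is not None:
        staple_i = int(row["staple"])
        # mutations never touch staple sites, so the two orders agree; apply
        # staple first to mirror the published construction
        spec = apply_staple(spec, staple_i)
    if mutations:
        spec = apply_mutations(spec, mutations)
    return spec
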