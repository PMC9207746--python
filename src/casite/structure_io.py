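"""Minimal hierarchical protein model read from PDB files.

The model keeps exactly what template work needs: chains of residues with
named heavy atoms and coordinates in Angstrom.  Reading applies the usual
reductions for site analysis -- first MODEL only, one conformation per atom
(highest occupancy), no hydrogens, HETATM excluded unless whitelisted.

The :class:`FunctionalAtomTable` defines, per residue type, which side-chain
heteroatoms carry the catalytic chemistry ("functional atoms") and which
atom names within a residue are chemically symmetric and therefore
interchangeable during matching (e.g. the two carboxylate oxygens of Asp).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import gemmi
import numpy as np

from .errors import MissingAtomsError, PDBParseError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "FunctionalAtomTable",
    "DEFAULT_TABLE",
    "BACKBONE_ATOMS",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "assemble_structure",
]

BACKBONE_ATOMS: tuple[str, str, str] = ("N", "CA", "C")


@dataclass(frozen=True)
class Atom:
    """A heavy atom with its PDB name and position in Angstrom."""

    name: str
    element: str
    pos: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    serial: int = 0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    """One residue: author numbering, 3-letter type, ordered atoms."""

    chain: str
    seqnum: str  # author residue number plus insertion code, e.g. "52" or "52A"
    restype: str
    atoms: list[Atom]
    chain_index: int = 0

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise MissingAtomsError(
            f"residue {self.chain}:{self.seqnum} ({self.restype}) has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def id(self) -> tuple[str, str]:
        return (self.chain, self.seqnum)


@dataclass
class Structure:
    """A single-model protein structure: ordered chains of residues."""

    id: str
    chains: dict[str, list[Residue]]
    model: int = 1

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def get_residue(self, chain: str, seqnum: str) -> Residue:
        for res in self.chains.get(chain, []):
            if res.seqnum == str(seqnum):
                return res
        raise KeyError(f"no residue {chain}:{seqnum} in structure {self.id}")


@dataclass(frozen=True)
class FunctionalAtomTable:
    """Which atoms per residue type are functional, and which are symmetric.

    ``functional`` maps a residue type to the ordered side-chain heteroatoms
    that perform its chemistry.  ``equivalence`` lists sets of atom names
    within one residue type that are chemically indistinguishable (carboxylate
    oxygens, guanidinium nitrogens, amide N/O endpoints); a matcher may swap
    atoms within a set.  The backbone selection is the fixed N, CA, C triple,
    enough to pin the local main-chain frame of every residue type.
    """

    functional: Mapping[str, tuple[str, ...]]
    equivalence: Mapping[str, tuple[frozenset[str], ...]]
    backbone: tuple[str, ...] = BACKBONE_ATOMS

    def equivalence_set(self, restype: str, atom_name: str) -> frozenset[str]:
        """The set of names interchangeable with ``atom_name`` (incl. itself)."""
        for s in self.equivalence.get(restype, ()):
            if atom_name in s:
                return s
        return frozenset({atom_name})


_FUNCTIONAL = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",),
}

_EQUIVALENCE = {
    "ASP": (frozenset({"OD1", "OD2"}),),
    "GLU": (frozenset({"OE1", "OE2"}),),
    "ASN": (frozenset({"OD1", "ND2"}),),
    "GLN": (frozenset({"OE1", "NE2"}),),
    "ARG": (frozenset({"NH1", "NH2"}),),
    "HIS": (frozenset({"ND1", "NE2"}),),
}


def default_table(his_equivalence: bool = True) -> FunctionalAtomTable:
    """The standard functional-atom table.

    ``his_equivalence`` controls whether the two imidazole nitrogens of His
    may be swapped during matching; superposition correspondences never swap
    them regardless.
    """
    equiv = dict(_EQUIVALENCE)
    if not his_equivalence:
        equiv.pop("HIS")
    return FunctionalAtomTable(functional=dict(_FUNCTIONAL), equivalence=equiv)


DEFAULT_TABLE = default_table()


# --- PDB reading -----------------------------------------------------------

def _validate_record_lines(text: str) -> None:
    """Light column check so malformed ATOM records fail with a line number.

    gemmi is deliberately permissive; we require the fixed-format essentials
    (record length through the coordinate block, parseable floats) up front.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(
                f"line {lineno}: {rec} record shorter than the coordinate block"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: cannot parse {what} coordinate "
                    f"from columns {lo + 1}-{hi}"
                ) from None
        occ = line[54:60].strip()
        if occ:
            try:
                float(occ)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: cannot parse occupancy from columns 55-60"
                ) from None


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties to the first altloc."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        kept.append(min(group, key=lambda a: (-a.occupancy, a.altloc)))
    return kept


def read_pdb(
    source,
    structure_id: str = "",
    hetatm_whitelist: Sequence[str] = (),
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first MODEL is kept; hydrogens are dropped; HETATM residues are
    excluded unless their residue name appears in ``hetatm_whitelist``;
    alternate locations are resolved to the highest-occupancy copy (ties go
    to the alphabetically first altloc).

    ``source`` may be a string of PDB text, a text stream, or a path.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".pdb", ".ent")):
            with open(text) as fh:
                text = fh.read()
    _validate_record_lines(text)

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBParseError(f"structure {structure_id or st.name!r}: no ATOM records")
    model = st[0]
    whitelist = {w.upper() for w in hetatm_whitelist}

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and res.name.upper() not in whitelist:
                continue
            atoms: list[Atom] = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        altloc=atom.altloc.strip("\x00").strip(),
                        occupancy=float(np.clip(atom.occ, 0.0, 1.0)),
                        serial=atom.serial,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            seqnum = f"{res.seqid.num}{(res.seqid.icode or ' ').strip()}"
            residues = chains.setdefault(chain.name, [])
            residues.append(
                Residue(
                    chain=chain.name,
                    seqnum=seqnum,
                    restype=res.name.upper(),
                    atoms=atoms,
                    chain_index=len(residues),
                )
            )
    chains = {c: r for c, r in chains.items() if r}
    if not chains:
        raise PDBParseError(
            f"structure {structure_id or st.name!r}: no residues retained"
        )
    return Structure(id=structure_id or st.name, chains=chains, model=model.num)


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` back to fixed-column PDB text.

    Output is deterministic: atoms are renumbered serially in storage order,
    coordinates are written %8.3f.  Round-trips through :func:`read_pdb`
    reproduce the retained content.
    """
    lines = []
    serial = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                num = res.seqnum
                icode = " "
                if num and not num[-1].isdigit():
                    num, icode = num[:-1], num[-1]
                lines.append(
                    f"ATOM  {serial:5d} {name}{a.altloc or ' '}"
                    f"{res.restype:>3s} {chain_id:1s}{int(num):4d}{icode}   "
                    f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def select_atoms(
    residue: Residue,
    mode: str,
    table: FunctionalAtomTable = DEFAULT_TABLE,
) -> list[Atom]:
    """Return the residue's functional or backbone atoms in canonical order.

    Order comes from the table, never from file order.  Missing atoms raise
    :class:`MissingAtomsError` naming every absent atom.
    """
    if mode == "backbone":
        names = table.backbone
    elif mode == "functional":
        if residue.restype not in table.functional:
            raise MissingAtomsError(
                f"residue type {residue.restype!r} has no functional-atom definition"
            )
        names = table.functional[residue.restype]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")

    missing = [n for n in names if not residue.has_atom(n)]
    if missing:
        raise MissingAtomsError(
            f"residue {residue.chain}:{residue.seqnum} ({residue.restype}) "
            f"missing {mode} atoms: {', '.join(missing)}"
        )
    return [residue.atom(n) for n in names]


def assemble_structure(
    structure_id: str, chains: Mapping[str, Sequence[Residue]]
) -> Structure:
    """Build a Structure from in-memory residues, fixing chain indices."""
    out: dict[str, list[Residue]] = {}
    for chain_id, residues in chains.items():
        fixed = []
        for i, res in enumerate(residues):
            fixed.append(
                Residue(
                    chain=chain_id,
                    seqnum=res.seqnum,
                    restype=res.restype,
                    atoms=list(res.atoms),
                    chain_index=i,
                )
            )
        out[chain_id] = fixed
    if not any(out.values()):
        raise ValueError("structure must contain at least one residue")
    return Structure(id=structure_id, chains=out)
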