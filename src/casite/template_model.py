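"""Coordinate templates: geometry plus fuzzy matching constraints.

A coordinate template is an ordered set of atom positions, grouped by
residue, together with the constraints a match must satisfy: per-atom
fuzzy alternatives (which residue types and atom names may occupy that
position), an inter-atom distance tolerance ``delta``, and a best-fit RMSD
acceptance threshold ``rho``.  Distance constraints are derived from the
positions themselves as the full pairwise distance matrix.

Fuzzy residue groups capture chemically conservative swaps seen in real
catalytic sites: the hydroxyl carriers Ser/Thr/Tyr, the carboxylates
Asp/Glu, and the amides Asn/Gln are matched interchangeably.  Atom-level
fuzziness covers symmetric side-chain atoms (Asp OD1/OD2 and friends).
Cross-type atom correspondence is positional within the functional-atom
table: the i-th functional atom of one type corresponds to the i-th of any
type in the same fuzz group (Ser OG <-> Thr OG1 <-> Tyr OH; Asp OD1/OD2 <->
Glu OE1/OE2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import MissingAtomsError, TemplateFormatError
from .structure_io import (
    DEFAULT_TABLE,
    FunctionalAtomTable,
    Residue,
    select_atoms,
)

__all__ = [
    "TemplateAtom",
    "Template",
    "FuzzGroups",
    "DEFAULT_FUZZ",
    "build_template",
    "write_template",
    "read_template",
]

DEFAULT_DELTA = 1.0  # Angstrom, inter-atom distance tolerance
DEFAULT_RHO = 2.0  # Angstrom, RMSD acceptance threshold

WILDCARD_RESTYPE = "*"  # backbone atoms match any residue type


@dataclass(frozen=True)
class FuzzGroups:
    """Sets of residue types that templates may match interchangeably."""

    residue_groups: tuple[frozenset[str], ...] = (
        frozenset({"SER", "THR", "TYR"}),
        frozenset({"ASP", "GLU"}),
        frozenset({"ASN", "GLN"}),
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.residue_groups:
            if seen & g:
                raise ValueError("fuzz groups must be disjoint")
            seen |= g

    def group_of(self, restype: str) -> frozenset[str]:
        for g in self.residue_groups:
            if restype in g:
                return g
        return frozenset({restype})


DEFAULT_FUZZ = FuzzGroups()


@dataclass
class TemplateAtom:
    """One template position with its fuzzy residue/atom alternatives.

    ``allowed`` maps residue type -> atom names acceptable at this position
    for that type; the wildcard type ``*`` (backbone templates) accepts any
    residue.  ``name`` is the canonical atom name in the source residue.
    """

    pos: np.ndarray
    group: int
    canonical_restype: str
    name: str
    allowed: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if self.canonical_restype not in self.allowed and WILDCARD_RESTYPE not in self.allowed:
            raise ValueError(
                f"canonical residue type {self.canonical_restype!r} absent from allowed map"
            )
        if any(not names for names in self.allowed.values()):
            raise ValueError("every allowed atom-name list must be non-empty")

    def allowed_names(self, restype: str) -> tuple[str, ...]:
        """Atom names this position accepts for ``restype`` ('' if none)."""
        if restype in self.allowed:
            return self.allowed[restype]
        return self.allowed.get(WILDCARD_RESTYPE, ())


@dataclass
class Template:
    """An ordered coordinate template with matching constraints."""

    id: str
    atoms: list[TemplateAtom]
    mode: str  # "functional" or "backbone"
    delta: float = DEFAULT_DELTA
    rho: float = DEFAULT_RHO

    def __post_init__(self) -> None:
        if self.mode not in ("functional", "backbone"):
            raise ValueError(f"unknown template mode {self.mode!r}")
        if len(self.atoms) < 3:
            raise ValueError("a template needs at least 3 atoms")
        if self.n_groups < 2:
            raise ValueError("a template needs at least 2 residue groups")
        if self.delta <= 0 or self.rho <= 0:
            raise ValueError("delta and rho must be positive")

    @property
    def n_groups(self) -> int:
        return max(a.group for a in self.atoms) + 1

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([a.pos for a in self.atoms])

    @property
    def dmat(self) -> np.ndarray:
        """Pairwise distance matrix of template atom positions (Angstrom)."""
        return squareform(pdist(self.coords))

    def group_atom_indices(self, group: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.group == group]

    def group_restypes(self) -> list[str]:
        seen: dict[int, str] = {}
        for a in self.atoms:
            seen.setdefault(a.group, a.canonical_restype)
        return [seen[g] for g in range(self.n_groups)]


def _functional_allowed(
    restype: str,
    atom_index: int,
    table: FunctionalAtomTable,
    fuzz: FuzzGroups,
) -> dict[str, tuple[str, ...]]:
    """Fuzzy alternatives for the ``atom_index``-th functional atom of ``restype``.

    For each residue type in the fuzz group with the same functional-atom
    count, the positionally corresponding atom name is expanded across its
    within-residue equivalence set.
    """
    n_atoms = len(table.functional[restype])
    allowed: dict[str, tuple[str, ...]] = {}
    for alt in sorted(fuzz.group_of(restype)):
        names = table.functional.get(alt)
        if names is None or len(names) != n_atoms:
            continue  # no positional correspondence to this type
        base = names[atom_index]
        equiv = table.equivalence_set(alt, base)
        allowed[alt] = tuple(sorted(equiv, key=lambda n: (names.index(n) if n in names else 99, n)))
    return allowed


def build_template(
    site_residues: Sequence[Residue],
    mode: str,
    table: FunctionalAtomTable = DEFAULT_TABLE,
    fuzz: FuzzGroups = DEFAULT_FUZZ,
    template_id: str = "template",
    delta: float = DEFAULT_DELTA,
    rho: float = DEFAULT_RHO,
) -> Template:
    """Build a coordinate template from an annotated catalytic site.

    One residue group per input residue; atom order within each group is the
    canonical table order, independent of file order.  In functional mode
    each atom's ``allowed`` map spans the residue's fuzz group and the
    symmetric-atom equivalence sets; in backbone mode atoms are N, CA, C and
    any residue type is acceptable.
    """
    if len(site_residues) < 2:
        raise ValueError("a template needs at least 2 residues")
    atoms: list[TemplateAtom] = []
    for g, res in enumerate(site_residues):
        selected = select_atoms(res, mode, table)
        for i, atom in enumerate(selected):
            if mode == "functional":
                allowed = _functional_allowed(res.restype, i, table, fuzz)
            else:
                allowed = {WILDCARD_RESTYPE: (atom.name,)}
            atoms.append(
                TemplateAtom(
                    pos=atom.xyz,
                    group=g,
                    canonical_restype=res.restype,
                    name=atom.name,
                    allowed=allowed,
                )
            )
    return Template(
        id=template_id, atoms=atoms, mode=mode, delta=delta, rho=rho
    )


# --- template text format --------------------------------------------------
#
# REMARK TEMPLATE <id> MODE <functional|backbone> DELTA <x> RHO <x>
# REMARK ALLOW <atom-index> <RESTYPE>:<name1>[,<name2>...]      (one per type)
# ATOM records carrying the canonical residue type / atom name, residue
# number = group index + 1, coordinates %8.3f.  Human-readable, diff-able,
# loadable in structure viewers.


def write_template(t: Template, sink) -> None:
    """Write a template to a text sink in the template file format."""
    own = hasattr(sink, "write")
    fh = sink if own else open(sink, "w")
    try:
        fh.write(
            f"REMARK TEMPLATE {t.id} MODE {t.mode} DELTA {t.delta:g} RHO {t.rho:g}\n"
        )
        for i, a in enumerate(t.atoms):
            for restype in sorted(a.allowed):
                names = ",".join(a.allowed[restype])
                fh.write(f"REMARK ALLOW {i} {restype}:{names}\n")
        for i, a in enumerate(t.atoms):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {i + 1:5d} {name} {a.canonical_restype:>3s} "
                f"A{a.group + 1:4d}    "
                f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")
    finally:
        if not own:
            fh.close()


def read_template(source) -> Template:
    """Read a template file; distance constraints are recomputed from coords."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
    lines = text.splitlines()

    header = None
    allow: dict[int, dict[str, tuple[str, ...]]] = {}
    atom_rows: list[tuple[str, str, int, np.ndarray]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("REMARK TEMPLATE"):
            parts = line.split()
            try:
                header = {
                    "id": parts[2],
                    "mode": parts[parts.index("MODE") + 1],
                    "delta": float(parts[parts.index("DELTA") + 1]),
                    "rho": float(parts[parts.index("RHO") + 1]),
                }
            except (ValueError, IndexError):
                raise TemplateFormatError(
                    f"line {lineno}: malformed REMARK TEMPLATE header"
                ) from None
        elif line.startswith("REMARK ALLOW"):
            parts = line.split()
            try:
                idx = int(parts[2])
                restype, names = parts[3].split(":")
                allow.setdefault(idx, {})[restype] = tuple(names.split(","))
            except (ValueError, IndexError):
                raise TemplateFormatError(
                    f"line {lineno}: malformed REMARK ALLOW record"
                ) from None
        elif line.startswith("ATOM"):
            try:
                name = line[12:16].strip()
                restype = line[17:20].strip()
                group = int(line[22:26]) - 1
                pos = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError:
                raise TemplateFormatError(
                    f"line {lineno}: malformed template ATOM record"
                ) from None
            atom_rows.append((name, restype, group, pos))
        elif line.strip() and not line.startswith(("REMARK", "END", "TER")):
            raise TemplateFormatError(
                f"line {lineno}: unknown record {line.split()[0]!r}"
            )
    if header is None:
        raise TemplateFormatError("missing REMARK TEMPLATE header")
    if not atom_rows:
        raise TemplateFormatError("template file contains no ATOM records")

    groups = sorted({g for _, _, g, _ in atom_rows})
    if groups != list(range(len(groups))):
        raise TemplateFormatError(
            f"group indices are not contiguous from 1: found {[g + 1 for g in groups]}"
        )
    atoms = []
    for i, (name, restype, group, pos) in enumerate(atom_rows):
        allowed = allow.get(i)
        if not allowed:
            allowed = (
                {WILDCARD_RESTYPE: (name,)}
                if header["mode"] == "backbone"
                else {restype: (name,)}
            )
        atoms.append(
            TemplateAtom(
                pos=pos,
                group=group,
                canonical_restype=restype,
                name=name,
                allowed=allowed,
            )
        )
    return Template(
        id=header["id"],
        atoms=atoms,
        mode=header["mode"],
        delta=header["delta"],
        rho=header["rho"],
    )
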