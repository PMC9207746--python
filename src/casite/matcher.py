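"""Template matching by distance-constrained depth-first search.

The search assigns template residue groups to structure residues, cheapest
group (fewest candidates) first, pruning any partial assignment in which an
assigned atom pair deviates from the template's internal distance by more
than ``delta``.  Complete assignments are Kabsch-fitted and kept when their
best-fit RMSD is at most ``rho``.  Matches over the same unordered residue
set are deduplicated to the lowest-RMSD atom mapping, so symmetric-atom
swaps (e.g. Asp OD1/OD2) never produce duplicate hits.

There is no analytic significance model here; ``empirical_significance``
estimates how often a decoy residue combination beats a match's RMSD by
seeded sampling over user-supplied decoy structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CasiteError
from .geometry import Transform, superpose
from .structure_io import Atom, Residue, Structure
from .template_model import Template

__all__ = [
    "Match",
    "MatchList",
    "MatchParams",
    "candidates",
    "match_template",
    "check_sequence_order",
    "empirical_significance",
    "write_matches_tsv",
]


@dataclass
class MatchParams:
    """Knobs of a template search (Angstrom tolerances)."""

    delta: float = 1.0
    rho: float = 2.0
    max_matches: int = 10_000
    same_chain_only: bool = False

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.rho <= 0:
            raise ValueError("delta and rho must be positive")


@dataclass
class Match:
    """One template occurrence in a structure."""

    template_id: str
    structure_id: str
    residues: tuple[Residue, ...]  # per template group, in group order
    atom_map: tuple[Atom, ...]  # per template atom index
    rmsd: float
    transform: Transform  # template frame -> structure frame
    in_sequence_order: bool = False
    multi_chain: bool = False

    @property
    def assignment(self) -> dict[int, tuple[str, str, str]]:
        return {
            g: (r.chain, r.seqnum, r.restype) for g, r in enumerate(self.residues)
        }

    @property
    def residue_key(self) -> frozenset[tuple[str, str]]:
        return frozenset(r.id for r in self.residues)

    def describe_residues(self) -> str:
        return ";".join(
            f"{r.chain}:{r.seqnum}:{r.restype}" for r in self.residues
        )


class MatchList(list):
    """A list of matches; ``truncated`` flags a hit-cap overflow."""

    truncated: bool = False


def _seqnum_key(seqnum: str) -> tuple[int, str]:
    num = seqnum.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    icode = seqnum[len(num):]
    return (int(num), icode)


def candidates(
    t: Template, s: Structure
) -> list[list[tuple[Residue, list[tuple[Atom, ...]]]]]:
    """Per template group: residues that can fill it, with atom mappings.

    A residue qualifies for a group when every template atom of the group
    accepts its residue type and all required atom names resolve.  Each atom
    mapping is an injective choice of one structure atom per template atom
    of the group; symmetric alternatives (e.g. the two Asp carboxylate
    oxygens) yield several mappings.
    """
    out = []
    for g in range(t.n_groups):
        idxs = t.group_atom_indices(g)
        group_hits: list[tuple[Residue, list[tuple[Atom, ...]]]] = []
        for res in s.residues():
            per_atom: list[list[Atom]] = []
            ok = True
            for i in idxs:
                names = t.atoms[i].allowed_names(res.restype)
                pool = [res.atom(n) for n in names if res.has_atom(n)]
                if not pool:
                    ok = False
                    break
                per_atom.append(pool)
            if not ok:
                continue
            mappings = [
                combo
                for combo in itertools.product(*per_atom)
                if len({a.name for a in combo}) == len(combo)
            ]
            if mappings:
                group_hits.append((res, mappings))
        out.append(group_hits)
    return out


def _distances_ok(
    coords: dict[int, np.ndarray], new_idxs: list[int], dmat: np.ndarray, delta: float
) -> bool:
    """Check |d_structure - d_template| <= delta for all pairs touching new atoms."""
    placed = list(coords)
    for i in new_idxs:
        pi = coords[i]
        for j in placed:
            if j == i:
                continue
            d = float(np.linalg.norm(pi - coords[j]))
            if abs(d - dmat[i, j]) > delta:
                return False
    return True


def match_template(
    t: Template, s: Structure, p: MatchParams | None = None
) -> MatchList:
    """All occurrences of template ``t`` in structure ``s``.

    Results are sorted by RMSD ascending (ties by chain, then residue
    number); one match is reported per unordered residue set, carrying its
    best atom mapping.
    """
    p = p or MatchParams(delta=t.delta, rho=t.rho)
    cand = candidates(t, s)
    results: dict[frozenset, Match] = {}
    truncated = False
    if any(not c for c in cand):
        return MatchList()

    order = sorted(range(t.n_groups), key=lambda g: len(cand[g]))
    group_idxs = {g: t.group_atom_indices(g) for g in range(t.n_groups)}
    dmat = t.dmat
    n_found = 0

    assigned_res: dict[int, Residue] = {}
    assigned_map: dict[int, tuple[Atom, ...]] = {}
    coords: dict[int, np.ndarray] = {}

    def dfs(depth: int) -> None:
        nonlocal n_found, truncated
        if truncated:
            return
        if depth == len(order):
            _record_complete()
            return
        g = order[depth]
        idxs = group_idxs[g]
        used = {r.id for r in assigned_res.values()}
        for res, mappings in cand[g]:
            if res.id in used:
                continue
            if p.same_chain_only and assigned_res:
                if any(r.chain != res.chain for r in assigned_res.values()):
                    continue
            for mapping in mappings:
                for i, atom in zip(idxs, mapping):
                    coords[i] = atom.xyz
                if _distances_ok(coords, idxs, dmat, p.delta):
                    assigned_res[g] = res
                    assigned_map[g] = mapping
                    dfs(depth + 1)
                    del assigned_res[g], assigned_map[g]
                for i in idxs:
                    del coords[i]
                if truncated:
                    return

    def _record_complete() -> None:
        nonlocal n_found, truncated
        atom_map: list[Atom] = [None] * len(t.atoms)  # type: ignore[list-item]
        for g in range(t.n_groups):
            for i, atom in zip(group_idxs[g], assigned_map[g]):
                atom_map[i] = atom
        target = np.vstack([a.xyz for a in atom_map])
        transform, rmsd = superpose(t.coords, target)
        if rmsd > p.rho:
            return
        residues = tuple(assigned_res[g] for g in range(t.n_groups))
        m = Match(
            template_id=t.id,
            structure_id=s.id,
            residues=residues,
            atom_map=tuple(atom_map),
            rmsd=rmsd,
            transform=transform,
        )
        key = m.residue_key
        prev = results.get(key)
        if prev is None or m.rmsd < prev.rmsd:
            if prev is None:
                n_found += 1
                if n_found > p.max_matches:
                    truncated = True
                    return
            results[key] = m

    dfs(0)

    out = MatchList(results.values())
    for m in out:
        m.in_sequence_order = check_sequence_order(m)
    out.sort(
        key=lambda m: (
            m.rmsd,
            tuple((r.chain, _seqnum_key(r.seqnum)) for r in m.residues),
        )
    )
    out.truncated = truncated
    return out


def check_sequence_order(m: Match) -> bool:
    """True iff matched residues follow the template's group order in sequence.

    Requires all matched residues on a single chain; a multi-chain match is
    flagged on the Match and reported as False.
    """
    chains = {r.chain for r in m.residues}
    if len(chains) > 1:
        m.multi_chain = True
        return False
    idx = [r.chain_index for r in m.residues]
    return all(a < b for a, b in zip(idx, idx[1:]))


def empirical_significance(
    m: Match,
    decoy_structures: Sequence[Structure],
    template: Template,
    n_samples: int = 200,
    seed: int = 0,
) -> float:
    """Chance of a decoy residue combination fitting at least as well.

    Samples ``n_samples`` random residue-type-compatible combinations (with
    their symmetric atom mappings) from the decoy structures, Kabsch-fits
    each to the template, and returns the add-one-smoothed fraction with
    best-fit RMSD <= ``m.rmsd``: ``(1 + hits) / (1 + n_effective)``.  This is
    an empirical tail probability, not an analytic significance model; it is
    monotone non-decreasing in the match RMSD.
    """
    if not decoy_structures:
        raise ValueError("at least one decoy structure is required")
    rng = np.random.default_rng(seed)

    per_structure = []
    for s in decoy_structures:
        cand = candidates(template, s)
        if all(c for c in cand):
            per_structure.append(cand)
    if not per_structure:
        raise CasiteError(
            "no decoy structure offers a residue-type-compatible combination"
        )

    hits = 0
    n_effective = 0
    for _ in range(n_samples):
        cand = per_structure[rng.integers(len(per_structure))]
        combo_res: list[Residue] = []
        combo_atoms: list[Atom] = []
        ok = True
        for g in range(template.n_groups):
            res, mappings = cand[g][rng.integers(len(cand[g]))]
            if any(res.id == r.id for r in combo_res):
                ok = False
                break
            mapping = mappings[rng.integers(len(mappings))]
            combo_res.append(res)
            combo_atoms.extend(mapping)
        if not ok:
            continue
        n_effective += 1
        coords = np.vstack([a.xyz for a in combo_atoms])
        _, rmsd = superpose(template.coords, coords)
        if rmsd <= m.rmsd:
            hits += 1
    if n_effective == 0:
        raise CasiteError("no valid decoy combination was drawn")
    return (1 + hits) / (1 + n_effective)


def write_matches_tsv(
    matches: Iterable[Match],
    sink,
    significance: dict[int, float] | None = None,
) -> None:
    """Write a match report as TSV."""
    own = hasattr(sink, "write")
    fh = sink if own else open(sink, "w")
    try:
        cols = [
            "structure_id",
            "template_id",
            "rmsd",
            "residues",
            "in_sequence_order",
        ]
        if significance is not None:
            cols.append("significance")
        fh.write("\t".join(cols) + "\n")
        for i, m in enumerate(matches):
            row = [
                m.structure_id,
                m.template_id,
                f"{m.rmsd:.4f}",
                m.describe_residues(),
                str(m.in_sequence_order).lower(),
            ]
            if significance is not None:
                row.append(f"{significance.get(i, float('nan')):.4g}")
            fh.write("\t".join(row) + "\n")
    finally:
        if not own:
            fh.close()
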