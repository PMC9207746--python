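"""Evolutionary interpretation of template matches.

A structure queried with two templates of the same site -- one over backbone
atoms, one over side-chain functional atoms -- separates two situations: a
functional-atom match accompanied by a backbone match over the same residues
means the main chain also adopts the template geometry (consistent with
homology), while a functional-atom match with no corresponding backbone
match means the side-chain chemistry has been rebuilt on an unrelated
scaffold -- the signature of convergent evolution.

Against an explicit reference site and a pairwise sequence alignment, each
matched residue is further classified: conserved (same type, same aligned
position), functional substitution (chemically analogous type at the same
aligned position, e.g. Asp -> Glu), or spatial substitution (the functional
group arrives from a different sequence position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .matcher import Match, MatchList, MatchParams, match_template
from .structure_io import Residue, Structure
from .template_model import Template

__all__ = [
    "BACKBONE_SUPPORTED",
    "PUTATIVE_CONVERGENT",
    "ScanResult",
    "SubstitutionCall",
    "Alignment",
    "scan_structures",
    "align_sequences",
    "classify_substitutions",
    "summarize_scan",
    "chain_sequence",
]

logger = logging.getLogger(__name__)

BACKBONE_SUPPORTED = "backbone_supported"
PUTATIVE_CONVERGENT = "putative_convergent"

CONSERVED = "conserved"
FUNCTIONAL_SUBSTITUTION = "functional_substitution"
SPATIAL_SUBSTITUTION = "spatial_substitution"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

GAP_SCORE = -8.0  # linear gap penalty for the pairwise global alignment


@dataclass
class ScanResult:
    """Paired backbone/functional match sets for one structure."""

    structure_id: str
    functional_matches: MatchList
    backbone_matches: MatchList
    classifications: list[str]  # parallel to functional_matches

    def n_class(self, label: str) -> int:
        return sum(1 for c in self.classifications if c == label)


@dataclass
class SubstitutionCall:
    """Per-group comparison of a match against the reference site."""

    group: int
    template_restype: str
    matched_restype: str
    aligned_position_same: bool
    call: str | None  # None when the residue could not be aligned
    unalignable: bool = False


@dataclass
class Alignment:
    """A pairwise global alignment as matched chain-index pairs."""

    pairs: tuple[tuple[int, int], ...]
    score: float

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise ValueError("aligned pairs must increase in both sequences")

    def partner_of(self, index_a: int) -> int | None:
        for a, b in self.pairs:
            if a == index_a:
                return b
        return None

    def aligned_b_indices(self) -> frozenset[int]:
        return frozenset(b for _, b in self.pairs)


def scan_structures(
    structures: Sequence[Structure],
    functional_template: Template,
    backbone_template: Template,
    params: MatchParams | None = None,
    overlap_min: float = 1.0,
) -> list[ScanResult]:
    """Query every structure with the backbone and functional templates.

    Both searches use identical parameters.  A functional match is
    ``backbone_supported`` when some backbone match covers at least
    ``overlap_min`` of its residues (default: all of them); otherwise it is
    ``putative_convergent``.
    """
    if functional_template.n_groups != backbone_template.n_groups:
        raise ValueError(
            "functional and backbone templates must have the same group count"
        )
    if not 0.0 < overlap_min <= 1.0:
        raise ValueError("overlap_min must be in (0, 1]")
    results = []
    for s in structures:
        fm = match_template(functional_template, s, params)
        bm = match_template(backbone_template, s, params)
        backbone_sets = [m.residue_key for m in bm]
        classifications = []
        for m in fm:
            need = overlap_min * len(m.residue_key)
            supported = any(
                len(m.residue_key & b) >= need - 1e-9 for b in backbone_sets
            )
            classifications.append(
                BACKBONE_SUPPORTED if supported else PUTATIVE_CONVERGENT
            )
        results.append(
            ScanResult(
                structure_id=s.id,
                functional_matches=fm,
                backbone_matches=bm,
                classifications=classifications,
            )
        )
    return results


def _aligner() -> PairwiseAligner:
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "X" or b == "X":
                mat[a, b] = 0.0  # unknown residues are neutral
            else:
                mat[a, b] = blosum[a, b]
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def chain_sequence(residues: Sequence[Residue]) -> str:
    """One-letter sequence of a residue list; unknown types become X."""
    return "".join(THREE_TO_ONE.get(r.restype, "X") for r in residues)


def align_sequences(seq_a: str, seq_b: str) -> Alignment:
    """Global pairwise alignment (BLOSUM62, linear gap -8), deterministic.

    Unknown residue codes are treated as X, scoring 0 against everything.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    clean_a = "".join(c if c in THREE_TO_ONE.values() else "X" for c in seq_a.upper())
    clean_b = "".join(c if c in THREE_TO_ONE.values() else "X" for c in seq_b.upper())
    alignments = _aligner().align(clean_a, clean_b)
    best = alignments[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*best.aligned):
        for k in range(a_end - a_start):
            pairs.append((a_start + k, b_start + k))
    return Alignment(pairs=tuple(pairs), score=float(best.score))


def classify_substitutions(
    match: Match,
    reference_residues: Sequence[Residue],
    alignment: Alignment,
    target_chain: str | None = None,
) -> list[SubstitutionCall]:
    """Compare a match's residues with the reference site's, group by group.

    ``alignment`` pairs chain indices of the reference chain (side A) with
    the matched structure's chain (side B).  A residue is conserved when the
    type is unchanged and its position aligns to the reference catalytic
    position; a type change at the aligned position is a functional
    substitution; any residue arriving from a non-aligned position is a
    spatial substitution.  When ``target_chain`` is given, matched residues
    on any other chain are not covered by the alignment: they are flagged
    unalignable and receive no call.
    """
    if len(reference_residues) != len(match.residues):
        raise ValueError("reference site and match must share group structure")
    calls = []
    for g, (ref, got) in enumerate(zip(reference_residues, match.residues)):
        if target_chain is not None and got.chain != target_chain:
            calls.append(
                SubstitutionCall(
                    group=g,
                    template_restype=ref.restype,
                    matched_restype=got.restype,
                    aligned_position_same=False,
                    call=None,
                    unalignable=True,
                )
            )
            continue
        partner = alignment.partner_of(ref.chain_index)
        same_pos = partner is not None and partner == got.chain_index
        if same_pos:
            call = CONSERVED if got.restype == ref.restype else FUNCTIONAL_SUBSTITUTION
        else:
            call = SPATIAL_SUBSTITUTION
        calls.append(
            SubstitutionCall(
                group=g,
                template_restype=ref.restype,
                matched_restype=got.restype,
                aligned_position_same=same_pos,
                call=call,
            )
        )
    return calls


def summarize_scan(
    results: Sequence[ScanResult],
    ec_map: Mapping[str, str] | None = None,
    ec_filter: str | None = None,
) -> pd.DataFrame:
    """Per-structure summary table of a paired scan.

    With ``ec_map`` (structure id -> EC number string) and ``ec_filter``
    (prefix, e.g. ``"3."``) only structures whose EC starts with the prefix
    are retained -- the hook used to focus on, say, hydrolase annotations.
    """
    if not results:
        raise ValueError("no scan results to summarize")
    rows = []
    for r in results:
        if ec_filter is not None:
            ec = (ec_map or {}).get(r.structure_id, "")
            if not ec.startswith(ec_filter):
                continue
        fm = r.functional_matches
        bm = r.backbone_matches
        rows.append(
            {
                "structure_id": r.structure_id,
                "n_functional": len(fm),
                "n_backbone": len(bm),
                "n_backbone_supported": r.n_class(BACKBONE_SUPPORTED),
                "n_putative_convergent": r.n_class(PUTATIVE_CONVERGENT),
                "best_rmsd_functional": min((m.rmsd for m in fm), default=np.nan),
                "best_rmsd_backbone": min((m.rmsd for m in bm), default=np.nan),
                "any_in_sequence_order": any(m.in_sequence_order for m in fm),
                "ec": (ec_map or {}).get(r.structure_id, ""),
            }
        )
    return pd.DataFrame(rows)
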