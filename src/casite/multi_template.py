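"""Variation-aware template extraction.

A flexible active site is poorly served by one average template.  Here the
homologous sites of a family are put into a shared functional-atom
correspondence, superposed, clustered on pairwise best-fit RMSD with an
agglomerative dendrogram, and the tree is cut at a prune height to yield
conformational clusters.  Each cluster contributes one representative
template: the member site closest to the cluster's iterative consensus.
Cutting lower gives finer clusters; cutting higher merges conformations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import EnsembleError, MissingAtomsError
from .geometry import CoordSet, iterative_consensus, pairwise_rmsd_matrix, rmsd_fitted
from .structure_io import (
    DEFAULT_TABLE,
    FunctionalAtomTable,
    Residue,
    read_pdb,
    select_atoms,
)
from .template_model import DEFAULT_FUZZ, FuzzGroups, Template, build_template

__all__ = [
    "Site",
    "SiteEnsemble",
    "ClusterResult",
    "load_ensemble",
    "cluster_sites",
    "representative_site",
    "extract_family_templates",
]

logger = logging.getLogger(__name__)

DEFAULT_PRUNE_HEIGHT = 1.0  # Angstrom; same scale as the matcher's delta


@dataclass
class Site:
    """One homologous catalytic site with its functional-atom coordinates."""

    structure_id: str
    residues: list[Residue]
    coords: CoordSet


@dataclass
class SiteEnsemble:
    """Homologous sites sharing one ordered functional-atom correspondence."""

    family_id: str
    sites: list[Site]
    correspondence: list[str]

    def __post_init__(self) -> None:
        n = len(self.correspondence)
        for s in self.sites:
            if len(s.coords) != n:
                raise EnsembleError(
                    f"site {s.structure_id} has {len(s.coords)} atoms, "
                    f"correspondence has {n}"
                )

    def coord_sets(self) -> list[CoordSet]:
        return [s.coords for s in self.sites]


@dataclass
class ClusterResult:
    """Flat conformational clusters cut from the dendrogram."""

    labels: np.ndarray  # per-site cluster index, 0-based
    linkage: np.ndarray  # scipy linkage matrix, heights in Angstrom
    prune_height: float
    representatives: dict[int, int]  # cluster -> site index

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == cluster]


def _site_correspondence(
    restypes: Sequence[str], table: FunctionalAtomTable
) -> list[str]:
    labels = []
    for g, rt in enumerate(restypes):
        for i in range(len(table.functional[rt])):
            labels.append(f"g{g}.f{i}")
    return labels


def _compatible(rt_a: str, rt_b: str, table: FunctionalAtomTable, fuzz: FuzzGroups) -> bool:
    return rt_b in fuzz.group_of(rt_a) and len(table.functional.get(rt_a, ())) == len(
        table.functional.get(rt_b, ())
    )


def load_ensemble(
    site_definitions,
    structure_dir,
    table: FunctionalAtomTable = DEFAULT_TABLE,
    fuzz: FuzzGroups = DEFAULT_FUZZ,
) -> SiteEnsemble:
    """Assemble a :class:`SiteEnsemble` from site definitions and PDB files.

    ``site_definitions`` is a JSON path or an already-parsed dict of the form
    ``{"family_id": ..., "sites": [{"structure": ..., "chain_residues":
    [{"chain", "seqnum", "restype"}, ...]}, ...]}`` (the shape of a curated
    catalytic-residue export).  Structures are read from
    ``structure_dir/<structure>.pdb``.

    The correspondence is fuzz-aware: a site whose residue types fall in the
    same fuzz groups as the first usable site's (with equal functional-atom
    counts) aligns to it positionally, so an Asp-bearing homolog corresponds
    to a Glu-bearing one atom-for-atom.  Sites with missing atoms or
    incompatible residues are skipped with a logged warning.
    """
    if isinstance(site_definitions, (str, Path)):
        with open(site_definitions) as fh:
            defs = json.load(fh)
    else:
        defs = site_definitions
    structure_dir = Path(structure_dir)

    family_id = defs.get("family_id", "family")
    ref_types: list[str] | None = None
    correspondence: list[str] | None = None
    sites: list[Site] = []
    for entry in defs["sites"]:
        sid = entry["structure"]
        try:
            structure = read_pdb(structure_dir / f"{sid}.pdb", structure_id=sid)
            residues = [
                structure.get_residue(cr["chain"], str(cr["seqnum"]))
                for cr in entry["chain_residues"]
            ]
            for cr, res in zip(entry["chain_residues"], residues):
                want = cr.get("restype", res.restype).upper()
                if res.restype != want:
                    raise EnsembleError(
                        f"{sid} {res.chain}:{res.seqnum} is {res.restype}, "
                        f"definition says {want}"
                    )
            coords, labels = [], []
            for res in residues:
                for a in select_atoms(res, "functional", table):
                    coords.append(a.xyz)
            types = [r.restype for r in residues]
            if ref_types is None:
                ref_types = types
                correspondence = _site_correspondence(types, table)
            else:
                if len(types) != len(ref_types) or not all(
                    _compatible(a, b, table, fuzz) for a, b in zip(ref_types, types)
                ):
                    raise EnsembleError(
                        f"{sid}: residue types {types} incompatible with "
                        f"family reference {ref_types}"
                    )
            sites.append(
                Site(
                    structure_id=sid,
                    residues=residues,
                    coords=CoordSet(np.vstack(coords), list(correspondence)),
                )
            )
        except (OSError, KeyError, MissingAtomsError, EnsembleError) as exc:
            logger.warning("skipping site %s: %s", sid, exc)
            continue
    if len(sites) < 2:
        raise EnsembleError(
            f"family {family_id}: only {len(sites)} usable site(s); need >= 2"
        )
    return SiteEnsemble(family_id=family_id, sites=sites, correspondence=correspondence)


def cluster_sites(
    e: SiteEnsemble,
    prune_height: float = DEFAULT_PRUNE_HEIGHT,
    linkage: str = "average",
    fit: str = "pair",
) -> ClusterResult:
    """Agglomerative clustering of sites on pairwise best-fit RMSD.

    The dendrogram is cut at ``prune_height`` (Angstrom): flat clusters are
    the subtrees entirely below it.  Cluster indices are deterministic,
    ordered by cluster size descending, then by smallest member index.
    """
    if prune_height <= 0:
        raise ValueError("prune_height must be positive")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if len(e.sites) < 2:
        raise EnsembleError("clustering needs at least 2 sites")

    D = pairwise_rmsd_matrix(e.coord_sets(), fit=fit)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    raw = fcluster(Z, t=prune_height, criterion="distance")

    sizes: dict[int, tuple[int, int]] = {}
    for i, c in enumerate(raw):
        n, first = sizes.get(c, (0, i))
        sizes[c] = (n + 1, min(first, i))
    ordered = sorted(sizes, key=lambda c: (-sizes[c][0], sizes[c][1]))
    relabel = {c: k for k, c in enumerate(ordered)}
    labels = np.array([relabel[c] for c in raw], dtype=int)

    representatives = {
        k: representative_site(e, [i for i in range(len(labels)) if labels[i] == k])
        for k in range(len(ordered))
    }
    return ClusterResult(
        labels=labels, linkage=Z, prune_height=prune_height,
        representatives=representatives,
    )


def representative_site(e: SiteEnsemble, member_indices: Sequence[int]) -> int:
    """The member closest (best-fit RMSD) to the cluster's consensus.

    Singletons represent themselves; ties go to the smallest site index.
    """
    members = sorted(member_indices)
    if not members:
        raise ValueError("empty member list")
    if len(members) == 1:
        return members[0]
    consensus, _, _ = iterative_consensus([e.sites[i].coords for i in members])
    best, best_rmsd = members[0], np.inf
    for i in members:
        r = rmsd_fitted(e.sites[i].coords, consensus)
        if r < best_rmsd - 1e-12:
            best, best_rmsd = i, r
    return best


def extract_family_templates(
    e: SiteEnsemble,
    prune_height: float = DEFAULT_PRUNE_HEIGHT,
    mode: str = "functional",
    table: FunctionalAtomTable = DEFAULT_TABLE,
    fuzz: FuzzGroups = DEFAULT_FUZZ,
    linkage: str = "average",
    delta: float = 1.0,
    rho: float = 2.0,
    min_cluster_size: int = 2,
    drop_small_clusters: bool = False,
) -> tuple[list[Template], ClusterResult]:
    """One representative template per conformational cluster.

    Templates are built from the representative site's own residues (not an
    averaged geometry) and named ``<family_id>.c<k>``.  With
    ``drop_small_clusters`` clusters below ``min_cluster_size`` members are
    not emitted.
    """
    result = cluster_sites(e, prune_height=prune_height, linkage=linkage)
    templates = []
    for k in range(result.n_clusters):
        members = result.members(k)
        if drop_small_clusters and len(members) < min_cluster_size:
            logger.info(
                "family %s: dropping cluster %d (%d member(s))",
                e.family_id, k, len(members),
            )
            continue
        rep = result.representatives[k]
        templates.append(
            build_template(
                e.sites[rep].residues,
                mode=mode,
                table=table,
                fuzz=fuzz,
                template_id=f"{e.family_id}.c{k}",
                delta=delta,
                rho=rho,
            )
        )
    return templates, result
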