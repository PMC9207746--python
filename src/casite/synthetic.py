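"""Seeded synthetic fixtures with exact ground truth.

Real curated site data (family annotations plus their deposited structures)
is large and external; the generators here emit small, fully deterministic
stand-ins that exercise every pipeline stage with known answers:

* an idealized Ser-His-Asp catalytic triad with hydrogen-bond-range
  heteroatom contacts (Ser OG - His NE2 = 2.80 A, His ND1 - Asp OD2 =
  2.70 A; fixed constants of this artifact),
* decoy structures -- residues of random type at ideal internal geometry,
  randomly oriented and placed in a box with a minimum spacing,
* planted triads under controlled per-atom Gaussian noise, optionally with
  scrambled backbone atoms (the convergence fixture: side-chain chemistry
  intact, main chain unrelated),
* multi-state site ensembles: k conformational states separated by a fixed
  rigid displacement of one residue's functional atoms, members jittered
  with Gaussian noise.

Residues are geometrically simplified (ideal internal coordinates, no
packing or clash minimization beyond the spacing rule) -- sufficient for
matcher and clustering stress tests, not physical models.  One integer seed
drives all randomness; identical seeds give byte-identical PDB text.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import CoordSet
from .multi_template import Site, SiteEnsemble, _site_correspondence
from .structure_io import (
    DEFAULT_TABLE,
    Atom,
    FunctionalAtomTable,
    Residue,
    Structure,
    assemble_structure,
    select_atoms,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "PlantSpec",
    "GroundTruth",
    "PlantedSite",
    "canonical_triad_geometry",
    "build_residue",
    "generate_structure",
    "generate_ensemble",
    "mutate_functional",
    "move_residue",
    "AMINO_ACIDS",
]

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

ELEMENT_OF_PREFIX = {"C": "C", "N": "N", "O": "O", "S": "S"}

OG_NE2_DISTANCE = 2.80  # Angstrom, Ser OG to His NE2 hydrogen bond
ND1_OD2_DISTANCE = 2.70  # Angstrom, His ND1 to Asp OD2 hydrogen bond


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate atom placement (NeRF).

    Returns D with |D-c| = length, angle(b,c,D) = angle_deg and torsion
    (a,b,c,D) = torsion_deg.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


# Backbone seed frame: CA at the origin, N and C at ideal bond geometry.
_N = np.array([-1.458, 0.0, 0.0])
_CA = np.zeros(3)
_C = np.array([0.546, 1.424, 0.0])

# Side chains as internal-coordinate recipes: (atom, frame atoms, bond
# length A, bond angle deg, torsion deg).  Simplified topologies -- every
# residue gets its backbone, its functional heteroatoms, and just enough
# connecting atoms to give those a sensible direction.
_SIDE_CHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, 60.0)],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.5, 60.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 111.5, 180.0),
    ],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 114.4, -60.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.4, 60.0)],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
    ],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, -60.0)],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, -60.0),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
    ],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, -60.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.495, 104.5, 30.0)],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, -60.0),
        ("CZ", ("CA", "CB", "CG"), 2.775, 150.0, 180.0),
        ("OH", ("CB", "CG", "CZ"), 1.376, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, -60.0),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.356, 129.7, -90.0),
        ("CE1", ("CB", "CG", "ND1"), 1.323, 109.0, 180.0),
        ("NE2", ("CG", "ND1", "CE1"), 1.310, 108.5, 0.0),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, -60.0),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 180.0),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, -60.0),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 180.0),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
    ],
}


def build_residue(restype: str, chain: str = "A", seqnum: str = "1") -> Residue:
    """One residue at ideal internal geometry in its local frame (CA at 0)."""
    if restype not in _SIDE_CHAINS:
        raise ValueError(f"unknown residue type {restype!r}")
    coords: dict[str, np.ndarray] = {"N": _N.copy(), "CA": _CA.copy(), "C": _C.copy()}
    coords["O"] = _place(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, 0.0)
    if restype != "GLY":
        coords["CB"] = _place(coords["C"], coords["N"], coords["CA"], 1.530, 110.4, 123.0)
    for name, (a, b, c), length, angle, torsion in _SIDE_CHAINS[restype]:
        coords[name] = _place(coords[a], coords[b], coords[c], length, angle, torsion)
    atoms = [
        Atom(name=n, element=ELEMENT_OF_PREFIX[n[0]], pos=tuple(p))
        for n, p in coords.items()
    ]
    return Residue(chain=chain, seqnum=str(seqnum), restype=restype, atoms=atoms)


def move_residue(res: Residue, rotation: np.ndarray, translation: np.ndarray) -> Residue:
    atoms = [
        Atom(
            name=a.name, element=a.element,
            pos=tuple(rotation @ a.xyz + translation),
            altloc=a.altloc, occupancy=a.occupancy, serial=a.serial,
        )
        for a in res.atoms
    ]
    return Residue(
        chain=res.chain, seqnum=res.seqnum, restype=res.restype,
        atoms=atoms, chain_index=res.chain_index,
    )


def _align_one_vector(from_vec: np.ndarray, to_vec: np.ndarray) -> np.ndarray:
    """Minimal rotation taking from_vec onto to_vec (deterministic)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors([to_vec], [from_vec])
    return rot.as_matrix()


def canonical_triad_geometry() -> list[Residue]:
    """The idealized Ser-His-Asp triad used as planted ground truth.

    His sits in its local frame; Ser is rigidly placed so that OG lies
    exactly 2.80 A from NE2 along the outward ring direction, and Asp so
    that OD2 lies exactly 2.70 A from ND1.  Full (simplified) side chains
    and backbones are included.
    """
    his = build_residue("HIS", seqnum="2")
    ring = np.mean(
        [his.atom(n).xyz for n in ("CG", "ND1", "CD2", "CE1", "NE2")], axis=0
    )
    ne2, nd1 = his.atom("NE2").xyz, his.atom("ND1").xyz

    ser = build_residue("SER", seqnum="1")
    u1 = ne2 - ring
    u1 = u1 / np.linalg.norm(u1)
    og_target = ne2 + OG_NE2_DISTANCE * u1
    R1 = _align_one_vector(ser.atom("CB").xyz - ser.atom("OG").xyz, u1)
    ser = move_residue(ser, R1, og_target - R1 @ ser.atom("OG").xyz)

    asp = build_residue("ASP", seqnum="3")
    u2 = nd1 - ring
    u2 = u2 / np.linalg.norm(u2)
    od2_target = nd1 + ND1_OD2_DISTANCE * u2
    R2 = _align_one_vector(asp.atom("CG").xyz - asp.atom("OD2").xyz, u2)
    asp = move_residue(asp, R2, od2_target - R2 @ asp.atom("OD2").xyz)

    out = []
    for i, res in enumerate((ser, his, asp)):
        res.chain_index = i
        out.append(res)
    return out


GEOMETRIES = {"triad": canonical_triad_geometry}


# --- planted-structure generator ------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """One planted site: which geometry, how noisy, backbone intact or not."""

    geometry_id: str = "triad"
    sigma: float = 0.0  # Angstrom, per-atom Gaussian noise
    backbone_scrambled: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.geometry_id not in GEOMETRIES:
            raise ValueError(f"unknown site geometry {self.geometry_id!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure."""

    seed: int
    n_decoys: int = 50
    planted: tuple[PlantSpec, ...] = ()
    box: float = 40.0  # Angstrom cube edge for residue placement
    min_sep: float = 4.0  # Angstrom minimum spacing between residue anchors

    def __post_init__(self) -> None:
        if self.min_sep <= 0:
            raise ValueError("min_sep must be positive")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")
        object.__setattr__(self, "planted", tuple(self.planted))


@dataclass
class PlantedSite:
    """Ground truth for one planted site in an emitted fixture."""

    geometry_id: str
    residue_ids: list[tuple[str, str]]  # (chain, seqnum) per site residue
    exact_coords: dict[str, dict[str, list[float]]]  # seqnum -> atom -> xyz
    sigma: float
    backbone_scrambled: bool


@dataclass
class GroundTruth:
    """What was planted where, with exact pre-noise coordinates."""

    structure_id: str
    sites: list[PlantedSite]

    def to_json(self) -> str:
        return json.dumps(
            {
                "structure_id": self.structure_id,
                "sites": [
                    {
                        "geometry_id": s.geometry_id,
                        "residue_ids": [list(r) for r in s.residue_ids],
                        "exact_coords": s.exact_coords,
                        "sigma": s.sigma,
                        "backbone_scrambled": s.backbone_scrambled,
                    }
                    for s in self.sites
                ],
            },
            indent=1,
        )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _draw_position(
    rng: np.random.Generator, box: float, anchors: list[np.ndarray], min_sep: float,
    retries: int = 2000,
) -> np.ndarray:
    for _ in range(retries):
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - a) >= min_sep for a in anchors):
            return p
    raise RuntimeError(
        f"could not place a residue with min_sep={min_sep} in a {box} A box"
    )


def generate_structure(spec: FixtureSpec) -> tuple[str, GroundTruth]:
    """Emit one synthetic PDB fixture and its ground truth.

    Decoy residue types are drawn uniformly from the 20 standard amino
    acids; each residue is randomly oriented and placed in the box honoring
    ``min_sep`` between residue anchors (CA atoms).  Planted sites get one
    random rigid placement, then per-atom Gaussian noise of the requested
    sigma; with ``backbone_scrambled`` the backbone atoms (N, CA, C, O) are
    re-placed at random nearby positions while the side chain stays put.
    Identical specs produce byte-identical text.
    """
    rng = np.random.default_rng(spec.seed)
    anchors: list[np.ndarray] = []
    residues: list[Residue] = []

    for _ in range(spec.n_decoys):
        restype = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        res = build_residue(restype)
        center = _draw_position(rng, spec.box, anchors, spec.min_sep)
        res = move_residue(res, _random_rotation(rng), center)
        anchors.append(res.atom("CA").xyz)
        residues.append(res)

    planted_records: list[tuple[list[Residue], PlantSpec, list[dict]]] = []
    for plant in spec.planted:
        site = GEOMETRIES[plant.geometry_id]()
        R = _random_rotation(rng)
        for _ in range(2000):
            center = rng.uniform(0.0, spec.box, size=3)
            cas = [R @ r.atom("CA").xyz + center for r in site]
            if all(
                np.linalg.norm(ca - a) >= spec.min_sep for ca in cas for a in anchors
            ):
                break
        else:
            raise RuntimeError("could not place the planted site in the box")
        moved = [move_residue(r, R, center) for r in site]
        anchors.extend(r.atom("CA").xyz for r in moved)
        exact = [
            {a.name: a.xyz.tolist() for a in r.atoms} for r in moved
        ]
        noisy = []
        for r in moved:
            atoms = [
                Atom(
                    name=a.name, element=a.element,
                    pos=tuple(a.xyz + rng.normal(0.0, plant.sigma, size=3))
                    if plant.sigma > 0 else a.pos,
                )
                for a in r.atoms
            ]
            if plant.backbone_scrambled:
                ca = r.atom("CA").xyz
                atoms = [
                    Atom(
                        name=a.name, element=a.element,
                        pos=tuple(ca + rng.uniform(-6.0, 6.0, size=3)),
                    )
                    if a.name in ("N", "CA", "C", "O")
                    else a
                    for a in atoms
                ]
            noisy.append(
                Residue(chain="A", seqnum=r.seqnum, restype=r.restype, atoms=atoms)
            )
        planted_records.append((noisy, plant, exact))

    # interleave planted residues at random chain positions
    order = list(residues)
    insert_points = sorted(
        (int(rng.integers(len(order) + 1)) for rec in planted_records for _ in rec[0]),
    )
    flat_planted = [r for rec in planted_records for r in rec[0]]
    for offset, (pos, res) in enumerate(zip(insert_points, flat_planted)):
        order.insert(min(pos + offset, len(order)), res)

    renumbered = []
    planted_seq: dict[int, str] = {}
    for i, res in enumerate(order):
        seq = str(i + 1)
        renumbered.append(
            Residue(chain="A", seqnum=seq, restype=res.restype, atoms=res.atoms)
        )
        if any(res is p for p in flat_planted):
            planted_seq[id(res)] = seq

    structure_id = f"synth{spec.seed}"
    structure = assemble_structure(structure_id, {"A": renumbered})

    sites = []
    for noisy, plant, exact in planted_records:
        seqs = [planted_seq[id(r)] for r in noisy]
        sites.append(
            PlantedSite(
                geometry_id=plant.geometry_id,
                residue_ids=[("A", s) for s in seqs],
                exact_coords={s: e for s, e in zip(seqs, exact)},
                sigma=plant.sigma,
                backbone_scrambled=plant.backbone_scrambled,
            )
        )
    return write_pdb(structure), GroundTruth(structure_id=structure_id, sites=sites)


# --- multi-state ensemble generator ----------------------------------------

def generate_ensemble(
    k_states: int,
    n_per_state: int,
    between_state_shift: float,
    within_noise: float,
    seed: int,
    table: FunctionalAtomTable = DEFAULT_TABLE,
    family_id: str = "synthetic_triad",
) -> tuple[SiteEnsemble, list[int]]:
    """Homologous triad sites drawn from k conformational states.

    State 0 is the canonical triad's functional-atom geometry; each further
    state rigidly displaces one residue's functional atoms (cycling Ser,
    His, Asp) along a fixed seeded direction.  ``between_state_shift``
    (Angstrom) is the separation on the scale the dendrogram metric uses:
    the translation is calibrated so that the state's best-fit RMSD to the
    base site equals the requested shift.  Every member adds per-atom
    Gaussian noise ``within_noise`` and receives its own random global
    rigid motion.  Returns the ensemble and the ground-truth state label
    per site.
    """
    if k_states < 1 or n_per_state < 1:
        raise ValueError("k_states and n_per_state must be >= 1")
    if within_noise < 0 or between_state_shift < 0:
        raise ValueError("noise and shift must be non-negative")
    if k_states > 1 and between_state_shift <= 4 * within_noise:
        warnings.warn(
            "between_state_shift <= 4*sigma: states may not be separable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    base = canonical_triad_geometry()
    restypes = [r.restype for r in base]
    correspondence = _site_correspondence(restypes, table)

    def _functional_coords(site: list[Residue]) -> np.ndarray:
        return np.vstack(
            [a.xyz for res in site for a in select_atoms(res, "functional", table)]
        )

    base_coords = _functional_coords(base)

    state_sites: list[list[Residue]] = [base]
    for s in range(1, k_states):
        which = (s - 1) % len(base)
        direction = rng.normal(size=3)
        direction = direction / np.linalg.norm(direction)

        def displaced(magnitude: float) -> list[Residue]:
            return [
                move_residue(
                    res, np.eye(3),
                    magnitude * direction if i == which else np.zeros(3),
                )
                for i, res in enumerate(base)
            ]

        # calibrate the translation so the site-level best-fit RMSD to the
        # base geometry equals between_state_shift (fixed-point iteration;
        # the residual is nearly linear in the magnitude)
        magnitude = between_state_shift
        if between_state_shift > 0:
            from .geometry import rmsd_fitted

            for _ in range(60):
                r = rmsd_fitted(_functional_coords(displaced(magnitude)), base_coords)
                if abs(r - between_state_shift) < 1e-10:
                    break
                magnitude *= between_state_shift / r
        state_sites.append(displaced(magnitude))

    sites: list[Site] = []
    labels: list[int] = []
    for s, state in enumerate(state_sites):
        for m in range(n_per_state):
            R = _random_rotation(rng)
            t = rng.uniform(-20.0, 20.0, size=3)
            member_res = []
            for res in state:
                atoms = []
                for a in res.atoms:
                    p = a.xyz
                    if within_noise > 0:
                        p = p + rng.normal(0.0, within_noise, size=3)
                    atoms.append(
                        Atom(name=a.name, element=a.element, pos=tuple(R @ p + t))
                    )
                member_res.append(
                    Residue(
                        chain="A", seqnum=res.seqnum, restype=res.restype,
                        atoms=atoms, chain_index=res.chain_index,
                    )
                )
            coords = np.vstack(
                [
                    a.xyz
                    for res in member_res
                    for a in select_atoms(res, "functional", table)
                ]
            )
            sites.append(
                Site(
                    structure_id=f"{family_id}_s{s}m{m}",
                    residues=member_res,
                    coords=CoordSet(coords, list(correspondence)),
                )
            )
            labels.append(s)
    ensemble = SiteEnsemble(
        family_id=family_id, sites=sites, correspondence=correspondence
    )
    return ensemble, labels


def mutate_functional(
    residue: Residue,
    new_restype: str,
    table: FunctionalAtomTable = DEFAULT_TABLE,
) -> Residue:
    """Relabel a residue as a chemically analogous type, coordinates fixed.

    Functional atom names are renamed by positional correspondence in the
    table (e.g. Asp OD1/OD2 -> Glu OE1/OE2), which makes exact functional-
    substitution fixtures: same geometry, different residue identity.
    """
    old_names = table.functional[residue.restype]
    new_names = table.functional[new_restype]
    if len(old_names) != len(new_names):
        raise ValueError(
            f"{residue.restype} and {new_restype} have different functional-atom counts"
        )
    rename = dict(zip(old_names, new_names))
    atoms = [
        Atom(
            name=rename.get(a.name, a.name), element=a.element, pos=a.pos,
            altloc=a.altloc, occupancy=a.occupancy, serial=a.serial,
        )
        for a in residue.atoms
    ]
    return Residue(
        chain=residue.chain, seqnum=residue.seqnum, restype=new_restype,
        atoms=atoms, chain_index=residue.chain_index,
    )
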