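# Methods

This note documents the models and algorithmic choices behind `casite`:
what each stage computes, the parameters that matter, and what the
synthetic fixtures do and do not establish about real structures.

## Structure model and atom tables

Structures are read from PDB text (via gemmi) into a minimal hierarchy:
chains → residues → named heavy atoms with coordinates in Å. Reading
applies the standard reductions for site analysis: only the first MODEL is
kept; hydrogens are dropped; HETATM residues are excluded unless
explicitly whitelisted; alternate locations are resolved to the
highest-occupancy copy, with ties going to the alphabetically first
altloc. Author residue numbering (with insertion codes) is preserved;
each residue also carries a 0-based ordinal within its chain, used by the
sequence-order diagnostic. Malformed fixed-column records are rejected
with the offending line number; file order wins over any numbering
anomalies.

**Functional atoms** are the terminal side-chain heteroatoms that carry a
residue's catalytic chemistry. The table used throughout:

| restype | functional atoms | symmetric sets |
|---|---|---|
| SER | OG | — |
| THR | OG1 | — |
| TYR | OH | — |
| CYS | SG | — |
| HIS | ND1, NE2 | {ND1, NE2} (matching only) |
| ASP | OD1, OD2 | {OD1, OD2} |
| GLU | OE1, OE2 | {OE1, OE2} |
| ASN | OD1, ND2 | {OD1, ND2} |
| GLN | OE1, NE2 | {OE1, NE2} |
| LYS | NZ | — |
| ARG | NE, NH1, NH2 | {NH1, NH2} |
| TRP | NE1 | — |

Symmetric sets list atoms a matcher may swap (chemically
indistinguishable or near-indistinguishable positions); superposition
correspondences for ensemble building never swap them, so the His
equivalence can be switched off (`default_table(his_equivalence=False)`)
without affecting clustering. Gly has no functional-atom entry and is
excluded from functional templates; backbone templates use the fixed
N, CA, C triple — three points suffice to pin the local main-chain frame,
and the carbonyl O adds no discriminative power at the tolerances used.

## Superposition and RMSD

All fits are least-squares optimal proper rotations (Kabsch; implemented
via `scipy.spatial.transform.Rotation.align_vectors`), equal weights, no
reflections even for planar or near-planar sets. The reported RMSD is
recomputed from the fitted coordinates rather than taken from the solver's
residual, which loses several digits to cancellation near zero.
Collinear inputs emit a warning (the in-line rotation component is
arbitrary) but still return a result.

`iterative_consensus` superposes all sites onto the first, averages,
re-superposes all onto the running mean, and repeats until the mean moves
by less than 1e-4 Å (well below coordinate precision in PDB files) or 100
iterations. The consensus is unique only up to a global rigid motion; the
orientation returned is the one reached from the first site's frame.

Pairwise site distances default to **per-pair best fit**, which is
invariant to each site's deposited frame and to the choice of a reference
member. A single-consensus-frame variant (`fit="consensus"`), which
compares coordinates after one joint superposition and therefore upper-
bounds the per-pair values, is provided for comparison with dendrograms
built in a common frame.

## Templates

A template stores ordered atoms grouped by residue, each with a map of
allowed residue types → allowed atom names, plus the derived pairwise
distance matrix and two tolerances: δ (inter-atom distance, default
1.0 Å) and ρ (best-fit RMSD, default 2.0 Å). δ follows the tolerance
commonly used to suppress false positives in functional-atom searches; ρ
has no canonical published value and 2.0 Å was chosen as a permissive
default that still rejects random residue triples (the decoy studies in
the test suite measure zero false hits at ρ = 0.5 and full planted
recovery at ρ = 1.0). Both are overridable per template and per search.

Fuzzy groups {Ser, Thr, Tyr}, {Asp, Glu}, {Asn, Gln} expand each atom's
allowed map across residue types; cross-type atom correspondence is
positional in the functional table (the i-th functional atom of one type
corresponds to the i-th of any type in its group), and each name is then
expanded across its symmetric set. Backbone template atoms accept any
residue type (wildcard `*`).

The template file format is PDB-like text: a
`REMARK TEMPLATE <id> MODE <mode> DELTA <x> RHO <x>` header,
`REMARK ALLOW <atom-index> <RESTYPE>:<names>` records, and ATOM records
carrying the canonical residue type with the group index as residue
number, coordinates `%8.3f`. It is diff-able and loads in structure
viewers; distance constraints are always recomputed from the coordinates
on read.

## Matching

Search proceeds by depth-first assignment of template residue groups to
structure residues, cheapest group (fewest candidate residues) first.
Candidates are residues whose type every template atom of the group
accepts and whose required atoms all resolve; symmetric-atom alternatives
enumerate injective atom mappings per residue. A partial assignment is
pruned as soon as any pair of assigned atoms violates
|d_structure − d_template| ≤ δ — the constraint applies to **all** template
atom pairs, including within-residue pairs, which is the stricter reading
and the cheaper prune. Complete assignments are Kabsch-fitted and kept
when RMSD ≤ ρ.

One match is reported per unordered residue set: the lowest-RMSD atom
mapping wins, so OD1/OD2-style swaps and group-permutation duplicates
never appear twice. Results are sorted by RMSD with deterministic
tie-breaking (chain, then residue number). Matches may span chains by
default (`same_chain_only` restricts them); the sequence-order flag is
true only for single-chain matches whose residues follow the template's
group order along the chain. A hit cap (`max_matches`, default 10,000)
guards pathological inputs and sets a `truncated` flag instead of failing.

The test suite holds the matcher to *exact* equivalence — same residue
sets, RMSDs within 1e-9 — with an independent brute-force enumerator over
all residue tuples and atom mappings on ≤ 60-residue fixtures.

**Significance.** There is no published closed-form significance model for
this kind of match score, so the package deliberately provides an
empirical one: sample residue-type-compatible combinations from
user-supplied decoy structures with a seeded generator, fit each to the
template, and report the add-one-smoothed fraction with RMSD at or below
the match's, `(1 + hits) / (1 + n_effective)`. It is a tail-probability
estimate whose resolution is limited by the sample count, monotone in the
match RMSD by construction.

## Multi-template extraction

Family sites are loaded from a JSON site-definition file (the shape of a
curated catalytic-residue export: family id, then per structure the chain,
number, and type of each catalytic residue). Sites whose residues fall in
the same fuzzy groups as the family reference (with equal functional-atom
counts) join a shared positional atom correspondence — an Asp-bearing
homolog aligns atom-for-atom with a Glu-bearing one. Sites with missing
atoms or incompatible residues are skipped with a logged warning; a family
needs at least two usable sites.

Clustering is agglomerative (average linkage by default; complete and
single available) on the pairwise best-fit RMSD matrix, cut at a prune
height *h* (default 1.0 Å, the same scale as δ — the primary tuning knob:
lower cuts give finer conformational states, higher cuts merge them).
Cluster labels are deterministic: ordered by cluster size descending, then
by smallest member index. Each cluster's representative is the member
with minimal best-fit RMSD to the cluster's iterative consensus (ties to
the smallest site index); a representative built from a real member is
preferred over the consensus itself so every emitted template is an
observed geometry. Templates are built from the representative's residues
and named `<family_id>.c<k>`; clusters below a minimum size can be
dropped.

## Convergence and substitution classification

Paired scanning runs the same search parameters twice per structure, once
with the backbone template and once with the functional template. A
functional match is `backbone_supported` when some backbone match covers
at least `overlap_min` of its residues; the default (`overlap_min = 1.0`,
i.e. the identical residue set) is the strictest reading and yields the
fewest convergence calls — relax it to tolerate partial backbone support.
Classification is a pure function of the two match lists.

Substitution calls compare a match against an explicit reference site
(by default the site the template came from) through a pairwise global
alignment: BLOSUM62 scores, linear gap penalty −8, unknown codes treated
as X scoring 0 against everything, deterministic traceback. Per residue
group: `conserved` if the type is unchanged and the matched residue sits
at the position aligned to the reference catalytic residue;
`functional_substitution` if a different (fuzzy-group) type sits at that
aligned position; `spatial_substitution` if the matched residue arrives
from any non-aligned position, regardless of type. Residues on a chain
not covered by the alignment are flagged unalignable and receive no call.
A pairwise alignment stands in for multiple-alignment inspection; the tool
reports the evidence (calls, order flags, alignment status) and does not
assert an evolutionary verdict, which in ambiguous cases — e.g. an order
mismatch that could be convergence or double spatial substitution — needs
information beyond geometry.

The summary table aggregates per-structure counts, best RMSDs, and order
flags, with an optional EC-prefix filter over a user-supplied id→EC map
(e.g. `"3."` to keep hydrolases).

## Synthetic data

The generators define the package's controlled study conditions.

* **Canonical triad.** An idealized Ser-His-Asp site: residues built from
  ideal internal coordinates (NeRF placement; simplified topologies with
  backbone, CB, and the atoms that give functional heteroatoms their
  direction), His fixed, Ser and Asp rigidly placed so that
  Ser OG–His NE2 = 2.80 Å and His ND1–Asp OD2 = 2.70 Å exactly —
  canonical hydrogen-bond lengths, the fixed ground-truth constants of
  this artifact.
* **Planted structures.** Decoy residues drawn uniformly from the 20
  standard types, randomly oriented, placed uniformly in a 40 Å box with a
  4 Å minimum spacing between CA anchors (bounded retries, then an error).
  Planted sites receive one random rigid placement, then per-atom Gaussian
  noise σ; the ground truth records the exact pre-noise coordinates and
  residue numbers. With `backbone_scrambled` the backbone atoms are
  re-placed uniformly within ±6 Å of the residue anchor while the side
  chain stays put — side-chain geometry intact on an unrelated main chain,
  the positive control for convergence detection.
* **Ensembles.** k conformational states: state 0 is the canonical triad;
  each further state displaces one residue's functional atoms (cycling
  Ser, His, Asp) along a fixed seeded direction. The displacement is
  calibrated (fixed-point iteration on the nearly linear residual) so the
  state's site-level best-fit RMSD to the base equals the requested
  `between_state_shift` — the separation parameter lives on the same scale
  as the dendrogram metric and the prune height, which is what makes
  "states 1.5 Å apart, prune at 1.0 Å" a meaningful design. Members add
  per-atom Gaussian noise and a random global rigid motion. A warning is
  emitted when the shift is within 4σ of the noise, where separability is
  not guaranteed.

One integer seed drives all randomness; identical seeds give byte-identical
PDB text. Default study conditions used by the tests and the acceptance
script: 0.2 Å planted noise among 100 decoys for recall (δ = ρ = 1.0 Å),
ρ = 0.5 Å for decoy silence, 50-decoy fixtures for matcher-enumeration
equivalence, 20 fixtures per arm for convergence classification, and
k = 3 states × 20 members at 1.5 Å shift / 0.15 Å noise for cluster
recovery — sizes at which the exhaustive oracle remains tractable and each
run completes in seconds.

**What the fixtures do not show.** Decoys are isolated residues with ideal
internal geometry — no chains, packing, secondary structure, rotamer
statistics, or crystallographic artifacts. Passing these tests
demonstrates algorithmic correctness (search completeness, constraint
handling, classification logic, determinism), not false-positive rates on
real proteomes: real structures have correlated residue placements and far
denser candidate sets, and template specificity there must be assessed
against real decoy databases. The family-clustering test against real
curated site annotations requires external data (see
`tests/test_acceptance.py`) and is the one check that cannot run from
synthetic input.

## Numerical choices and edge cases

* Consensus loop: 1e-4 Å displacement tolerance, 100 iterations.
* Distance-constraint comparisons are strict (`> δ` rejects); RMSD
  thresholds are inclusive (`≤ ρ` keeps).
* Representative ties and label ties always break toward the smallest
  index; match ordering breaks RMSD ties by chain then residue number.
* Degenerate (collinear) point sets warn and return; fewer than 3 points
  or length mismatches raise.
* Dendrogram cutting uses cophenetic distance ≤ prune height; heights are
  in Å throughout.
* Template coordinates are written at 3 decimals; a template that has been
  through one write/read cycle round-trips exactly thereafter.

## Known limitations

* No analytic match significance; the empirical estimate depends on the
  decoy set supplied and is labelled as such.
* Functional-atom superposition uses fixed positional correspondences;
  sites whose fuzzy partners have different functional-atom counts (e.g.
  Ser vs His) cannot share an ensemble correspondence.
* Pairwise alignment only; no MSA, no structure-guided alignment.
* mmCIF, assemblies, and ligand chemistry are out of scope; PDB text only.
* The matcher is exact but exhaustive in spirit: very permissive
  tolerances on large structures can explode the search; the hit cap
  truncates rather than reorders in that regime.
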