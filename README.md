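# casite — catalytic-site 3D coordinate templates

`casite` is a toolkit for representing enzyme active sites as **3D
coordinate templates** and using them to find, compare, and interpret
catalytic motifs in protein structures. It is aimed at structural
bioinformaticians studying catalytic geometry, active-site flexibility, and
the evolutionary events — convergence, functional substitution, spatial
substitution — that reshape catalytic sites while preserving their
chemistry.

## What it does

A coordinate template is an ordered set of atom positions (Å) taken from a
curated catalytic site, together with the constraints a match must satisfy:

* **fuzzy residue matching** — Ser/Thr/Tyr, Asp/Glu, and Asn/Gln are
  interchangeable residue groups, with positional atom correspondence
  (Ser OG ↔ Thr OG1 ↔ Tyr OH; Asp OD1/OD2 ↔ Glu OE1/OE2);
* **fuzzy atom matching** — chemically symmetric side-chain atoms
  (carboxylate oxygens, amide N/O endpoints, the His imidazole nitrogens,
  guanidinium NH1/NH2) may be swapped;
* a **distance tolerance** δ (default 1.0 Å): every inter-atom distance in
  a match must satisfy |d_structure − d_template| ≤ δ;
* an **RMSD threshold** ρ (default 2.0 Å) on the best-fit (Kabsch,
  proper-rotation) root-mean-square deviation of corresponding atoms.

On top of that the package provides:

* **Matching** — depth-first search over candidate residues ordered by
  candidate count, pruned by the pairwise distance constraints, scored by
  best-fit RMSD, deduplicated per residue set, with a sequence-order
  diagnostic and an optional decoy-sampled empirical significance.
* **Multi-template extraction** — homologous sites of a family are put into
  a common functional-atom correspondence, iteratively superposed,
  clustered on pairwise best-fit RMSD (agglomerative dendrogram, pruned at
  a height *h*), and each conformational cluster is represented by the
  member site closest to the cluster's iterative consensus. A flexible
  site thus yields one template per major conformational state instead of
  a single blurred average.
* **Evolutionary classification** — a structure set is queried with two
  templates of the same site, one over backbone atoms (N, CA, C) and one
  over side-chain functional atoms. Functional matches with a backbone
  match over the same residues are `backbone_supported`; functional matches
  without one are `putative_convergent` (the side-chain chemistry has been
  rebuilt on an unrelated main-chain scaffold). Against a reference site
  and a BLOSUM62 global alignment, each matched residue is called
  `conserved`, `functional_substitution` (e.g. Asp→Glu at the aligned
  position), or `spatial_substitution` (the same functional group arriving
  from a different sequence position).
* **Synthetic data** — seeded generators for decoy structures, planted
  Ser-His-Asp triads with controlled Gaussian noise (optionally with
  scrambled backbones, the convergence fixture), and multi-state site
  ensembles — every test answer is known by construction.

## Worked example

```python
from casite import build_template, match_template, read_pdb, MatchParams, scan_structures
from casite.synthetic import FixtureSpec, PlantSpec, canonical_triad_geometry, generate_structure

triad = canonical_triad_geometry()                       # idealized Ser-His-Asp site
functional = build_template(triad, "functional", template_id="triad_f")
backbone = build_template(triad, "backbone", template_id="triad_b")

text, truth = generate_structure(
    FixtureSpec(seed=42, n_decoys=100, planted=(PlantSpec(sigma=0.2),))
)
structure = read_pdb(text, "synth42")
print("planted at:", truth.sites[0].residue_ids)

for m in match_template(functional, structure, MatchParams(delta=1.0, rho=2.0)):
    print(f"{m.structure_id}  rmsd={m.rmsd:.3f} A  {m.describe_residues()}  "
          f"in_sequence_order={m.in_sequence_order}")

(result,) = scan_structures([structure], functional, backbone)
print("classification:", result.classifications)
```

Output:

```
planted at: [('A', '48'), ('A', '61'), ('A', '79')]
synth42  rmsd=0.283 A  A:48:SER;A:61:HIS;A:79:ASP  in_sequence_order=True
classification: ['backbone_supported']
```

The planted triad — residues 48 (Ser), 61 (His), 79 (Asp) of the synthetic
chain — is the only hit among 100 decoy residues; its best-fit RMSD of
0.28 Å reflects the 0.2 Å per-atom noise the generator injected. Because
the planted backbone is intact, the paired backbone search also matches the
same residues and the site is classified `backbone_supported`; repeating
this on a fixture generated with `backbone_scrambled=True` flips the call
to `putative_convergent`.

The same operations are available from the shell:

```sh
casite generate-fixtures --preset triad-scan --seed 1 --n 5 --out-dir fixtures/
casite match --template triad_f.tpl --pdb-dir fixtures/ --delta 1.0 --rho 2.0 --out matches.tsv
casite extract-templates --sites family.json --pdb-dir structures/ --prune 1.0 --out-dir templates/
casite scan-convergence --functional triad_f.tpl --backbone triad_b.tpl \
    --pdb-dir structures/ --ec-map ec.tsv --ec-filter 3. --out scan.tsv
```

## Documentation

`docs/methods.md` describes the models, algorithms, parameter defaults,
numerical choices, and the scope and limitations of the synthetic-data
generators.
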