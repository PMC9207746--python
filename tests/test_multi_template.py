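"""Ensemble loading, conformational clustering, representative templates."""

import json
import logging

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from casite.errors import EnsembleError
from casite.geometry import CoordSet, iterative_consensus, rmsd_fitted
from casite.matcher import MatchParams, match_template
from casite.multi_template import (
    cluster_sites,
    extract_family_templates,
    load_ensemble,
    representative_site,
)
from casite.structure_io import assemble_structure, write_pdb
from casite.synthetic import (
    canonical_triad_geometry,
    generate_ensemble,
    move_residue,
    mutate_functional,
)

from conftest import random_rigid


def write_family(tmp_path, variants):
    """Write triad PDB files and a site-definition JSON; returns paths.

    ``variants`` maps structure id -> (residues, noise_sigma, rng_seed).
    """
    pdb_dir = tmp_path / "pdbs"
    pdb_dir.mkdir(exist_ok=True)
    defs = {"family_id": "fam", "sites": []}
    for sid, (residues, sigma, seed) in variants.items():
        rng = np.random.default_rng(seed)
        if sigma > 0:
            from casite.structure_io import Atom, Residue

            residues = [
                Residue(
                    chain=r.chain, seqnum=r.seqnum, restype=r.restype,
                    atoms=[
                        Atom(a.name, a.element, tuple(a.xyz + rng.normal(0, sigma, 3)))
                        for a in r.atoms
                    ],
                    chain_index=r.chain_index,
                )
                for r in residues
            ]
        s = assemble_structure(sid, {"A": residues})
        (pdb_dir / f"{sid}.pdb").write_text(write_pdb(s))
        defs["sites"].append(
            {
                "structure": sid,
                "chain_residues": [
                    {"chain": r.chain, "seqnum": r.seqnum, "restype": r.restype}
                    for r in residues
                ],
            }
        )
    sites_json = tmp_path / "fam.json"
    sites_json.write_text(json.dumps(defs))
    return sites_json, pdb_dir


class TestLoadEnsemble:
    def test_site_with_missing_atom_skipped_with_warning(self, tmp_path, caplog):
        triad = canonical_triad_geometry()
        broken = canonical_triad_geometry()
        ser = broken[0]
        ser.atoms = [a for a in ser.atoms if a.name != "OG"]
        sites_json, pdb_dir = write_family(
            tmp_path,
            {"a": (triad, 0, 0), "b": (canonical_triad_geometry(), 0, 0), "c": (broken, 0, 0)},
        )
        with caplog.at_level(logging.WARNING):
            e = load_ensemble(sites_json, pdb_dir)
        assert len(e.sites) == 2
        assert any("skipping site c" in r.message for r in caplog.records)

    def test_asp_and_glu_homologs_share_correspondence(self, tmp_path):
        triad = canonical_triad_geometry()
        glu_variant = canonical_triad_geometry()
        glu_variant[2] = mutate_functional(glu_variant[2], "GLU")
        sites_json, pdb_dir = write_family(
            tmp_path, {"asp": (triad, 0, 0), "glu": (glu_variant, 0, 0)}
        )
        e = load_ensemble(sites_json, pdb_dir)
        assert len(e.correspondence) == 5
        assert rmsd_fitted(e.sites[0].coords, e.sites[1].coords) == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_definitions_give_zero_rmsd(self, tmp_path):
        sites_json, pdb_dir = write_family(
            tmp_path,
            {"a": (canonical_triad_geometry(), 0, 0), "b": (canonical_triad_geometry(), 0, 0)},
        )
        e = load_ensemble(sites_json, pdb_dir)
        assert rmsd_fitted(e.sites[0].coords, e.sites[1].coords) == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_two_usable_sites_rejected(self, tmp_path):
        sites_json, pdb_dir = write_family(
            tmp_path, {"a": (canonical_triad_geometry(), 0, 0)}
        )
        with pytest.raises(EnsembleError):
            load_ensemble(sites_json, pdb_dir)


class TestClusterSites:
    def test_identical_sites_form_one_cluster(self):
        e, _ = generate_ensemble(1, 6, 0.0, 0.0, seed=1)
        result = cluster_sites(e, prune_height=0.5)
        assert result.n_clusters == 1

    def test_three_states_recovered_exactly(self):
        e, labels = generate_ensemble(3, 20, 1.5, 0.15, seed=7)
        result = cluster_sites(e, prune_height=1.0)
        assert result.n_clusters == 3
        assert adjusted_rand_score(labels, result.labels) == pytest.approx(1.0)

    def test_prune_height_limits(self):
        e, _ = generate_ensemble(3, 4, 1.5, 0.15, seed=7)
        assert cluster_sites(e, prune_height=1e6).n_clusters == 1
        assert cluster_sites(e, prune_height=1e-9).n_clusters == len(e.sites)

    def test_partitions_refine_as_height_drops(self):
        e, _ = generate_ensemble(3, 6, 1.5, 0.15, seed=7)
        fine = cluster_sites(e, prune_height=0.3).labels
        coarse = cluster_sites(e, prune_height=2.5).labels
        # every fine cluster sits inside exactly one coarse cluster
        for k in set(fine):
            parents = {coarse[i] for i in range(len(fine)) if fine[i] == k}
            assert len(parents) == 1

    def test_labels_invariant_under_per_site_rigid_motion(self):
        e, _ = generate_ensemble(3, 5, 1.5, 0.15, seed=7)
        rng = np.random.default_rng(0)
        for site in e.sites:
            R, t = random_rigid(rng)
            site.coords = CoordSet(site.coords.coords @ R.T + t, list(site.coords.labels))
        moved = cluster_sites(e, prune_height=1.0)
        fresh, labels = generate_ensemble(3, 5, 1.5, 0.15, seed=7)
        assert np.array_equal(moved.labels, cluster_sites(fresh, prune_height=1.0).labels)

    def test_permuting_sites_permutes_labels_consistently(self):
        e, _ = generate_ensemble(2, 5, 1.5, 0.1, seed=3)
        base = cluster_sites(e, prune_height=1.0).labels
        perm = np.arange(len(e.sites))[::-1]
        e.sites = [e.sites[i] for i in perm]
        permuted = cluster_sites(e, prune_height=1.0).labels
        assert adjusted_rand_score(base[perm], permuted) == pytest.approx(1.0)

    def test_nonpositive_prune_height_rejected(self):
        e, _ = generate_ensemble(1, 3, 0.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            cluster_sites(e, prune_height=0.0)


class TestRepresentativeSite:
    def test_singleton_represents_itself(self):
        e, _ = generate_ensemble(1, 3, 0.0, 0.1, seed=2)
        assert representative_site(e, [2]) == 2

    def test_exact_member_beats_noisy_ones(self):
        e, _ = generate_ensemble(1, 3, 0.0, 0.0, seed=4)
        rng = np.random.default_rng(8)
        for i in (1, 2):  # jitter all but site 0
            noisy = e.sites[i].coords.coords + rng.normal(0, 0.3, (5, 3))
            e.sites[i].coords = CoordSet(noisy, list(e.sites[i].coords.labels))
        assert representative_site(e, [0, 1, 2]) == 0

    def test_brute_force_argmin_agreement(self):
        e, _ = generate_ensemble(2, 8, 1.2, 0.2, seed=5)
        members = list(range(len(e.sites)))
        rep = representative_site(e, members)
        consensus, _, _ = iterative_consensus([e.sites[i].coords for i in members])
        dists = [rmsd_fitted(e.sites[i].coords, consensus) for i in members]
        assert rep == int(np.argmin(dists))

    def test_tie_breaks_to_smaller_index(self):
        e, _ = generate_ensemble(1, 2, 0.0, 0.0, seed=6)
        assert representative_site(e, [0, 1]) == 0

    def test_empty_member_list_rejected(self):
        e, _ = generate_ensemble(1, 2, 0.0, 0.0, seed=6)
        with pytest.raises(ValueError):
            representative_site(e, [])


class TestExtractFamilyTemplates:
    def test_single_conformation_yields_one_template(self):
        e, _ = generate_ensemble(1, 5, 0.0, 0.05, seed=9)
        templates, _ = extract_family_templates(e, prune_height=1.0)
        assert len(templates) == 1
        assert templates[0].id == "synthetic_triad.c0"

    def test_three_state_family_yields_state_specific_templates(self):
        e, labels = generate_ensemble(3, 10, 1.5, 0.15, seed=7)
        templates, result = extract_family_templates(e, prune_height=1.0)
        assert len(templates) == 3
        structures = [
            assemble_structure(s.structure_id, {"A": s.residues}) for s in e.sites
        ]
        for k, t in enumerate(templates):
            own = [i for i in range(len(labels)) if result.labels[i] == k]
            others = [i for i in range(len(labels)) if result.labels[i] != k]
            hit_own = sum(
                bool(match_template(t, structures[i], MatchParams(delta=1.0, rho=1.0)))
                for i in own
            )
            hit_other = sum(
                bool(match_template(t, structures[i], MatchParams(delta=1.0, rho=0.3)))
                for i in others
            )
            assert hit_own >= 0.9 * len(own)
            assert hit_other == 0

    def test_small_clusters_droppable(self):
        e, _ = generate_ensemble(3, 2, 1.5, 0.1, seed=12)
        all_templates, _ = extract_family_templates(e, prune_height=1.0)
        kept, _ = extract_family_templates(
            e, prune_height=1.0, min_cluster_size=3, drop_small_clusters=True
        )
        assert len(all_templates) == 3
        assert kept == []  # every state has only 2 members
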