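"""Distance-constrained search: candidates, DFS matches, order, significance."""

import numpy as np
import pytest

from casite.errors import CasiteError
from casite.matcher import (
    MatchParams,
    candidates,
    check_sequence_order,
    empirical_significance,
    match_template,
)
from casite.structure_io import Atom, Residue, assemble_structure
from casite.synthetic import (
    FixtureSpec,
    PlantSpec,
    build_residue,
    canonical_triad_geometry,
    generate_structure,
    move_residue,
    mutate_functional,
)
from casite.structure_io import read_pdb
from casite.template_model import build_template

from conftest import place_residues, random_rigid
from helpers_oracles import brute_force_matches, quaternion_superpose


def fuzzy_variant_structure():
    """Thr/His/Glu at the exact triad geometry plus unrelated residues."""
    ser, his, asp = canonical_triad_geometry()
    thr = mutate_functional(ser, "THR")
    glu = mutate_functional(asp, "GLU")
    extras = place_residues([build_residue("ALA"), build_residue("GLY")], spacing=10.0)
    extras = [move_residue(r, np.eye(3), np.array([0.0, 30.0, 0.0])) for r in extras]
    residues = [thr, his, glu] + extras
    for i, r in enumerate(residues):
        r.seqnum = str(i + 1)
    return assemble_structure("fuzzy", {"A": residues})


class TestCandidates:
    def test_fuzzy_types_fill_each_group_once(self, triad_functional):
        s = fuzzy_variant_structure()
        cand = candidates(triad_functional, s)
        assert [len(c) for c in cand] == [1, 1, 1]
        assert cand[0][0][0].restype == "THR"
        assert cand[2][0][0].restype == "GLU"

    def test_asp_candidate_has_two_symmetric_mappings(self, triad_functional, triad_structure):
        cand = candidates(triad_functional, triad_structure)
        asp_entries = [(r, maps) for r, maps in cand[2] if r.restype == "ASP"]
        assert len(asp_entries) == 1
        _, mappings = asp_entries[0]
        named = {tuple(a.name for a in m) for m in mappings}
        assert ("OD1", "OD2") in named and ("OD2", "OD1") in named

    def test_backbone_groups_accept_every_complete_residue(self, triad_backbone):
        s = fuzzy_variant_structure()
        cand = candidates(triad_backbone, s)
        n = s.n_residues()
        assert all(len(c) == n for c in cand)


class TestMatchTemplate:
    def test_self_match_unique_and_exact(self, triad_functional, triad_structure):
        matches = match_template(triad_functional, triad_structure)
        assert len(matches) == 1
        m = matches[0]
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert [r.restype for r in m.residues] == ["SER", "HIS", "ASP"]

    def test_planted_triad_recovered_and_oracle_identical(self, triad_functional):
        text, truth = generate_structure(
            FixtureSpec(seed=11, n_decoys=40, planted=(PlantSpec(sigma=0.2),))
        )
        s = read_pdb(text, "fx")
        params = MatchParams(delta=1.0, rho=2.0)
        matches = match_template(triad_functional, s, params)
        assert matches
        top = matches[0]
        assert top.residue_key == frozenset(truth.sites[0].residue_ids)
        oracle = brute_force_matches(triad_functional, s, delta=1.0, rho=2.0)
        assert {m.residue_key for m in matches} == set(oracle)
        for m in matches:
            assert m.rmsd == pytest.approx(oracle[m.residue_key][0], abs=1e-9)

    def test_displaced_his_breaks_distance_constraint(self, triad_functional, triad_residues):
        ser, his, asp = triad_residues
        his_moved = move_residue(his, np.eye(3), np.array([0.0, 0.0, 3.0]))
        s = assemble_structure("broken", {"A": [ser, his_moved, asp]})
        assert match_template(triad_functional, s, MatchParams(delta=1.0, rho=2.0)) == []

    def test_symmetric_swaps_not_reported_separately(self, triad_functional, triad_structure):
        matches = match_template(triad_functional, triad_structure)
        keys = [m.residue_key for m in matches]
        assert len(keys) == len(set(keys))

    def test_rigid_motion_invariance(self, triad_functional):
        text, _ = generate_structure(
            FixtureSpec(seed=21, n_decoys=20, planted=(PlantSpec(sigma=0.2),))
        )
        s = read_pdb(text, "fx")
        rng = np.random.default_rng(5)
        R, t = random_rigid(rng)
        moved = assemble_structure(
            s.id,
            {
                c: [move_residue(r, R, t) for r in residues]
                for c, residues in s.chains.items()
            },
        )
        m1 = match_template(triad_functional, s)
        m2 = match_template(triad_functional, moved)
        assert [m.residue_key for m in m1] == [m.residue_key for m in m2]
        for a, b in zip(m1, m2):
            assert a.rmsd == pytest.approx(b.rmsd, abs=1e-9)

    @pytest.mark.parametrize("loosen", ["delta", "rho"])
    def test_monotone_in_tolerances(self, triad_functional, loosen):
        text, _ = generate_structure(
            FixtureSpec(seed=31, n_decoys=40, planted=(PlantSpec(sigma=0.3),))
        )
        s = read_pdb(text, "fx")
        tight = MatchParams(delta=0.8, rho=1.0)
        loose = MatchParams(
            delta=1.6 if loosen == "delta" else 0.8,
            rho=2.0 if loosen == "rho" else 1.0,
        )
        keys_tight = {m.residue_key for m in match_template(triad_functional, s, tight)}
        keys_loose = {m.residue_key for m in match_template(triad_functional, s, loose)}
        assert keys_tight <= keys_loose

    def test_truncation_flagged(self, triad_backbone):
        text, _ = generate_structure(FixtureSpec(seed=41, n_decoys=12))
        s = read_pdb(text, "fx")
        out = match_template(triad_backbone, s, MatchParams(delta=100.0, rho=100.0, max_matches=2))
        assert out.truncated


class TestSequenceOrder:
    def _match_with_indices(self, triad_functional, idx):
        residues = canonical_triad_geometry()
        for r, i in zip(residues, idx):
            r.chain_index = i
        from casite.matcher import Match
        from casite.geometry import Transform

        return Match(
            template_id="t", structure_id="s", residues=tuple(residues),
            atom_map=(), rmsd=0.0, transform=Transform.identity(),
        )

    def test_ascending_indices_in_order(self, triad_functional):
        assert check_sequence_order(self._match_with_indices(triad_functional, (5, 40, 80)))

    def test_out_of_order_detected(self, triad_functional):
        assert not check_sequence_order(self._match_with_indices(triad_functional, (5, 80, 40)))

    def test_his_asp_swap_out_of_order(self, triad_functional):
        # His and Asp occur swapped in sequence relative to the template
        assert not check_sequence_order(self._match_with_indices(triad_functional, (10, 50, 30)))

    def test_multi_chain_flagged_false(self, triad_functional):
        m = self._match_with_indices(triad_functional, (1, 2, 3))
        object.__setattr__(m.residues[1], "chain", "B")
        assert not check_sequence_order(m)
        assert m.multi_chain


class TestEmpiricalSignificance:
    @pytest.fixture()
    def decoys(self):
        structures = []
        for seed in (101, 102, 103):
            text, _ = generate_structure(FixtureSpec(seed=seed, n_decoys=40))
            structures.append(read_pdb(text, f"decoy{seed}"))
        return structures

    def test_zero_rmsd_gets_minimum_value(self, triad_functional, triad_structure, decoys):
        (m,) = match_template(triad_functional, triad_structure)
        p = empirical_significance(m, decoys, triad_functional, n_samples=100, seed=3)
        assert 0 < p <= 1 / 50  # only exact-zero ties could inflate it

    def test_huge_rmsd_saturates_at_one(self, triad_functional, triad_structure, decoys):
        (m,) = match_template(triad_functional, triad_structure)
        m.rmsd = 1e6
        assert empirical_significance(m, decoys, triad_functional, n_samples=100, seed=3) == 1.0

    def test_monotone_in_rmsd(self, triad_functional, triad_structure, decoys):
        (m,) = match_template(triad_functional, triad_structure)
        values = []
        for r in (0.0, 1.0, 3.0, 10.0):
            m.rmsd = r
            values.append(
                empirical_significance(m, decoys, triad_functional, n_samples=150, seed=9)
            )
        assert values == sorted(values)

    def test_matches_reference_reimplementation(self, triad_functional, triad_structure, decoys):
        """Same seed, same sampling scheme, RMSD via the quaternion oracle."""
        (m,) = match_template(triad_functional, triad_structure)
        m.rmsd = 2.0
        got = empirical_significance(m, decoys, triad_functional, n_samples=200, seed=17)

        rng = np.random.default_rng(17)
        per_structure = []
        for s in decoys:
            cand = candidates(triad_functional, s)
            if all(cand):
                per_structure.append(cand)
        hits = n_eff = 0
        for _ in range(200):
            cand = per_structure[rng.integers(len(per_structure))]
            combo_res, coords, ok = [], [], True
            for g in range(triad_functional.n_groups):
                res, mappings = cand[g][rng.integers(len(cand[g]))]
                if any(res.id == r.id for r in combo_res):
                    ok = False
                    break
                mapping = mappings[rng.integers(len(mappings))]
                combo_res.append(res)
                coords.extend(a.xyz for a in mapping)
            if not ok:
                continue
            n_eff += 1
            _, rmsd = quaternion_superpose(triad_functional.coords, np.vstack(coords))
            if rmsd <= m.rmsd:
                hits += 1
        assert got == pytest.approx((1 + hits) / (1 + n_eff), abs=1e-12)

    def test_no_compatible_decoys_flagged(self, triad_functional):
        gly_only = assemble_structure(
            "gly", {"A": place_residues([build_residue("GLY") for _ in range(4)])}
        )
        (m,) = [
            m for m in match_template(
                triad_functional,
                assemble_structure("t", {"A": canonical_triad_geometry()}),
            )
        ]
        with pytest.raises(CasiteError):
            empirical_significance(m, [gly_only], triad_functional, n_samples=10, seed=1)
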