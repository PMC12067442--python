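"""Nitrogen-feature enumeration: validity rules, symmetry dedup, orbits."""

from collections import Counter

import networkx as nx
import pytest

from aminescaffolds import (
    FeatureKind,
    amine_class,
    enumerate_all,
    enumerate_scaffolds,
    feature_candidates,
    fixture_molecule,
    from_smiles,
    generate_monocycles,
    generate_spiro,
    is_valid,
)
from aminescaffolds.enumeration import AmineClass


class TestAmineClass:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("piperazine", AmineClass.NH),
            ("dabco", AmineClass.N),
            ("cyclohexylamine", AmineClass.NH2),
        ],
    )
    def test_fixture_nitrogens(self, name, expected):
        g = fixture_molecule(name)
        for i, e in enumerate(g.elements):
            if e == "N":
                assert amine_class(g, i) is expected

    def test_carbon_rejected(self):
        g = fixture_molecule("cyclohexane")
        with pytest.raises(TypeError):
            amine_class(g, 0)


class TestValidityRules:
    def test_aminal_hexahydropyrimidine(self):
        ok, v = is_valid(from_smiles("C1CNCNC1"))
        assert not ok and v.rule == "aminal"

    def test_piperazine_valid(self):
        ok, v = is_valid(fixture_molecule("piperazine"))
        assert ok and v is None

    def test_hydrazine_bond(self):
        ok, v = is_valid(from_smiles("C1CCNNC1"))
        assert not ok and v.rule == "hydrazine"

    def test_quaternary_spiro_nitrogen(self):
        (spiro,) = generate_spiro({(5, 5)})
        center = next(
            i for i in range(spiro.graph.n_atoms) if spiro.graph.degree(i) == 4
        )
        g = spiro.graph.with_elements({center: "N"})
        ok, v = is_valid(g)
        assert not ok and v.rule == "quaternary"

    def test_geminal_diamine_is_aminal(self):
        ok, v = is_valid(from_smiles("NC(N)C1CCCC1"))
        assert not ok and v.rule == "aminal"

    def test_dabco_passes_all_rules(self):
        ok, _ = is_valid(fixture_molecule("dabco"))
        assert ok


class TestFeatureCandidates:
    def test_cyclopentane_singles(self):
        (skel,) = generate_monocycles({5})
        cands = feature_candidates(skel, 1)
        kinds = Counter(f.kind for (f,) in cands)
        assert kinds == {FeatureKind.RING_N: 5, FeatureKind.EXO_NH2: 5}

    def test_spiro_center_never_targeted(self):
        (spiro,) = generate_spiro({(5, 5)})
        center = next(
            i for i in range(spiro.graph.n_atoms) if spiro.graph.degree(i) == 4
        )
        for k in (1, 2):
            for feats in feature_candidates(spiro, k):
                assert all(f.site != center for f in feats)

    def test_pairs_never_share_a_site(self):
        (skel,) = generate_monocycles({6})
        for a, b in feature_candidates(skel, 2):
            assert a.site != b.site

    def test_bad_k(self):
        (skel,) = generate_monocycles({5})
        with pytest.raises(ValueError):
            feature_candidates(skel, 3)


def automorphism_orbits(graph, sites):
    """Oracle: orbits of ``sites`` under the full automorphism group,
    found by VF2 self-isomorphism search (independent of canonicalization)."""
    g = graph.to_networkx()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    parent = {s: s for s in sites}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for mapping in matcher.isomorphisms_iter():
        for s in sites:
            a, b = find(s), find(mapping[s])
            if a != b:
                parent[a] = b
    return len({find(s) for s in sites})


class TestEnumerateScaffolds:
    def test_cyclopentane_profile_breakdown(self):
        (skel,) = generate_monocycles({5})
        scaffolds = enumerate_scaffolds(skel)
        assert Counter(s.profile for s in scaffolds) == {
            "NH": 1, "NH2": 1, "NH/NH2": 1, "NH2/NH2": 2,
        }

    def test_cyclohexane_eight_with_one_piperazine(self):
        (skel,) = generate_monocycles({6})
        scaffolds = enumerate_scaffolds(skel)
        assert len(scaffolds) == 8
        nh_nh = [s for s in scaffolds if s.profile == "NH/NH"]
        assert len(nh_nh) == 1
        from aminescaffolds import canonical_key

        assert nh_nh[0].key == canonical_key(fixture_molecule("piperazine"))

    def test_cycloheptane_eight(self):
        (skel,) = generate_monocycles({7})
        assert len(enumerate_scaffolds(skel)) == 8

    def test_all_outputs_valid_and_consistent(self, full_scaffolds):
        for sc in full_scaffolds:
            ok, _ = is_valid(sc.graph)
            assert ok
            n_atoms = sum(1 for e in sc.graph.elements if e == "N")
            assert n_atoms == len(sc.features)

    def test_single_ring_n_counts_equal_automorphism_orbits(
        self, full_skeletons
    ):
        """Unique single C->N scaffolds per skeleton == orbit count of
        valid nitrogen sites under the skeleton's automorphism group."""
        for skel in full_skeletons:
            g = skel.graph
            sites = [i for i in range(g.n_atoms) if g.degree(i) <= 3]
            expected = automorphism_orbits(g, sites)
            ring_n_only = {
                sc.key
                for sc in enumerate_scaffolds(skel)
                if len(sc.features) == 1
                and sc.features[0].kind is FeatureKind.RING_N
            }
            assert len(ring_n_only) == expected


class TestEnumerateAll:
    def test_monocycles_only_21(self):
        assert len(enumerate_all(generate_monocycles({5, 6, 7}))) == 21

    def test_union_of_one_matches_single(self):
        (skel,) = generate_monocycles({6})
        assert [s.key for s in enumerate_all([skel])] == [
            s.key for s in enumerate_scaffolds(skel)
        ]

    def test_global_dedup_is_noop_across_skeletons(self, full_skeletons):
        per_skeleton = sum(
            len(enumerate_scaffolds(s)) for s in full_skeletons
        )
        assert per_skeleton == len(enumerate_all(full_skeletons))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            enumerate_all([])

    def test_dabco_is_the_unique_ditertiary_on_bicyclooctane(
        self, full_scaffolds
    ):
        from aminescaffolds import canonical_key

        nn = [s for s in full_scaffolds if s.profile == "N/N"]
        dabco_key = canonical_key(fixture_molecule("dabco"))
        assert dabco_key in {s.key for s in nn}
        on_222 = [
            s for s in nn if s.parent.name == "bicyclo[2.2.2]octane"
        ]
        assert [s.key for s in on_222] == [dabco_key]
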