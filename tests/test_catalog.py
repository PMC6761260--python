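import math

import numpy as np
import pytest

from mircomp.catalog import (
    ConservationClass,
    FamilyAssignment,
    MatureMiRNA,
    annotate_known,
    assign_isomirs,
    build_families,
    classify_conservation,
    dollo_gain_loss,
    gene_species_map,
    guaranteed_kmer,
    local_align_score,
    sequences_linked,
    variability_table,
)
from mircomp.tree import SpeciesTree, TreeError

BASE = "UGGAAUGUAAAGAAGUAUGUAU"  # 22 nt


def sub(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1 :]


class TestLocalAlign:
    def test_identical_short_sequences(self):
        score, cols, ident = local_align_score("ACGU", "ACGU")
        assert (score, cols, ident) == (20.0, 4, 1.0)

    def test_no_similarity_gives_empty_alignment(self):
        assert local_align_score("AAAA", "CCCC") == (0.0, 0, 0.0)

    def test_perfect_substring(self):
        score, cols, ident = local_align_score("ACGUACGU", "GUAC")
        assert (score, cols, ident) == (20.0, 4, 1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align_score("", "ACGU")


class TestBuildFamilies:
    def test_identical_sequences_one_family(self):
        ms = [MatureMiRNA("a", "s1", BASE), MatureMiRNA("b", "s2", BASE)]
        fam = build_families(ms)
        assert fam.family_of == {"a": "a", "b": "a"}

    def test_single_linkage_chains_through_middle(self):
        # a-b and b-c are edges (2 substitutions apart) but a-c is not (4)
        a = BASE
        b = sub(sub(a, 10, "C"), 15, "C")
        c = sub(sub(b, 12, "C"), 18, "C")
        assert sequences_linked(a, b) and sequences_linked(b, c)
        assert not sequences_linked(a, c)
        fam = build_families([
            MatureMiRNA("a", "s", a), MatureMiRNA("b", "s", b),
            MatureMiRNA("c", "s", c),
        ])
        assert set(fam.family_of.values()) == {"a"}

    def test_dissimilar_sequences_stay_singletons(self):
        seqs = ["UGGAAUGUAAAGAAGUAUGUAU",
                "CCGCGAUACCCUGGCCAAUCGG",
                "AAGUCCGGUUAGGACGAUAUCC"]
        ms = [MatureMiRNA(f"m{i}", "s", q) for i, q in enumerate(seqs)]
        fam = build_families(ms)
        assert len(set(fam.family_of.values())) == 3

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGU"))
        seqs = ["".join(rng.choice(bases, 22)) for _ in range(15)]
        seqs += [sub(s, 5, "A") for s in seqs[:5]]  # guaranteed relatives
        ms = [MatureMiRNA(f"m{i:02d}", "s", q) for i, q in enumerate(seqs)]
        fam1 = build_families(ms)
        fam2 = build_families(list(reversed(ms)))
        assert fam1.family_of == fam2.family_of

    def test_prefilters_match_unpruned_edges(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGU"))
        seqs = ["".join(rng.choice(bases, 22)) for _ in range(25)]
        seqs += [sub(s, 3, "G") for s in seqs[:6]]
        ms = [MatureMiRNA(f"m{i:02d}", "s", q) for i, q in enumerate(seqs)]
        fam = build_families(ms)
        # naive edges: full alignment for every pair, no prefilters
        parent = {m.id: m.id for m in ms}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, a in enumerate(ms):
            for b in ms[i + 1 :]:
                _, cols, ident = local_align_score(a.sequence, b.sequence)
                if (a.sequence == b.sequence) or (cols >= 16 and ident >= 0.85):
                    parent[max(find(a.id), find(b.id))] = min(find(a.id), find(b.id))
        naive = {}
        for m in ms:
            naive.setdefault(find(m.id), set()).add(m.id)
        ours = {}
        for mid, f in fam.family_of.items():
            ours.setdefault(f, set()).add(mid)
        assert set(map(frozenset, naive.values())) == set(
            map(frozenset, ours.values())
        )

    def test_guaranteed_kmer_default_thresholds(self):
        assert guaranteed_kmer(0.85, 16, 22) == 5
        assert guaranteed_kmer(0.75, 14, 22) >= 3


class TestIsomirs:
    def test_three_prime_variant_is_one_variable_gene(self):
        ms = [MatureMiRNA("a", "s1", BASE), MatureMiRNA("b", "s2", BASE[:-1])]
        fam = assign_isomirs(build_families(ms), ms)
        assert fam.gene_of["a"] == fam.gene_of["b"]
        assert fam.variable[fam.gene_of["a"]] is True

    def test_seed_difference_splits_genes(self):
        ms = [MatureMiRNA("a", "s1", BASE), MatureMiRNA("b", "s2", sub(BASE, 4, "C"))]
        fam = assign_isomirs(build_families(ms), ms)
        assert fam.family_of["a"] == fam.family_of["b"]
        assert fam.gene_of["a"] != fam.gene_of["b"]

    def test_singleton_gene_not_variable(self):
        ms = [MatureMiRNA("a", "s1", BASE)]
        fam = assign_isomirs(build_families(ms), ms)
        assert fam.variable[fam.gene_of["a"]] is False


@pytest.fixture
def tree8():
    return SpeciesTree.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


class TestConservation:
    def test_three_way_classes(self, tree8):
        tips = set(tree8.tip_names)
        classes = classify_conservation(
            {"g1": tips, "g2": {"A"}, "g3": {"A", "B", "C"}}, tree8
        )
        assert classes.class_of == {
            "g1": "conserved", "g2": "species-specific", "g3": "non-conserved"
        }
        counts = classes.counts()
        assert sum(counts.values()) == 3

    def test_unknown_species_rejected(self, tree8):
        with pytest.raises(TreeError, match="Z"):
            classify_conservation({"g": {"Z"}}, tree8)

    def test_gene_species_map(self):
        ms = [MatureMiRNA("a", "s1", BASE), MatureMiRNA("b", "s2", BASE)]
        fam = assign_isomirs(build_families(ms), ms)
        gs = gene_species_map(fam, ms)
        assert list(gs.values()) == [{"s1", "s2"}]


class TestAnnotateKnown:
    def test_identical_member_is_known(self):
        members = {"g": [MatureMiRNA("a", "s", BASE)]}
        assert annotate_known(members, {"ref1": BASE}) == {"g": "known"}

    def test_no_similarity_is_novel(self):
        members = {"g": [MatureMiRNA("a", "s", BASE)]}
        ref = {"ref1": "CCGCGAUACCCUGGCCAAUCGG"}
        assert annotate_known(members, ref) == {"g": "novel"}

    def test_identity_threshold_is_strict(self):
        two_subs = sub(sub(BASE, 5, "C"), 15, "C")  # 20/22 = 0.909
        three_subs = sub(two_subs, 10, "C")  # 19/22 = 0.864
        ref = {"r": BASE}
        assert annotate_known(
            {"g": [MatureMiRNA("a", "s", two_subs)]}, ref, min_identity=0.9
        ) == {"g": "known"}
        assert annotate_known(
            {"g": [MatureMiRNA("a", "s", three_subs)]}, ref, min_identity=0.9
        ) == {"g": "novel"}


def clade_tips(tree, node):
    return {l.taxon.label for l in node.leaf_iter()}


def brute_force_dollo(tree, presence):
    """Minimum events over every single-gain placement (enumeration)."""
    present = {t for t, v in presence.items() if v}
    best = None
    for node in tree.postorder():
        if not present <= clade_tips(tree, node):
            continue

        def losses(n):
            total = 0
            for child in n.child_nodes():
                if clade_tips(tree, child) & present:
                    total += losses(child)
                else:
                    total += 1
            return total

        events = 1 + losses(node)
        if best is None or events < best[1]:
            best = (tree.node_id(node), events)
    return best


class TestDollo:
    def test_present_everywhere_gains_at_root(self, tree8):
        gain, losses, n = dollo_gain_loss(
            tree8, {t: True for t in tree8.tip_names}
        )
        assert gain == tree8.node_id(tree8.root)
        assert losses == [] and n == 1

    def test_single_tip_gains_on_terminal_branch(self):
        tree = SpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gain, losses, n = dollo_gain_loss(
            tree, {"A": False, "B": True, "C": False, "D": False}
        )
        assert (gain, losses, n) == ("B", [], 1)

    def test_three_of_four_needs_one_loss(self):
        tree = SpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gain, losses, n = dollo_gain_loss(
            tree, {"A": True, "B": True, "C": False, "D": True}
        )
        assert gain == tree.node_id(tree.root)
        assert losses == ["C"] and n == 2

    def test_no_present_tip_rejected(self, tree8):
        with pytest.raises(ValueError):
            dollo_gain_loss(tree8, {t: False for t in tree8.tip_names})

    @pytest.mark.parametrize("newick", [
        "((((A:1,B:1):1,C:1):1,D:1):1,E:1);",  # 5-tip caterpillar
        "(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);",  # 6 tips
    ])
    def test_matches_exhaustive_enumeration(self, newick):
        tree = SpeciesTree.from_newick(newick)
        tips = tree.tip_names
        for mask in range(1, 2 ** len(tips)):
            presence = {t: bool(mask >> i & 1) for i, t in enumerate(tips)}
            gain, losses, n = dollo_gain_loss(tree, presence)
            ref_gain, ref_events = brute_force_dollo(tree, presence)
            assert n == ref_events
            assert gain == ref_gain


class TestVariabilityTable:
    def test_printed_row_percentages(self):
        class_of = {}
        variable = {}
        for i in range(108):
            g = f"c{i}"
            class_of[g] = "conserved"
            variable[g] = i < 51
        for i in range(424):
            g = f"s{i}"
            class_of[g] = "species-specific"
            variable[g] = i < 19
        classes = ConservationClass(class_of=class_of, presence={})
        assignment = FamilyAssignment(family_of={}, variable=variable)
        table, pct = variability_table(classes, assignment)
        assert table.tolist() == [[51, 57], [19, 405]]
        assert pct == [47.2, 4.5]

    def test_empty_class_percentage_is_nan(self):
        classes = ConservationClass(
            class_of={"g": "species-specific"}, presence={}
        )
        assignment = FamilyAssignment(family_of={}, variable={"g": False})
        table, pct = variability_table(classes, assignment)
        assert table[0].sum() == 0
        assert math.isnan(pct[0]) and pct[1] == 0.0
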