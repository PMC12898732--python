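"""Distances, neighbor joining, bootstrap and monophyly checks."""

import itertools
import math

import numpy as np
import pytest

import barhrm as b
from barhrm.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    clade_check,
    distance_matrix,
    nj_tree,
    pairwise_distance,
)


class TestPairwiseDistance:
    def test_p_distance_counts_mismatches(self):
        assert pairwise_distance("ACGT", "ACGA", model="p") == pytest.approx(0.25)

    def test_identical_sequences_are_zero(self):
        for model in ("p", "k2p"):
            assert pairwise_distance("ACGTACGTAC", "ACGTACGTAC", model=model) == 0.0

    def test_k2p_closed_form_pure_transitions(self):
        # P = 0.1, Q = 0 -> -0.5*ln(0.8)
        a = "A" * 9 + "A"
        bb = "A" * 9 + "G"
        assert pairwise_distance(a, bb) == pytest.approx(-0.5 * math.log(0.8))

    def test_gap_and_ambiguity_columns_excluded_pairwise(self):
        # 4 valid columns, one mismatch among them
        assert pairwise_distance("ACG-TN", "ACGAAA", model="p") == pytest.approx(0.25)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="satur"):
            pairwise_distance("AAAA", "GGGG")

    def test_no_valid_columns_raises(self):
        with pytest.raises(ValueError, match="valid"):
            pairwise_distance("----", "ACGT")

    def test_matches_skbio_hamming(self):
        from skbio import DNA
        from skbio.sequence.distance import hamming

        rng = np.random.default_rng(2)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 60))
            bb = "".join(rng.choice(list("ACGT"), 60))
            assert pairwise_distance(a, bb, model="p") == pytest.approx(
                float(hamming(DNA(a), DNA(bb)))
            )


def random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths."""
    # Build a random topology by sequential leaf attachment; track leaf paths.
    import networkx as nx

    g = nx.Graph()
    g.add_edge(0, 1, w=rng.uniform(0.05, 1.0))
    next_internal = n  # internal node ids start at n
    edges = [(0, 1)]
    for leaf in range(2, n):
        u, v = edges[rng.integers(len(edges))]
        w = g[u][v]["w"]
        g.remove_edge(u, v)
        mid = next_internal
        next_internal += 1
        split = rng.uniform(0.2, 0.8) * w
        g.add_edge(u, mid, w=split)
        g.add_edge(mid, v, w=w - split)
        g.add_edge(mid, leaf, w=rng.uniform(0.05, 1.0))
        edges.remove((u, v))
        edges += [(u, mid), (mid, v), (mid, leaf)]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(g, i, j, weight="w")
    return g, d


def tree_splits_from_graph(g, n):
    """Non-trivial bipartitions of the generating tree (edge cuts)."""
    import networkx as nx

    leaves = set(range(n))
    anchor = min(str(i) for i in leaves)
    splits = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(str(i) for i in (leaves & comp))
        if 1 < len(side) < n - 1:
            if anchor in side:
                side = frozenset(str(i) for i in leaves) - side
            splits.add(side)
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {c.name: c.branch_length for c in tree.root.clades}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_exact_recovery(self):
        # ((A:1,B:2):1,(C:3,D:4)) -> additive matrix written by hand
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # Path lengths reproduce the input matrix exactly (additivity).
        depths = {}
        for leaf in tree.get_terminals():
            depths[leaf.name] = tree.distance(tree.root, leaf)
        for i, j in itertools.combinations(range(4), 2):
            a, bname = "ABCD"[i], "ABCD"[j]
            ca = tree.common_ancestor({"name": a}, {"name": bname})
            dist = tree.distance({"name": a}, {"name": bname})
            assert dist == pytest.approx(d[i, j])

    def test_additive_recovery_100_random_trees(self):
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(4, 9))
            g, d = random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix([str(i) for i in range(n)], d))
            assert bipartitions(tree) == tree_splits_from_graph(g, n)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(6)
        for _ in range(5):
            n = 6
            _, d = random_additive_matrix(rng, n)
            ids = [str(i) for i in range(n)]
            ours = bipartitions(nj_tree(DistanceMatrix(ids, d)))
            sk_tree = sknj(SkDM(d, ids))
            anchor = min(ids)
            sk_splits = set()
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if anchor in side:
                    side = frozenset(ids) - side
                if 1 < len(side) < n - 1:
                    sk_splits.add(side)
            assert ours == sk_splits

    def test_nonfinite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            DistanceMatrix(list("ABC"), d)


def two_clade_alignment(rng, n_per_group=5, length=300, n_fixed=20):
    """Two groups separated by fixed differences plus light private noise."""
    base = rng.choice(list("ACGT"), size=length)
    other = base.copy()
    sites = rng.choice(length, size=n_fixed, replace=False)
    for s in sites:
        other[s] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[s]]
    ids, seqs = [], []
    for g, template in (("PG", base), ("PN", other)):
        for i in range(n_per_group):
            seq = template.copy()
            # a couple of private substitutions per sample
            for s in rng.choice(length, size=2, replace=False):
                seq[s] = rng.choice(list("ACGT"))
            ids.append(f"{g}{i}")
            seqs.append("".join(seq))
    return ids, seqs


class TestBootstrap:
    def test_fixed_difference_clades_get_full_support(self):
        rng = np.random.default_rng(13)
        ids, seqs = two_clade_alignment(rng)
        tree = bootstrap_support(ids, seqs, n_reps=200, seed=1)
        groups = {
            "PG": {i for i in ids if i.startswith("PG")},
            "PN": {i for i in ids if i.startswith("PN")},
        }
        assert clade_check(tree, groups) == {"PG": True, "PN": True}
        supports = [
            c.confidence for c in tree.get_nonterminals()
            if c.confidence is not None
            and frozenset(l.name for l in c.get_terminals()) in
            (frozenset(groups["PG"]), frozenset(groups["PN"]))
        ]
        assert supports and all(s > 95 for s in supports)

    def test_single_replicate_supports_are_0_or_100(self):
        rng = np.random.default_rng(3)
        ids, seqs = two_clade_alignment(rng, n_per_group=3, n_fixed=10)
        tree = bootstrap_support(ids, seqs, n_reps=1, seed=5)
        sup = [c.confidence for c in tree.get_nonterminals() if c.confidence is not None]
        assert sup and all(s in (0, 100) for s in sup)

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(4)
        ids, seqs = two_clade_alignment(rng, n_per_group=3)
        t1 = bootstrap_support(ids, seqs, n_reps=50, seed=9)
        t2 = bootstrap_support(ids, seqs, n_reps=50, seed=9)
        s1 = sorted(c.confidence for c in t1.get_nonterminals() if c.confidence is not None)
        s2 = sorted(c.confidence for c in t2.get_nonterminals() if c.confidence is not None)
        assert s1 == s2

    def test_invalid_reps_rejected(self):
        rng = np.random.default_rng(4)
        ids, seqs = two_clade_alignment(rng, n_per_group=2)
        with pytest.raises(ValueError):
            bootstrap_support(ids, seqs, n_reps=0, seed=1)


class TestCladeCheck:
    def _tree(self):
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        return nj_tree(DistanceMatrix(list("ABCD"), d))

    def test_true_clade(self):
        assert clade_check(self._tree(), {"g": {"A", "B"}}) == {"g": True}

    def test_paraphyletic_group(self):
        assert clade_check(self._tree(), {"g": {"A", "C"}}) == {"g": False}

    def test_singleton_is_monophyletic(self):
        assert clade_check(self._tree(), {"g": {"A"}}) == {"g": True}

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            clade_check(self._tree(), {"g": {"Z"}})


class TestEndToEndConcordance:
    def test_hrm_calls_agree_with_barcode_clades(self):
        """Same synthetic species pair drives both the melt assay and the
        barcode tree; the two routes must agree on every sample."""
        rec_a, rec_b = b.simulate.make_species_pair_fasta(
            length=400, n_snps=3, indel_len=12, gc_target=0.6, seed=21
        )
        aln = b.align_global(rec_a.sequence, rec_b.sequence)
        cands = b.enumerate_amplicons(aln, b.find_variant_sites(aln))
        report = b.screen_candidates(cands)
        chosen = next(c for c in cands if c.name == report.nominated)

        tm_pg = b.simulate.tm_with_dye_shift(chosen.amplicon_a)
        tm_pn = b.simulate.tm_with_dye_shift(chosen.amplicon_b)
        spec = b.CohortSpec(
            groups=[b.GroupSpec("PG", 6, tm_pg), b.GroupSpec("PN", 4, tm_pn)],
            seed=77,
        )
        curves, truth = b.simulate_cohort(spec)
        refs = {
            "PG": truth[truth.true_label == "PG"].sample_id[:2].tolist(),
            "PN": truth[truth.true_label == "PN"].sample_id[:2].tolist(),
        }
        analysis = b.analyze_cohort(curves, refs)
        hrm_calls = {c.sample_id: c.call for c in analysis.calls}

        # Barcode route: per-sample sequences are the aligned species
        # templates, so all samples share one alignment frame.
        gapped = {"PG": aln.aligned_a, "PN": aln.aligned_b}
        ids = list(truth.sample_id)
        seqs = [gapped[lab] for lab in truth.true_label]
        tree = nj_tree(distance_matrix(ids, seqs, model="p"))
        clades = clade_check(
            tree,
            {
                "PG": set(truth[truth.true_label == "PG"].sample_id),
                "PN": set(truth[truth.true_label == "PN"].sample_id),
            },
        )
        truth_map = dict(zip(truth.sample_id, truth.true_label))
        assert b.concordance(analysis.calls, truth_map).percent_agreement == 100.0
        assert all(clades.values())
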