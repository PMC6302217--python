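"""Comparative-genomics operations against brute-force and closed-form
oracles: dot plots, global identity (Gotoh DP), RSD recovery of planted
orthologs, shared cores, Welch tests, networks, and the proteome tree."""

from io import StringIO

import numpy as np
import pytest
from scipy import stats
from skbio import TreeNode

from thermavir.compare import (CategoryProfile, OrthologPair, dotplot_matches,
                               group_similarity, pairwise_identity,
                               proteome_tree, rsd_orthologs, shared_core,
                               tnf_network, welch_category_test)
from thermavir.contig import Contig, reverse_complement
from thermavir.errors import InputError, InsufficientInputError, ParameterError
from thermavir.synth import (generate_phage_set, generate_proteome_pair,
                             stage_rng, _mutate, _random_sequence)


class TestDotplot:
    def test_self_comparison_has_full_diagonal(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        matches = set(dotplot_matches(a, a, word=10))
        for x in range(len(a) - 9):
            assert (x, x, "+") in matches

    def test_reverse_complement_antidiagonal(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=200))
        matches = dotplot_matches(a, reverse_complement(a), word=10)
        rev = [(x, y) for x, y, s in matches if s == "-"]
        assert rev  # every forward word matches in reverse orientation
        assert all(y == len(a) - 10 - x for x, y in rev)

    def test_word_size_floor(self):
        with pytest.raises(ParameterError):
            dotplot_matches("ACGTACGT", "ACGTACGT", word=3)

    def test_matches_brute_force_enumeration(self, rng):
        w = 10
        a = "".join(rng.choice(list("ACGT"), size=2000))
        b = "".join(rng.choice(list("ACGT"), size=2000))
        # plant a shared word so the comparison is non-trivial
        b = b[:500] + a[100:100 + w] + b[500 + w:]
        got = set(dotplot_matches(a, b, word=w))
        expected = set()
        rc_b = reverse_complement(b)
        for x in range(len(a) - w + 1):
            wa = a[x:x + w]
            for y in range(len(b) - w + 1):
                if wa == b[y:y + w]:
                    expected.add((x, y, "+"))
                if wa == rc_b[y:y + w]:
                    expected.add((x, len(b) - w - y, "-"))
        assert got == expected


def gotoh_score(a, b, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    """Quadratic-space affine-gap global alignment score (reference DP)."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)   # gap in b (vertical)
    Y = np.full((n + 1, m + 1), neg)   # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_disjoint(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=150))
        b = "".join(rng.choice(list("ACGT"), size=140))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_planted_divergence_and_dp_oracle(self):
        rng = stage_rng(1, "ident")
        a = _random_sequence(rng, 300, 0.5)
        b = _mutate(a, 0.10, rng)
        ident = pairwise_identity(a, b)
        assert 85 <= ident <= 95
        # score of the package aligner equals the reference Gotoh DP
        from thermavir.compare import _global_aligner
        assert _global_aligner.score(a, b) == pytest.approx(gotoh_score(a, b))

    def test_gapped_case_matches_oracle(self):
        rng = stage_rng(2, "ident")
        a = _random_sequence(rng, 200, 0.5)
        b = a[:80] + a[95:]  # 15 nt deletion
        from thermavir.compare import _global_aligner
        assert _global_aligner.score(a, b) == pytest.approx(gotoh_score(a, b))


class TestGroupSimilarity:
    def test_identical_group(self):
        g = [Contig(f"g{i}", "ACGTTGCA" * 50, sample="s") for i in range(3)]
        df = group_similarity(g, {c.id: "s" for c in g})
        row = df.iloc[0]
        assert row["mean_identity"] == pytest.approx(100.0)
        assert row["sd_identity"] == pytest.approx(0.0)
        assert row["n_pairs"] == 3   # all pairs of a 3-genome group

    def test_low_divergence_group_scores_higher(self):
        rng = stage_rng(3, "groups")
        base1 = _random_sequence(rng, 1500, 0.5)
        base2 = _random_sequence(rng, 1500, 0.5)
        tight = [Contig(f"t{i}", _mutate(base1, 0.05, rng)) for i in range(3)]
        loose = [Contig(f"l{i}", _mutate(base2, 0.30, rng)) for i in range(3)]
        groups = {c.id: c.id[0] for c in tight + loose}
        df = group_similarity(tight + loose, groups).set_index("group")
        assert df.loc["t", "mean_identity"] > df.loc["l", "mean_identity"]

    def test_singleton_group_rejected(self):
        g = [Contig("a", "ACGT" * 100), Contig("b", "ACGT" * 100)]
        with pytest.raises(InsufficientInputError):
            group_similarity(g, {"a": "x", "b": "y"})


class TestTNFNetwork:
    def test_identical_pair(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        g = tnf_network([Contig("a", seq), Contig("b", seq)],
                        edge_threshold=0.5)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["weight"] == pytest.approx(1.0)
        assert g.nodes["a"]["weight"] == pytest.approx(1.0)

    def test_impossible_threshold_empty(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        g = tnf_network([Contig("a", seq), Contig("b", seq)],
                        edge_threshold=1.01)
        assert g.number_of_edges() == 0

    def test_within_target_edges_dominate(self):
        phages, manifest = generate_phage_set(
            6, [0.35, 0.65], length_range=(20_000, 30_000), seed=11)
        g = tnf_network(phages, edge_threshold=0.6)
        target = {pid: o["gc_target"] for pid, o in manifest.genome_origin.items()}
        within = sum(1 for a, b in g.edges if target[a] == target[b])
        cross = g.number_of_edges() - within
        assert within > cross

    def test_node_weight_consistency(self):
        phages, _ = generate_phage_set(5, [0.4, 0.6],
                                       length_range=(20_000, 25_000), seed=12)
        g = tnf_network(phages, edge_threshold=0.0)
        for node in g.nodes:
            incident = sum(d["weight"] for _, _, d in g.edges(node, data=True))
            assert g.nodes[node]["weight"] == pytest.approx(incident)


class TestRSD:
    def test_identical_proteomes(self):
        a, _, _ = generate_proteome_pair(4, 0, 100, 0.0, seed=1)
        b = {k.replace("A_", "B_"): v for k, v in a.items()}
        pairs = rsd_orthologs(a, b)
        assert len(pairs) == 4
        assert all(p.distance == pytest.approx(0.0) for p in pairs)

    def test_unrelated_proteins_empty(self):
        rng = stage_rng(4, "rsd")
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = {f"a{i}": "".join(aa[j] for j in rng.integers(0, 20, 80))
             for i in range(4)}
        b = {f"b{i}": "".join(aa[j] for j in rng.integers(0, 20, 80))
             for i in range(4)}
        assert rsd_orthologs(a, b) == []

    def test_planted_pairs_recovered(self):
        a, b, manifest = generate_proteome_pair(6, 4, 120, 0.05, seed=5)
        pairs = rsd_orthologs(a, b)
        got = sorted((p.protein_a, p.protein_b) for p in pairs)
        assert got == sorted(tuple(x) for x in manifest.true_orthologs)
        assert all(p.evalue_forward <= 1e-15 and p.evalue_reverse <= 1e-15
                   for p in pairs)

    def test_symmetric_in_arguments(self):
        a, b, _ = generate_proteome_pair(5, 2, 100, 0.05, seed=6)
        fwd = {(p.protein_a, p.protein_b) for p in rsd_orthologs(a, b)}
        rev = {(p.protein_b, p.protein_a) for p in rsd_orthologs(b, a)}
        assert fwd == rev

    def test_empty_proteome_rejected(self):
        with pytest.raises(InputError):
            rsd_orthologs({}, {"b": "ACDEF"})


class TestSharedCore:
    def _world(self, genomes, universal, missing_from=None):
        """Pairs linking gene g across every genome except exclusions."""
        pairs, p2g = {}, {}
        for g in genomes:
            for u in universal:
                if (g, u) != missing_from:
                    p2g[f"{g}_{u}"] = g
        for i, ga in enumerate(genomes):
            for gb in genomes[i + 1:]:
                lst = []
                for u in universal:
                    if (ga, u) != missing_from and (gb, u) != missing_from:
                        lst.append(OrthologPair(f"{ga}_{u}", f"{gb}_{u}",
                                                0.1, 1e-20, 1e-20))
                pairs[(ga, gb)] = lst
        return pairs, p2g

    def test_universal_gene_is_core(self):
        pairs, p2g = self._world(["G1", "G2", "G3"], ["g"])
        assert len(shared_core(pairs, p2g, ["G1", "G2", "G3"])) == 1

    def test_gene_missing_from_one_genome_not_core(self):
        pairs, p2g = self._world(["G1", "G2", "G3"], ["g"],
                                 missing_from=("G2", "g"))
        assert shared_core(pairs, p2g, ["G1", "G2", "G3"]) == []

    def test_ten_planted_universal_genes(self):
        genomes = ["G1", "G2", "G3", "G4"]
        universal = [f"u{i}" for i in range(10)]
        pairs, p2g = self._world(genomes, universal)
        assert len(shared_core(pairs, p2g, genomes)) == 10


class TestWelch:
    def _profiles(self, xa, xb, cat="c1"):
        profiles, groups = [], {}
        for i, v in enumerate(xa):
            profiles.append(CategoryProfile(f"a{i}", {cat: v, "rest": 1 - v}))
            groups[f"a{i}"] = "mat"
        for i, v in enumerate(xb):
            profiles.append(CategoryProfile(f"b{i}", {cat: v, "rest": 1 - v}))
            groups[f"b{i}"] = "sediment"
        return profiles, groups

    def test_identical_groups(self):
        profiles, groups = self._profiles([0.3, 0.4, 0.5], [0.5, 0.4, 0.3])
        df = welch_category_test(profiles, groups).set_index("category")
        assert df.loc["c1", "t"] == pytest.approx(0.0)
        assert df.loc["c1", "p"] == pytest.approx(1.0)

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(1)
        xa = 0.9 + rng.normal(0, 0.01, 5)
        xb = 0.1 + rng.normal(0, 0.01, 5)
        profiles, groups = self._profiles(xa, xb)
        df = welch_category_test(profiles, groups).set_index("category")
        assert bool(df.loc["c1", "significant"])

    def test_degenerate_flagged(self):
        profiles, groups = self._profiles([0.5, 0.5], [0.5, 0.5])
        df = welch_category_test(profiles, groups).set_index("category")
        assert bool(df.loc["c1", "degenerate"])
        assert not bool(df.loc["c1", "significant"])

    def test_matches_closed_form(self, rng):
        xa = rng.random(6)
        xb = rng.random(5)
        profiles, groups = self._profiles(xa, xb)
        df = welch_category_test(profiles, groups).set_index("category")
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        se2 = va / len(xa) + vb / len(xb)
        t = (xa.mean() - xb.mean()) / np.sqrt(se2)
        dof = se2 ** 2 / ((va / len(xa)) ** 2 / (len(xa) - 1)
                          + (vb / len(xb)) ** 2 / (len(xb) - 1))
        p = 2 * stats.t.sf(abs(t), dof)
        assert df.loc["c1", "t"] == pytest.approx(t)
        assert df.loc["c1", "df"] == pytest.approx(dof)
        assert df.loc["c1", "p"] == pytest.approx(p)

    def test_p_uniform_under_exchangeable_null(self):
        # fresh exchangeable profiles per replicate; KS distance < 0.05
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            xa, xb = rng.normal(0.5, 0.05, 6), rng.normal(0.5, 0.05, 6)
            res = stats.ttest_ind(xa, xb, equal_var=False)
            profiles, groups = self._profiles(xa, xb)
            df = welch_category_test(profiles, groups).set_index("category")
            assert df.loc["c1", "p"] == pytest.approx(float(res.pvalue))
            pvals.append(df.loc["c1", "p"])
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        d = np.max(np.abs(ecdf - pvals))
        assert d < 0.05


class TestProteomeTree:
    def test_identical_pair_forms_cherry(self):
        pairs = {("A", "B"): [OrthologPair(f"Ap{i}", f"Bp{i}", 0.0, 1e-30,
                                           1e-30) for i in range(6)],
                 ("A", "C"): [], ("B", "C"): []}
        sizes = {"A": 6, "B": 6, "C": 6}
        nwk = proteome_tree(["A", "B", "C"], pairs, sizes)
        tree = TreeNode.read(StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        a = tree.find("A")
        assert {t.name for t in a.parent.tips()} >= {"A", "B"}

    def test_nj_recovers_additive_topology(self):
        def fake(n):
            return [OrthologPair(f"p{i}", f"q{i}", 0.1, 1e-30, 1e-30)
                    for i in range(n)]
        genomes = ["A", "B", "C", "D"]
        # additive distances: d(AB)=d(CD)=0.2, all cross pairs 0.3
        pairs = {("A", "B"): fake(8), ("C", "D"): fake(8),
                 ("A", "C"): fake(7), ("A", "D"): fake(7),
                 ("B", "C"): fake(7), ("B", "D"): fake(7)}
        sizes = {g: 10 for g in genomes}
        nwk = proteome_tree(genomes, pairs, sizes)
        tree = TreeNode.read(StringIO(nwk))
        clades = [frozenset(t.name for t in node.tips())
                  for node in tree.non_tips(include_self=False)]
        assert frozenset({"A", "B"}) in clades or \
            frozenset({"C", "D"}) in clades

    def test_newick_contract_and_nonnegative_lengths(self):
        pairs = {("A", "B"): [], ("A", "C"): [], ("B", "C"): []}
        nwk = proteome_tree(["A", "B", "C"], pairs, {"A": 4, "B": 4, "C": 4})
        tree = TreeNode.read(StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0

    def test_too_few_genomes_rejected(self):
        with pytest.raises(InputError):
            proteome_tree(["A", "B"], {}, {"A": 1, "B": 1})
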