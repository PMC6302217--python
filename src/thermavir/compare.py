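"""Comparative genomics of reconstructed phage genomes.

Dot plots (exact shared words at a configurable word size, default 10,
both strands), pairwise and within-group whole-genome identity from an
affine-gap global alignment, tetranucleotide-correlation networks,
reciprocal-smallest-distance (RSD) orthologs at E-value/divergence cutoffs
of 1e-15 and 0.5, shared ortholog cores, per-category abundance profiles
with Welch's unequal-variance t-test, and a neighbor-joining proteome tree.

Alignment notes: global identity uses match +1 / mismatch -1 / gap open -5
/ extend -1; RSD scoring is local Smith-Waterman with BLOSUM62 (open -11 /
extend -1) and a fixed Karlin-Altschul parameterization (lambda=0.267,
K=0.041, the standard gapped-BLOSUM62 values) — RSD only needs a
consistent threshold, not database-calibrated significance. RSD distance
is 1 - fractional identity of the local alignment, a documented
simplification of the maximum-likelihood distance in the original
algorithm.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj
from statsmodels.stats.multitest import multipletests

from .contig import Contig, reverse_complement
from .errors import DegenerateVarianceError, InputError, InsufficientInputError, ParameterError
from .seqprofile import correlation_matrix, tnf_vector

#: the eight functional categories the phage ortholog set collapses into
FUNCTIONAL_CATEGORIES = (
    "host_lysis", "replication", "hypothetical", "recombination",
    "structural", "morphogenesis", "lysis_lysogeny_switching",
    "host_peptide_restriction",
)

KA_LAMBDA = 0.267   # gapped BLOSUM62
KA_K = 0.041


@dataclass
class OrthologPair:
    protein_a: str
    protein_b: str
    distance: float
    evalue_forward: float
    evalue_reverse: float


@dataclass
class CategoryProfile:
    genome_id: str
    abundances: dict[str, float]   # category -> relative abundance, sums to 1


# ---------------------------------------------------------------------------
# dot plots

def dotplot_matches(a: str, b: str, word: int = 10,
                    ) -> list[tuple[int, int, str]]:
    """All exact shared words between a and b, forward ('+') and
    reverse-complement ('-'), as 0-based start coordinate pairs (x in a,
    y in b)."""
    if word < 4:
        raise ParameterError(f"word size must be >= 4, got {word}")
    if len(a) < word or len(b) < word:
        raise ParameterError("sequences must be at least one word long")
    a, b = a.upper(), b.upper()
    index: dict[str, list[int]] = defaultdict(list)
    for y in range(len(b) - word + 1):
        index[b[y:y + word]].append(y)
    rc_b = reverse_complement(b)
    rc_index: dict[str, list[int]] = defaultdict(list)
    for y in range(len(rc_b) - word + 1):
        rc_index[rc_b[y:y + word]].append(y)
    matches: list[tuple[int, int, str]] = []
    for x in range(len(a) - word + 1):
        w = a[x:x + word]
        for y in index.get(w, ()):
            matches.append((x, y, "+"))
        for y_rc in rc_index.get(w, ()):
            # convert to the forward coordinate of the word's start in b
            matches.append((x, len(b) - word - y_rc, "-"))
    return matches


def matches_to_frame(matches: Sequence[tuple[int, int, str]]) -> pd.DataFrame:
    return pd.DataFrame(matches, columns=["x", "y", "strand"])


# ---------------------------------------------------------------------------
# whole-genome identity

_global_aligner = Align.PairwiseAligner()
_global_aligner.mode = "global"
_global_aligner.match_score = 1
_global_aligner.mismatch_score = -1
_global_aligner.open_gap_score = -5
_global_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the affine-gap global alignment of two
    nucleotide sequences (matches / alignment columns * 100)."""
    if not a or not b:
        raise InputError("sequences must be non-empty")
    aln = _global_aligner.align(a.upper(), b.upper())[0]
    c = aln.counts()
    total = c.identities + c.mismatches + c.gaps
    return 100.0 * c.identities / total if total else 0.0


def group_similarity(genomes: Sequence[Contig],
                     groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean and sample standard deviation of pairwise identity over all
    within-group genome pairs."""
    members: dict[str, list[Contig]] = defaultdict(list)
    for g in genomes:
        members[groups[g.id]].append(g)
    rows = []
    for group in sorted(members):
        gs = members[group]
        if len(gs) < 2:
            raise InsufficientInputError(
                f"group {group!r} has {len(gs)} genome(s); need >= 2")
        idents = [pairwise_identity(gs[i].sequence, gs[j].sequence)
                  for i in range(len(gs)) for j in range(i + 1, len(gs))]
        rows.append({"group": group, "n_pairs": len(idents),
                     "mean_identity": float(np.mean(idents)),
                     "sd_identity": float(np.std(idents, ddof=1))
                     if len(idents) > 1 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TNF correlation network

def tnf_network(genomes: Sequence[Contig],
                edge_threshold: float = 0.5) -> nx.Graph:
    """Undirected genome network: edges where TNF Pearson correlation >=
    threshold, edge weight = correlation, node weight = sum of incident
    edge weights (set threshold <= -1 to emit the complete graph)."""
    if len(genomes) < 2:
        raise InsufficientInputError("need >= 2 genomes")
    ids = [g.id for g in genomes]
    corr = correlation_matrix([tnf_vector(g) for g in genomes], ids=ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if corr[i, j] >= edge_threshold:
                g.add_edge(ids[i], ids[j], weight=float(corr[i, j]))
    for node in g.nodes:
        g.nodes[node]["weight"] = float(
            sum(d["weight"] for _, _, d in g.edges(node, data=True)))
    return g


def network_to_edge_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [{"a": a, "b": b, "weight": d["weight"]}
            for a, b, d in sorted(g.edges(data=True))]
    return pd.DataFrame(rows, columns=["a", "b", "weight"])


# ---------------------------------------------------------------------------
# RSD orthologs

_local_aligner = Align.PairwiseAligner()
_local_aligner.mode = "local"
_local_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_local_aligner.open_gap_score = -11
_local_aligner.extend_gap_score = -1


def _ka_evalue(score: float, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def rsd_orthologs(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
                  evalue_cutoff: float = 1e-15,
                  divergence_cutoff: float = 0.5) -> list[OrthologPair]:
    """Reciprocal-smallest-distance orthologs between two protein sets.

    (a, b) is emitted iff b is a's smallest-distance hit and a is b's,
    the E-value passes the cutoff in both directions, and the distance
    (1 - fractional identity of the local alignment) is within the
    divergence cutoff.
    """
    if not proteome_a or not proteome_b:
        raise InputError("proteomes must be non-empty")
    len_a = sum(len(s) for s in proteome_a.values())
    len_b = sum(len(s) for s in proteome_b.values())
    # distance and both-direction E-values for every pair passing the cutoff
    dist: dict[tuple[str, str], tuple[float, float, float]] = {}
    for pa, sa in proteome_a.items():
        for pb, sb in proteome_b.items():
            score = _local_aligner.score(sa, sb)
            ev_fwd = _ka_evalue(score, len(sa), len_b)
            ev_rev = _ka_evalue(score, len(sb), len_a)
            if ev_fwd > evalue_cutoff or ev_rev > evalue_cutoff:
                continue
            aln = _local_aligner.align(sa, sb)[0]
            c = aln.counts()
            cols = c.identities + c.mismatches + c.gaps
            if cols == 0:
                continue
            d = 1.0 - c.identities / cols
            if d <= divergence_cutoff:
                dist[(pa, pb)] = (d, ev_fwd, ev_rev)
    best_for_a: dict[str, tuple[tuple, str]] = {}
    best_for_b: dict[str, tuple[tuple, str]] = {}
    for (pa, pb), (d, ev_fwd, _) in dist.items():
        key = (d, ev_fwd, pb)
        if pa not in best_for_a or key < best_for_a[pa][0]:
            best_for_a[pa] = (key, pb)
    for (pa, pb), (d, _, ev_rev) in dist.items():
        key = (d, ev_rev, pa)
        if pb not in best_for_b or key < best_for_b[pb][0]:
            best_for_b[pb] = (key, pa)
    pairs = []
    for pa, (_, pb) in best_for_a.items():
        if best_for_b.get(pb, (None, None))[1] == pa:
            d, ev_fwd, ev_rev = dist[(pa, pb)]
            pairs.append(OrthologPair(pa, pb, d, ev_fwd, ev_rev))
    return sorted(pairs, key=lambda p: (p.protein_a, p.protein_b))


def shared_core(pairs_by_genome_pair: Mapping[tuple[str, str],
                                              Sequence[OrthologPair]],
                protein_to_genome: Mapping[str, str],
                genomes: Sequence[str]) -> list[set[str]]:
    """Single-linkage ortholog groups present in every genome.

    Pairwise RSD results are merged into connected components; a component
    is core iff it contains at least one protein from each genome."""
    g = nx.Graph()
    for pairs in pairs_by_genome_pair.values():
        for p in pairs:
            g.add_edge(p.protein_a, p.protein_b)
    core = []
    want = set(genomes)
    for comp in nx.connected_components(g):
        covered = {protein_to_genome[p] for p in comp}
        if want <= covered:
            core.append(set(comp))
    return sorted(core, key=lambda c: sorted(c)[0])


# ---------------------------------------------------------------------------
# category profiles and Welch tests

def category_profiles(genome_proteins: Mapping[str, Sequence[str]],
                      ortholog_category: Mapping[str, str],
                      categories: Sequence[str] = FUNCTIONAL_CATEGORIES,
                      ) -> list[CategoryProfile]:
    """Relative per-category abundance of annotated proteins per genome.

    Proteins absent from the category map are ignored; a genome with no
    annotated protein gets a uniform profile."""
    profiles = []
    for gid, proteins in genome_proteins.items():
        counts = {c: 0 for c in categories}
        for p in proteins:
            c = ortholog_category.get(p)
            if c in counts:
                counts[c] += 1
        total = sum(counts.values())
        if total == 0:
            ab = {c: 1.0 / len(categories) for c in categories}
        else:
            ab = {c: v / total for c, v in counts.items()}
        profiles.append(CategoryProfile(gid, ab))
    return profiles


def welch_category_test(profiles: Sequence[CategoryProfile],
                        groups: Mapping[str, str], alpha: float = 0.05,
                        ) -> pd.DataFrame:
    """Per-category Welch's unequal-variance t-test between two groups.

    Two-sided p from the t distribution with Welch-Satterthwaite degrees
    of freedom; significant iff p < alpha (raw p, matching the original
    uncorrected screen; a Benjamini-Hochberg column is reported alongside).
    Categories with zero variance in both groups and equal means are
    flagged degenerate and non-significant.
    """
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise InputError(f"need exactly 2 groups, got {names}")
    a = [p for p in profiles if groups[p.genome_id] == names[0]]
    b = [p for p in profiles if groups[p.genome_id] == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientInputError("each group needs >= 2 profiles")
    categories = list(profiles[0].abundances)
    rows = []
    for cat in categories:
        xa = np.array([p.abundances[cat] for p in a])
        xb = np.array([p.abundances[cat] for p in b])
        degenerate = xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0
        if degenerate and xa.mean() == xb.mean():
            rows.append({"category": cat, "t": np.nan, "df": np.nan,
                         "p": 1.0, "significant": False, "degenerate": True})
            continue
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"category": cat, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha),
                     "degenerate": False})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# proteome tree

def proteome_tree(genomes: Sequence[str],
                  pairs_by_genome_pair: Mapping[tuple[str, str],
                                                Sequence[OrthologPair]],
                  proteome_sizes: Mapping[str, int]) -> str:
    """Neighbor-joining tree in newick from shared-ortholog distances.

    d(A, B) = 1 - shared ortholog pairs / min(|A|, |B|); negative NJ
    branch lengths are clamped to 0.
    """
    if len(genomes) < 3:
        raise InputError("need >= 3 genomes for a tree")
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb = genomes[i], genomes[j]
            pairs = pairs_by_genome_pair.get((ga, gb),
                                             pairs_by_genome_pair.get((gb, ga), []))
            denom = min(proteome_sizes[ga], proteome_sizes[gb])
            shared = len(pairs)
            dist = 1.0 - shared / denom if denom else 1.0
            d[i, j] = d[j, i] = max(0.0, dist)
    tree = nj(DistanceMatrix(d, ids=list(genomes)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
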