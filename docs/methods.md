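# Methods

## Problem setting

Hot-spring metagenome assemblies mix contigs of bacterial/archaeal host
origin with contigs of viral origin. The analyses this package implements
are the desk half of that workflow: composition-based binning of long
contigs into draft host genomes, detection and characterization of CRISPR
repeat-spacer arrays (the genomic record of past phage infection),
taxonomic labelling of contigs from ranked homology hits, best-hit screening
against a virus reference set, and comparative genomics of reconstructed
phage genomes. Everything is exercised against a synthetic community
generator with a machine-readable ground-truth manifest, because the
original field data cannot be re-processed at desk scale.

## Synthetic community model (`synth`)

The generator states a deliberately simple world so that every oracle stays
trivial:

* **Bases are i.i.d.** at the target GC (P(G)=P(C)=gc/2). This is enough to
  give genomes generated at different GC targets distinct TNF centroids,
  which is all binning and network construction require. There is no
  higher-order Markov structure, codon bias, or repeat landscape.
* **CRISPR arrays**: one consensus repeat (default 35 nt, matching the
  ~35 nt direct repeats observed in hot-spring cassettes) copied
  `array_copies` times, each copy independently point-substituted at
  `repeat_mutation_rate` (default 0.01/base), separated by independent
  uniform-random spacers (default 34 nt). Real spacers are phage-derived
  sequence, but detection depends only on repeat periodicity, so uniform
  spacers are adequate. The array overwrites a seeded-random locus, keeping
  genome length fixed and coordinates exact.
* **Phage genomes** default to 24–200 kb, the observed size range of
  reconstructed bacteriophages (the pipeline's bundled config narrows this
  to 24–48 kb purely for runtime).
* **Fragmentation**: contig lengths are round(N(mean, sd)) floored at 1 and
  truncated at the genome end, tiling left to right; concatenating the
  fragments reproduces the genome exactly. Coverage is a proper truncated
  normal (left-truncated at 0, `scipy.stats.truncnorm`), except sd=0 which
  returns the mean exactly. No field coverage distribution is published for
  these communities; the truncated normal is a neutral choice.
* **Hit tables**: per query, bit scores start at U(150, 400) and decrease by
  U(0.5, 5) per rank (strictly decreasing), E-values are a fixed monotone
  transform of the bit score (non-decreasing down the ranking), identities
  are U(30, 100) and query coverages U(50, 100). Each hit carries the
  query's true lineage except with probability `hit_noise_rate`, when the
  lineage is resampled from a decoy pool of unrelated phyla. This emulates
  the error structure that the voting rule is meant to absorb, not any
  particular aligner's score model.
* **Seeding**: one master seed; each stage derives
  `default_rng([seed, crc32(label)])` from a stable label, so adding a stage
  never perturbs the draws of earlier stages, and identical configs produce
  byte-identical FASTA/TSV/JSON outputs.

What a green recovery test does **not** establish: performance on real
assemblies with chimeric contigs, strain mixtures, compositionally atypical
regions (mobile elements), degenerate tandem-repeat families, or coverage
that correlates with composition.

## CRISPR detection (`crispr`)

Two detectors generate candidates independently and share one refinement
backend:

1. **Seed-and-extend**: exact 8-mers recurring at offsets in
   [repeat_min+spacer_min, repeat_max+spacer_max] (default [41, 108]) are
   paired and merged into candidate regions. Within a region, the k-mer with
   the most occurrences anchors the copies at one fixed offset in the
   repeat; anchors closer than one period are de-duplicated (a spacer can
   coincidentally contain the seed).
2. **Periodic self-similarity**: the per-position match indicator between
   the sequence and its translate at every lag in the period range is
   smoothed with a repeat_min-wide window; windows scoring ≥ 0.75 (random
   expectation 0.25) seed candidates at the dominant lag.

Refinement: repeat boundaries are set by per-column agreement across the
anchored copies (threshold 0.7 of copies for ≥5 copies; at most one
disagreeing copy for 3–4 copies; exact match for 2), then a consensus probe
is stepped along the array — each step scans the allowed spacer window and
accepts the minimum-Hamming placement within 30% divergence — which recovers
copies whose seed k-mer was destroyed by mutation. Boundaries are re-refined
with the full copy set, partial copies hanging over a contig edge are
dropped, terminal copies with out-of-range spacers are trimmed, and a
complexity filter rejects near-homopolymer consensi and "arrays" whose
spacers are themselves repeat copies (tandem repeats, degenerate
periodicity).

Defaults bracket the observed ~35/~34 geometry: repeat length ∈ [21, 48],
spacer length ∈ [20, 60], min_copies = 3, seed k = 8. On the synthetic
world this yields, at 1% repeat mutation, exact copy counts and exact
35/34 geometry for arrays of ≥ 10 copies; with 3–4 copies the column
profile is noisy and boundaries can overshoot the repeat by 1–3 nt (the
copy count is still exact). Empirical false-positive rate on i.i.d. 10 kb
contigs: 0 consensus arrays in 100 contigs (the suite requires < 0.05 per
contig).

**Consensus retention** operationalizes "arrays found by both predictors":
an array is kept iff an array from the other detector on the same contig
overlaps it reciprocally by ≥ 0.5 of each interval; the retained record
takes the union interval and the seed detector's repeat structure. The 0.5
reciprocal overlap is our choice — the original two-tool practice never
quantified "consistent".

**Repeat types and motifs**: arrays are single-linkage clustered on global
alignment identity of their consensus repeats (best of forward and reverse
complement; matches/alignment columns), threshold 0.9 — exact-match typing
would shatter types under sequencing noise. The representative is the
medoid. Motif assignment takes the best identity over a user-supplied
(motif id, consensus) TSV, assigned iff ≥ 0.8, ties to the lowest motif id,
otherwise "novel". Consensus columns break ties in fixed base order
A<C<G<T; copies are aligned by position only (gapless), so an indel inside
a repeat copy shifts that copy's columns — a documented limitation.

## Composition features and binning (`seqprofile`, `binning`)

TNF vectors count all overlapping 4-mers on the given strand (no
reverse-complement canonicalization; users who want strand symmetry can
pre-canonicalize), skipping windows with ambiguous bases, normalized to sum
to 1. Correlations are Pearson.

The binning distance is weighted Euclidean over (TNF, log10(coverage+1),
GC) with default weights (1.0, 0.25, 1.0). Coverage is deliberately **not**
standardized: standardizing to unit variance inflates coverage to the
dominant axis even when all genomes have the same depth (pure noise), which
empirically destroys recovery of GC-separated genomes at any coverage
weight comparable to the compositional signal. On the log scale a 2-fold
depth difference is ~0.3 — already commensurate with GC differences — and
the 0.25 weight was fixed by a robustness sweep (60 synthetic communities,
same-depth and depth-separated; 0 failures at 0.25 vs 4/60 at 0.5) before
the test suite was frozen.

Clustering is average linkage, cut at an explicit k; `k="auto"` takes the
largest silhouette over k ∈ [2, 10]. Contigs below 10 kb are excluded and
reported separately. Completeness is strictly (distinct essential markers
found)/107, duplicates counted once and tallied separately; the default
marker id lists are placeholders (31 + 107 ids) standing in for the
published sets, which are data, not method.

## Hit classification (`hitclass`)

Hits are rows of a 12-column blast-tabular file; query coverage is
100·(qend−qstart+1)/query length. Ranking is bit score descending, E-value
ascending, subject id — a total order, so best-hit selection is
order-invariant. The voting rule: phylum assigned iff the top min(10, n)
hits carry one identical non-missing phylum **and** n ≥ 10 (queries with
fewer hits are unassigned; the cutoff is configurable); class/family/genus
assigned iff one taxon strictly exceeds 50% of the top min(30, n); the
deepest assignable rank is reported. "Majority" is interpreted as strict
(>50%), and the order rank is deliberately not votable — the quoted rule
lists only class, family, genus. Missing labels never vote. The BBH screen
filters at coverage ≥ 80 (inclusive) and takes the ranking's first
survivor; summary identity means are unweighted and rounded to integer.

## Comparative genomics (`compare`)

* **Dot plots**: all exact shared words (default 10 nt) in both
  orientations, as 0-based start pairs; reverse matches report the forward
  coordinate of the word in the second sequence.
* **Identity**: global alignment with match +1 / mismatch −1 / gap open −5
  / extend −1; identity = matches/alignment columns. Group similarity is
  the mean ± sample SD of pairwise identity over within-group pairs. This
  **re-defines** the published whole-genome similarity statistic (whose
  aligner score formula is not public); the numbers are not expected to
  reproduce the published 65%/49% values. O(nm) per pair — off by default
  in the pipeline.
* **TNF network**: edges where TNF Pearson correlation ≥ threshold (default
  0.5; set ≤ −1 for the complete graph, which is what a drawn network with
  all correlations corresponds to); node weight = sum of incident edge
  weights, recomputed after filtering.
* **RSD orthologs**: local Smith-Waterman with BLOSUM62 (open −11, extend
  −1), E-value from a fixed Karlin-Altschul parameterization (λ = 0.267,
  K = 0.041, the standard gapped-BLOSUM62 values, with m = query length and
  n = total partner-proteome length) — RSD needs a consistent threshold,
  not database-calibrated significance. Distance = 1 − fractional identity
  of the local alignment, a simplification of the maximum-likelihood
  distance in the original algorithm. A pair is emitted iff each protein is
  the other's smallest-distance hit, both direction E-values ≤ 1e-15, and
  distance ≤ 0.5. Ties break by E-value then id, keeping the output
  symmetric in its arguments.
* **Shared core**: single-linkage components of the pairwise RSD graph;
  core iff the component touches every genome.
* **Welch tests**: per functional category, `scipy.stats.ttest_ind`
  (equal_var=False), two-sided, df from Welch-Satterthwaite; significant
  iff raw p < 0.05 (matching the original uncorrected screen) with a
  Benjamini-Hochberg column reported alongside. Zero variance in both
  groups with equal means is flagged degenerate and non-significant.
* **Proteome tree**: d(A,B) = 1 − shared RSD pairs / min(|A|, |B|),
  neighbor-joining (scikit-bio), negative branch lengths clamped to 0. The
  published proteome phylogeny's method is not described; NJ on
  shared-ortholog distance is this package's choice.

## Pipeline (`pipeline`)

One YAML config with per-stage blocks and toggles; defaults are the
generator's stated world. Every effective value and the master seed are
written to `run.log`, so the scattered cutoffs (>10 kb, 80% coverage,
1e-15/0.5, word 10, p < 0.05) are auditable in one place. Disabling a
downstream stage never changes upstream artifacts, and a fixed seed gives
byte-identical outputs. The summary table reports, per sample, contig
counts, consensus-retained CRISPR cassette counts, and phage genome counts.
When fragmentation splits a planted array across a contig boundary, the
manifest records each remnant that keeps ≥ 3 complete copies (still a
detectable array) and drops smaller remnants.

## Known limitations

* Gapless repeat-copy alignment: indels inside repeat copies degrade the
  consensus rather than being absorbed.
* Boundary overshoot of 1–3 nt for 3–4-copy arrays (column consensus is
  noisy at that depth).
* Single-strand TNF counting makes profiles strand-dependent.
* The identity statistic, RSD distance, and proteome-tree distance are
  explicit re-definitions/simplifications of published tool outputs and are
  labelled as such above; only their qualitative behaviour (orderings,
  recovery of planted structure) is tested.
* The generator's i.i.d. base model cannot produce compositionally
  ambiguous contigs, so binning results on it are an upper bound on
  real-data performance.
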