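# Methods

`brackmag` implements the computational core of a time-series
metagenome-assembled-genome (MAG) workflow: merging ensemble assemblies,
quality-gating genome bins with single-copy genes, dereplicating bins into
genome clusters, quantifying seasonal abundance, profiling fragment
recruitment across environments, computing genome-streamlining features, and
aggregating contig taxonomy to bin level. External tools that normally
surround these steps (de Bruijn assembly, read mapping, gene prediction,
profile searches) are out of scope; their outputs enter as tables, or are
emulated by the synthetic-community generator.

## The shared local aligner

Every sequence-comparison step (spike-in recovery evaluation, ANI,
recruitment, filter-fraction matching) uses one aligner with one contract:
maximal non-overlapping **ungapped** local alignments with match +1 /
mismatch −2 scoring, reported when they meet a minimum length and a minimum
identity, on both strands.

*Why ungapped.* The synthetic world is substitution-only by design (below),
and the recruitment e-values quoted for this workflow (λ ≈ 1.33, K ≈ 0.621)
are the ungapped Karlin–Altschul parameters for +1/−2. Ungapped alignments
make identity, length and coverage arithmetic exact and make an independent
full-matrix dynamic-programming oracle cheap enough to run in the test suite.

*Algorithm.* Exact seed k-mers shared between query and target define
candidate diagonals; along each diagonal the maximal-scoring segments are
found with a Kadane-style recurrence (`H[i] = max(0, H[i-1] + s[i])`),
trimmed to their score peak. Segments are kept greedily by score subject to
non-overlap in both query and target coordinates. Non-ACGT positions are
hard breaks (a large negative score), so alignments never span the `N`
separators used to concatenate multi-contig bins.

*Seed choice and exactness.* If an alignment of length ≥ L has identity
≥ p, pigeonhole over its mismatch-free runs guarantees an exact k-mer match
for k ≤ min over ℓ≥L of ⌈(ℓ−m)/(m+1)⌉, m = ⌊(1−p)ℓ⌋ (k = 9 for L=100,
p=0.9). For inputs up to ~2 Mb of pairwise area the guaranteed k is used and
the best reported alignment provably equals the DP optimum; for larger
inputs k grows to `log4(area/16)` to bound spurious seed hits, and on very
noisy large inputs diagonals additionally require two seeds. This trades a
documented sensitivity floor (alignments near the identity threshold in very
large inputs) for near-linear behaviour; all alignments in this package's
use-cases (≥ 85 % identity) carry abundant clean seeds.

## Ensemble-assembly merging

Contigs from multiple assemblies of one sample are cut into 2000-bp windows
every 100 bp; contigs under 1100 bp pass uncut in two copies, and the first
and last window of each contig are duplicated, so every base is covered at
least twice. The windows are re-assembled by an overlap-layout-consensus
step with the two stated parameters only: minimum overlap 40 bp, minimum
overlap identity 90 %.

The OLC step is deterministic by construction: exact duplicates and exact
substrings (either strand) are removed; the longest qualifying suffix–prefix
(Hamming) overlap per oriented fragment pair forms the edge set; chains are
built greedily longest-overlap-first with ties broken by fragment id; a
fragment's orientation is fixed by the first edge that places it; consensus
is per-column majority with ties broken A<C<G<T. For small fragment sets
overlaps are enumerated exhaustively; for large sets candidates are anchored
on each fragment's prefix k-mer (k = min(31, min_overlap)), which is exact
for noise-free fragments. The edge-duplication reading of the cut-up rule
(only the first and last window count as "edges") is one of two defensible
interpretations; the alternative (every window touching the terminal `step`
bases) would only add redundancy.

The merge contract is validated the way the original was: tiling a reference
genome into 1000-bp windows every 100 bp, spiking them into an unrelated
contig background, re-assembling and aligning back. On a noise-free 100-kb
synthetic reference with 20 unrelated background genomes the pipeline
recovers 100 % of the reference at 100 % identity, against real-data
benchmarks of 99.66 % recovery and 99.97 % identity which serve as lower
bounds.

## Bin quality control

Marker hits (from a provided hit table, or derived from embedded-marker
ground truth in synthetic mode) count only when they cover **more than
half** of the marker reference length. The gate accepts a bin iff at least
30 of the 36 general single-copy genes are present with at most two in
multiple copies. Taxon-specific panels are selected from a genome × marker
copy-count table: presence in ≥ 97 % of the taxon's genomes and mean count
< 1.03 (mean over *all* genomes of the taxon, absent = 0; with the 97 %
presence floor the alternative mean-over-carriers differs negligibly).

Completeness is 100 × (distinct panel markers present) / (panel size). The
error estimate is the excess-copy fraction of observed marker copies,
100 × Σ max(cᵢ−1, 0) / Σ cᵢ — a base-rate proxy for misassembled or wrongly
binned sequence; the upstream workflow never defined this computation
precisely, so it is flagged as an approximation. Contigs of ≥ 20 kb are
split into 10-kb pieces before binning (remainder merged into the last
piece) and adjacent same-bin pieces are rejoined afterwards; the round trip
is the identity.

## Dereplication

The distance between two approved bins is 1 − ANI, where ANI is the
alignment-length-weighted mean identity over all reported alignments
(collection thresholds: length ≥ 100, identity ≥ 0.8), defined only when
the alignments cover at least 50 % of the smaller bin's bases; undefined
pairs are pinned at distance 1.0 so they can never merge. Agglomerative
clustering cut at 1 − ani_cutoff yields the genome clusters. The default
ani_cutoff of 0.96 sits inside the reported identity gap (intra-cluster
> 99 %, inter-cluster < 70 %); a stability check verifies that single,
average and complete linkage agree, which guards against gap violations.
Cluster ids are assigned by decreasing size (ties by smallest member id);
the representative is the member with the largest total assembly length
(ties by id). The triangle inequality is *not* assumed for this distance.

## Abundance

Reads per bin per sample = Σ over the bin's contigs of (mean per-nucleotide
coverage × contig length) / read length (default read length 100 bp, i.e.
2 × 100 bp libraries; the conversion is exact when the coverage table stores
mean per-nucleotide depth). The abundance statistic is
(reads_in_bin / total_reads) / bin_size — *fraction of reads per nucleotide
in bin* — which is invariant to sequencing depth and bin size by
construction, and satisfies Σ_bins value × size ≤ 1 per sample. Seasonal
profiles are row-wise population Z-scores (constant rows → all zeros),
computed on raw fractions by default with a log option (whether the original
heatmap standardized before or after log transform is unstated).
Co-occurrence structure is average-linkage clustering of 1 − Spearman
correlation between profiles; zero-variance rows are warned about and held
at the maximal distance 2. Spearman p-values use an exact permutation null
for n ≤ 8 and the t-approximation above (8! permutations are enumerable at
desk scale; the exact-permutation cut-off is an implementation choice).

## Fragment recruitment

Samples are sub-sampled to 10,000 reads of 350 bp (fewer reads pass through
whole, flagged). The database contains only the nucleotide sequences of
predicted ORFs, strand-resolved; concatenation separators are longer than
any read so alignments cannot span records. The best alignment per read is
kept when the alignment length exceeds 200 bp (strict) and the ungapped
Karlin–Altschul e-value against the total database length is below 1e-5
(strict). Best-hit-only counting avoids double-counting paralogs; a flag
reports all passing hits instead. Identity profiles count accepted hits at
≥ each cutoff in {70…100} %, hence are non-increasing; counts are
normalized to reads per kb of genome per 10,000 queried reads and averaged
over cluster members. Filter-fraction matching reuses the same aligner at
95 % identity / 100 bp.

Because maximal-scoring segments trim mismatching ends, the accepted-hit
identity of reads simulated at 15 % divergence is biased slightly above
85 % (≈ +1 %); tests allow for this.

## Taxonomy

Contig classifications (lineage + mass probability, several allowed per
contig) are weighted by contig length; a node's support is its weighted mass
over the total classified mass (a flag switches the denominator to all
contig bases). The bin lineage is found by walking from the root while
exactly one child reaches the 30 % support threshold (inclusive at the
threshold), i.e. the last common ancestor of all maximal qualifying nodes.
This reproduces the hand-computable cases exactly. Note that "raising the
threshold never yields a shallower assignment" is *not* a theorem under
these semantics: a threshold raised past the support of the only qualifying
child truncates the walk. The examples where raising the threshold resolves
a tie (and deepens the call) behave as expected.

## Streamlining features

GC is computed over unambiguous bases; the non-coding percentage only over
contigs longer than 5000 nt (undefined, and flagged, when no contig
qualifies), with overlapping genes merged first. COG category proportions
distribute multi-category genes fractionally so categories sum to 100 %.
The ordination table carries the log-transformed percentages of non-coding
DNA, GC and categories K, T, V, Q, I; a pseudocount of 0.01 percentage
points admits zero percentages (zero-handling was unstated upstream).
Welch's t-test with Benjamini–Hochberg correction serves the group
comparisons; the ordination itself (PCA/NMDS, Bray–Curtis, four dimensions)
is delegated to standard numeric routines.

## Synthetic community

The generator states one world: genomes of 1–3 Mb at GC 0.30–0.60, a
36-marker general panel embedded as unique random 500-bp tokens recoverable
by exact search, fragmentation into disjoint contigs covering ≥ 90 % of each
genome, 37 samples with per-genome Gaussian seasonal abundance bumps and
additive truncated-Gaussian coverage noise, and substitution-only reads at a
controlled per-base divergence (an indel rate exists but defaults to zero).
Two genomes are also emitted as near-identical replicates (0.5 %
divergence), giving dereplication true clusters to find. All generators are
bit-reproducible for a fixed seed, and a fixture regenerates identically
from its emitted config + seed.

What a green test does **not** establish: the generator has no quality
scores, chimeras, strain microdiversity, compositional bias or
phylogenetically realistic evolution, so passing tests certify the
*counting and thresholding semantics* of each stage, not robustness to real
sequencing artefacts. Runtime-sensitive tests use the same stated world at
smaller genome sizes; thresholds are never adjusted to the scaled inputs.

## Numerical conventions

Coordinates are 0-based half-open internally; GFF (1-based inclusive) is
converted at the I/O boundary. Identity comparisons use a 1e-12 tolerance on
their stated side (≥ for presence/identity thresholds, strict < / > where
the rules say strictly). Consensus ties break A<C<G<T; cluster and chain
construction ties break by id; all randomness flows from explicit seeds.

## Known limitations

- The aligner is ungapped; indel-rich data would fragment alignments and
  depress ANI/recruitment identities.
- Heuristic overlap anchoring (prefix k-mer) can miss overlaps whose first
  k bases contain a mismatch in *large noisy* fragment sets; exhaustive
  enumeration is used automatically for small sets.
- The greedy OLC layout is reproducible but not optimal; repeats longer
  than the window size would be collapsed.
- `est_error` is a marker-copy proxy, not a base-level misassembly rate.
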