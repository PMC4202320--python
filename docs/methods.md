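# Methods

This note documents the models, estimators, conventions and design
choices behind the package, and what the synthetic-data tests do and do
not establish about real data.

## Genome model and coordinates

Internal coordinates are 0-based half-open; GenBank and gene-table TSV
dialects are 1-based inclusive at the file boundary and converted exactly
once on read/write. A circular genome is one linear sequence with
wrap-aware features: a feature crossing the origin is an ordered list of
non-wrapping intervals, and modulo-length arithmetic happens only inside
operations that declare themselves wrap-aware (region partitioning, the
largest-noncoding-run search, CDS extraction). Multi-interval
reverse-strand features are stored in file order; extraction concatenates
intervals and reverse-complements the whole, which reproduces GenBank
`complement(join(...))` semantics (verified against Biopython's extractor
in the tests). The NCBI translation table defaults to 1 and is
configurable per record and per call — for the discobid mtDNAs the
applicable code is not firmly established, so it is deliberately exposed
as configuration rather than guessed.

CDS features whose length is not a multiple of three, or which contain
internal stop codons under the declared code, are flagged and kept:
genomes with RNA editing and extended reading frames legitimately contain
such genes, and silently dropping them would bias every downstream
statistic.

## Composition descriptors

AT and GC skews are computed on the deposited strand over the whole
molecule; whether published summary skews were computed genome-wide or on
coding regions only is generally unstated, so genome-wide is the default
and the alternative is a caller choice. N bases are excluded from every
denominator. For the size portions, positions are classified with
precedence protein-coding (CDS ∪ ORF) > RNA (tRNA ∪ rRNA) > noncoding, so
the three portions always sum to one even with overlapping annotations;
"coding" for the coding-fraction figure includes unknown ORFs, matching
how compactness is usually quoted for these genomes. The largest
noncoding region is the longest maximal unannotated run, joined across
the origin on circular genomes.

GC3s (the S of the expected-Nc curve) is GC at third positions of codons
belonging to synonymously variable families only: codons of single-codon
amino acids and stop codons are excluded under the declared code.

Protein divergence is the pooled p-distance: mismatches and comparable
(both-ungapped) columns are summed over all gene alignments before
dividing, which is what an "overall" divergence across a gene set means;
it is not the mean of per-gene distances.

## Codon-usage bias

**Nc (observed).** For each synonymous family with m codons and n counted
codons, the homozygosity estimate is F̂ = (n·Σp̂ᵢ² − 1)/(n − 1). Families
with n < 2 or F̂ ≤ 0 are excluded from their degeneracy-class mean. Nc is
the number of single-codon families plus Σₖ (number of k-fold families)/F̄ₖ,
with the class multiplicities (9 two-fold, 1 three-fold, 5 four-fold,
3 six-fold under the standard code) derived from the genetic code at run
time. An empty three-fold class is imputed as (F̄₂+F̄₄)/2 (the convention
of the classical implementation); any other empty class leaves Nc
undefined for that gene. Results are capped at the code maximum (61).

**Expected Nc.** The null curve Nc = 2 + S + 29/[S² + (1−S)²] is evaluated
exactly; a gene shaped only by G+C mutation pressure lies on it.

**Nc′.** The family homozygosity is replaced by
F̂′ = (χ² + n − m)/(m(n − 1)), where χ² measures the deviation of observed
family counts from counts expected under per-codon-position nucleotide
frequencies (the product over the three positions, renormalised within the
family; positions invariant within a family cancel in the
renormalisation). The background defaults to the positional composition
of the counted codons themselves — i.e. each gene is judged against its
own composition — with a genome-wide background available as an argument.
With a uniform background, F̂′ reduces algebraically to F̂, so Nc′ equals
Nc exactly in that limit (tested). "Overall" Nc′ is computed on the
pooled per-gene count tables (terminal stops excluded per gene), not as a
mean of per-gene values; both conventions are available because published
"overall" figures rarely state which was used.

**CDC.** Expected codon probabilities are the product over codon positions
of per-position nucleotide probabilities reconstructed from positional GC
and purine content (P(G) = g·r, P(A) = (1−g)·r, etc.), renormalised over
sense codons; CDC = 1 − cosine similarity between observed and expected
sense-codon frequency vectors. A full per-position 4-frequency
parameterisation is available behind a flag, since the cited toolkit's
exact choice is not published. Significance comes from parametric
bootstrap: n codons are resampled from the expected distribution `reps`
times (default 10,000, seeded) and p is the fraction of replicates with
CDC at least the observed value. Under the null this p-value is
approximately Uniform(0,1); the test suite checks this with 500 simulated
tables at n = 300 codons and 200 replicates each (problem sizes chosen to
keep the default suite fast) via a Kolmogorov–Smirnov test at α = 0.01.

**Rank-sum comparisons.** Two-sided Wilcoxon rank-sum via
`scipy.stats.mannwhitneyu`: the exact null distribution for combined
n ≤ 20 without ties, the normal approximation with continuity correction
otherwise; two all-identical samples return p = 1.

## Gene content and Dollo mapping

Gene labels are lower-cased, split-gene suffixes collapsed
(rps3_a/rps3_b → rps3) and passed once through an editable synonym table
(yejR → ccmF and kin); unmappable labels are kept verbatim with a warning,
never dropped, because silent label loss is the dominant failure mode in
cross-publication gene-content comparisons.

Dollo parsimony assumes one gain and unlimited independent losses. For
each gene every node is marked present iff at least one descendant leaf
carries the gene; with an explicit ancestral set the root is forced
present, otherwise the gain sits at the LCA of the possessing leaves and
no losses are counted above it. Losses are edges from a present parent to
an absent child; polytomies contribute one loss per absent child. This
construction yields the minimal number of loss edges for a single-gain
character (checked exhaustively against a brute-force oracle on all leaf
patterns of trees up to six leaves, polytomies included) and never loses
a gene twice on one root-to-leaf path.

The bundled curated inputs — presence matrix for the ten discobid
genomes, consensus rooted tree, 67-gene jakobid ancestral complement and
synonym table — use standard mitochondrial gene nomenclature. Published
sources print the totals (67 ancestral; 26/42/42/41 retained; branch
losses 20/6/5/16) and name the sixteen genes missing from *A. kona*, but
not the complete per-taxon rosters; unnamed membership was therefore
filled from standard jakobid mtDNA complements under the constraint that
every printed count and every named gene is honoured exactly. Swapping
one unnamed gene for another would relabel loss sets but cannot change
the branch counts.

## Synteny

Synteny is computed on gene-name orders, not nucleotide alignments —
published block figures for these genomes are drawn at gene granularity,
and name-level blocks are reproducible without an aligner. A shared block
is a maximal run of genes consecutive (circularly) in both orders, in
identical order with identical relative orientations, or exactly reversed
with flipped orientations (inverted). Circularity is handled by modular
extension with wrapped-hit deduplication; `min_block` defaults to 2.
Equivalence with an exhaustive common-circular-substring oracle is tested
on random signed permutations up to 12 genes. The cluster scan
(`cluster_presence`) classifies an order as intact (all cluster genes
consecutive in cluster order, in either reading direction, with at most k
interleaved foreign genes, default k = 0 — published block figures use the
strict convention), partial (a contiguous sub-run of ≥ 2, or the full cluster with
more than k insertions, reported by name), or absent.

## C-to-U editing prediction

Candidates are single C→T substitutions within a codon such that the
edited translation equals, and the unedited translation differs from, the
reference residue at the aligned column. Support is the fraction of
references with a non-gap residue at the column that predict the site;
sites at or above `strong_threshold` (default 0.8 — published analyses
say "strong candidate" without a number, so this is configuration, and
raw support is always reported) are flagged strong. Synonymous edits are
never emitted (editing restores conserved residues; a synonymous change
restores nothing), and multi-edit codons are out of scope by default.
Reference panels are accepted pre-aligned or built by global pairwise
alignment of each reference to the query (BLOSUM62, gap open −10, extend
−0.5, via Biopython's PairwiseAligner) projected onto query coordinates —
a deliberate simplification of profile-based prediction servers.
Confirmation compares genomic and cDNA-derived sequence at the site:
C/T confirms, C/C rejects, and a non-C genomic base flags the site as
inconsistent instead of failing silently.

tRNA acceptor-stem checks take the secondary structure as input
(dot-bracket); the first three '(' positions, paired by nesting, are the
acceptor stem's first three pairs, and a pair is a mismatch if not
Watson–Crick (G:U counts as valid by default, configurable). The PG-box
scan matches the 15-residue degenerate motif PGxSWIEVxGxxHxF with
overlapping matches allowed.

## Synthetic-data generator

The generator's defaults are the study conditions of the compact AT-rich
regime: overall AT 0.83, GC3s 0.10, bias strength 0 (no selection on
synonymous usage), 10 unknown ORFs, 11 tRNAs, geometric spacers with mean
60 nt, gene lengths uniform on [300, 1500] nt (ORFs [210, 1200]),
loss-only gene content. Within each synonymous family, codons are
weighted by a GC3s-controlled nucleotide distribution over the family's
varying positions; because some families (e.g. three-fold Ile) cannot
realise an arbitrary third-position GC, the distribution parameter is
solved numerically so that the *expected measured* GC3s equals the target
under the realised amino-acid usage. Amino-acid usage itself is an
exponentially tilted distribution solved so expected coding AT hits the
AT target; unreachable targets clamp with a warning. `bias_strength`
exponentially favours one codon per family: 0 gives the composition-only
null, large values drive Nc to its one-codon-per-family minimum of 20.

Planted C-to-U edits force a Ser TCA codon at the stated codon index in
the genome while the emitted transcript reads Leu TTA, so prediction
(against references built from the edited protein) and confirmation
(genomic C / cDNA T) recover the site exactly. Planted tRNA mismatches
replace the 3′ partner of the stated acceptor pair with a base that is
neither Watson–Crick nor wobble. Clade simulation removes each branch's
loss set from the gene roster along root-to-leaf paths (explicit sets or
a per-branch rate), erroring if a gene would be lost twice on one path,
and re-simulates sequences independently per leaf.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: nucleotide-level homology and divergence
between taxa (no substitution model), rearrangement histories (synteny
tests use hand-built permutations), realistic tRNA cloverleaves beyond
the acceptor stem, strand asymmetry (simulated skews sit near zero,
unlike the strongly positive GC skew of real heterolobosean mtDNA), and
annotation error. In particular, CDC's expected-usage model differs from
the generator's family-conditional sampling, so simulated genes can show
small but "significant" CDC values; the CDC null calibration is therefore
tested against its own resampling model, not against the genome
generator.

All randomness flows through `numpy.random.default_rng(seed)`; identical
spec and seed give byte-identical genomes, transcripts and structures.

## Problem sizes and numerical choices

Default test and acceptance runs use 10⁴-codon sequences for composition
recovery (binomial error ≈ 0.003, tolerance ±0.01), 500 × 200-replicate
bootstrap calibration, exhaustive Dollo checks to six leaves and synteny
oracles to 12 genes — sizes chosen so the whole suite completes in well
under a minute while keeping Monte-Carlo margins at ≥ 3σ. Bootstrap
replicates default to 10,000 in the public API. Seeds are explicit
everywhere; derived seeds stay below 2³¹. Ties in rank-sum comparisons
switch the test to its normal approximation; all-constant input returns
p = 1 rather than NaN.

## Known limitations

* The curated matrix resolves only protein-coding content; tRNA/rRNA
  content comparisons require the deposited records.
* Block detection treats duplicate gene names as distinct occurrences but
  can suppress a maximal block in pathological duplicate-rich orders
  where every candidate start is preceded by another match; real
  mitochondrial gene orders (and the tested permutation space) do not hit
  this corner.
* `enc_observed` is undefined (None) for short genes missing a whole
  degeneracy class other than the imputable three-fold class — such genes
  are reported as missing rather than extrapolated.
* The editing predictor enumerates single edits per codon; double-edited
  codons would need the pair mode, which is deliberately off by default.
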