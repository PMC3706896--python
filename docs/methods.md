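# Methods

`concordkit` measures agreement between variant call sets produced by
different alignment/variant-calling pipelines (or sequencing platforms) for
the same sample, and implements the family-based filters that separate
genuine de novo variants from parental false negatives. This note records
the model behind each stage, the parameters that matter, the synthetic-data
generator used to exercise everything at desk scale, and the numerical and
design choices that were genuinely open.

## Matching model

**What counts as "the same variant".** Two SNVs match when chromosome,
position, reference base, alternate base, and (by default) zygosity all
agree. Two indels match when, *after left-normalization*, they lie on the
same chromosome within a coordinate window of each other and have the same
net length change and (by default) the same inserted/deleted sequence.
MNVs and complex substitutions match by exact normalized key.

**Left-normalization.** An indel inside a homopolymer or short tandem
repeat has many equivalent VCF representations. `left_normalize` rewrites a
call to the unique leftmost minimal anchored form: shared trailing bases
are trimmed (borrowing the preceding reference base whenever an allele
would become empty, which is what walks the position left through the
repeat), then shared leading bases are trimmed down to a single anchor.
The operation is idempotent and edit-preserving: applying the original and
the normalized edit to the reference yields the same alternate sequence.
The test suite verifies both properties against a brute-force oracle that
enumerates every equivalent edit position, and against `bcftools norm`.

**Intervalization.** Normalized indel coordinates are widened by a window
of ±10 (a total range of 20 coordinates; configurable, inclusive at the
boundary, clamped to the chromosome). This absorbs residual representation
disagreement that normalization alone cannot remove — e.g. neighbouring
non-identical repeats, or callers that report slightly shifted breakpoints.
Widening the window well beyond 10 changes results only marginally, which
is why 10 is the default rather than a tuned value.

**Clustering.** The pairwise indel match is reflexive and symmetric but not
transitive (A–B and B–C within the window does not imply A–C). Classes are
therefore defined as connected components of the match graph —
single-linkage, the unique parameter-free closure of the pairwise rule.
Greedy one-to-one assignment was rejected because the downstream statistics
are set-level overlaps, not bijections. On a line, components reduce to
chaining positions sorted within each (chromosome, net length, composition)
group, splitting where consecutive gaps exceed the window; a test confirms
equality with exhaustive `networkx` connected components on random
instances. Output is deterministic and invariant under permutation of input
call sets and of calls within sets.

## Concordance statistics

For N call sets, each equivalence class has support k = number of distinct
sources containing it. **Concordance** is defined as
|classes with support = N| / |all classes| — intersection over union. Tier
counts (support exactly k), known/novel stratification against a catalogue
of previously observed sites, Ti/Tv ratios per tier (computed on class
representatives, one vote per class), and per-sample means are derived from
the same clustering. Per-sample concordances are computed independently and
then averaged.

Depth sweeps filter each call set to calls with depth > t *in its own set*
before re-clustering, since each pipeline observes its own read depth.

## Truth-set evaluation

Array-style truth genotypes include homozygous-reference sites, so a full
confusion matrix is defined: a non-reference truth genotype is a true
positive only when a call matches position, alternate allele *and*
genotype; a homozygous-reference site with any call is a false positive.
The specificity denominator is the array's hom-ref sites, not all genomic
positions — the only denominator under which specificity is a meaningful
per-site rate. A call at a truth site with a discordant allele counts both
as FN (missed genotype) and FP (spurious call) by default; this is
configurable. Validation rates (fraction of a query set confirmed by an
orthogonal call set) use class co-membership under the same match
configuration, never raw string equality, and report percentages rounded
half-away-from-zero.

## Pedigree de novo filtering

A candidate de novo variant is a child call whose equivalence class
contains no call from either parent. Parental matching deliberately ignores
zygosity: a heterozygous parent call must suppress a homozygous child
candidate. With per-individual false-negative (dropout) rate d and H
inherited variants in the child, roughly H·d·(terms for the second parent)
inherited variants masquerade as de novo — far more than the 1–2 genuine
coding events expected per generation. The grandparent filter removes any
candidate whose allele appears in an ancestor call set: a grandparental
match implies transmission through a parental false negative. An empty
ancestor list (two-generation family) leaves candidates unchanged.

## Synthetic-data generator

The generator emulates the statistical structure of a multi-pipeline exome
study at desk scale; all sizes below are the package defaults and are the
conditions the test suite runs under.

* **Reference**: 500 kb over 2 chromosomes, random sequence with ~2
  homopolymer runs per kb (lengths 6–14) injected so indel representation
  ambiguity actually occurs.
* **Truth**: 2,000 SNVs and 200 indels per sample (the ~10:1 ratio typical
  of human coding variation), SNVs transition-rich at Ti/Tv 3.0, HET:HOM
  2:1, indel sizes geometric (capped at 20) placed inside runs with
  probability 0.9 and always stored left-normalized. 70% of truth sites are
  flagged "known". Sites keep ≥25 bp spacing so distinct truth variants
  never share a matching window.
* **Pipelines**: five simulated callers with independent per-variant
  false-negative rates of 4.7/5.3/7.7/13.4/5.5% (the sensitivity spread
  typical of the tools being emulated; two of the five call SNVs only) and
  pipeline-private false positives. FP rates are set by the analytic
  calibration helper: with independent FN events and disjoint FP strata the
  expected N-way concordance is ∏(1−fn_i) / (1−∏fn_i + Σfp_i), solved for
  the FP mass that yields a target concordance (default 0.574). Simulated
  concordance matches this closed form to well within ±0.02 at default
  sizes. False-positive SNVs are transversion-rich (Ti/Tv 0.5), which
  produces the rising Ti/Tv trend across support tiers.
* **Representation jitter**: with probability `jitter_prob` an emitted
  indel is re-anchored at a uniformly chosen non-leftmost equivalent
  coordinate in its run (the rightmost-aligned form is the
  maximal-displacement case). A uniform choice, rather than always
  rightmost, is used so that three or more pipelines rarely collide on the
  same wrong representation — with only two dialects, three pipelines would
  agree on raw keys ~52% of the time at jitter 0.8, masking exactly the
  raw-vs-normalized contrast the jitter exists to exercise.
* **Depth** is gamma-Poisson (mean 120×, shape 2) and independent of truth
  status by default, so tightening a depth threshold cannot raise
  concordance; a correlated mode is deliberately absent from defaults.
* **Platform set**: an orthogonal whole-genome-style call set carrying all
  truth (including an 11% private stratum the exome pipelines never emit)
  minus its own 5% dropout, with VQHIGH/VQLOW quality flags (90/10).
* **Pedigree**: three generations (4 grandparents, 2 parents, children),
  8,000 polymorphic sites, Mendelian transmission of one allele per parent,
  2 injected heterozygous de novo SNVs per child, 5% per-individual call
  dropout. Founder genotypes are drawn with per-site population allele
  frequencies ~ Uniform(0.3, 0.9): variants an individual carries are
  size-biased toward common alleles, and a common allele is usually carried
  by several ancestors, so a spurious candidate survives the grandparent
  filter only if *every* carrier dropped out. Under this calibration the
  exact per-site model gives ≈79 expected parental-only candidates and
  ≈0.3 expected spurious survivors per child, reproducing the
  characteristic collapse from hundreds of candidates to approximately the
  injected count.

**What the generator does not model**: read-level errors, capture
efficiency or GC bias (beyond the private platform stratum), linkage
between sites, codon structure behind consequence tags (assigned i.i.d.:
10% NONSYN, 2% NONSENSE, 25% SYN), systematic error modes shared between
pipelines, and multi-nucleotide or structural variation beyond 20 bp
indels. Passing tests therefore demonstrate correctness of the comparison
machinery under the stated error model, not calling performance on real
sequencing data.

## Numerical choices and degenerate inputs

* Percentages are rounded half-away-from-zero (`decimal` arithmetic, no
  binary-float artifacts); `rate_percent` agrees with exact rational
  arithmetic at every printed precision.
* Concordance of an empty union is NaN/`null`, never 0.
* Ti/Tv with zero transversions is reported as NA.
* Genotypes 0/0 and ./. never become calls; hemizygous single-allele
  genotypes are treated as HOM_ALT (documented approximation).
* FILTER handling defaults to PASS/"." only; `keep_filtered` retains all.
* A depth filter drops calls with missing DP while active (conservative).
* Region restriction uses the anchored position for SNVs and the full
  closed reference-allele span for indels; BED input is 0-based half-open,
  converted only at the I/O boundary.
* Class identifiers and report ordering derive from sorted
  (chrom, position, alleles) keys, making reports byte-stable for a fixed
  seed; all generators draw from `numpy` PCG64 streams keyed on
  (seed, stage salt).
* Everything is single-threaded; results are trivially independent of
  parallelism.

## Known limitations

* Indel matching is representation-based, not haplotype-aware: a complex
  substitution decomposed differently by two callers (e.g. MNV vs two
  adjacent SNVs) will not match.
* The window rule compares normalized anchor distance, not interval
  overlap; the two coincide for equal windows.
* The de novo machinery supports indels through the same normalized
  matching, but the evaluated scenarios are SNV-only.
* Multi-sample joint VCF semantics, structural variants > 50 bp, breakend
  notation and BAM/CRAM input are out of scope.
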