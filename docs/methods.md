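# Methods

## Distance model

Pairwise distances follow the Kimura 2-parameter (K2P) model. For each
sequence pair, sites where either sequence carries a gap or any IUPAC
ambiguity code are excluded (pairwise deletion); ambiguity codes are never
partially matched. Over the remaining sites, transitions are A<->G and
C<->T, every other differing pure-base pair is a transversion, and

d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the transition and transversion proportions. When
1 - 2P - Q <= 0, 1 - 2Q <= 0, or no sites overlap, the entry is stored as
undefined (NaN). Undefined entries propagate: divergence summaries skip
and count them, identification drops those candidates with a warning, and
tree building refuses the matrix naming the offending pair. We prefer this
explicit behaviour to saturation capping or silent imputation, either of
which would bias gap statistics invisibly.

## Divergence parameters

Three interspecific and three intraspecific parameters summarise a
labelled matrix: mean/SD over all defined between-species pairs; theta'
(by default the unweighted mean over species pairs of the mean
between-species distance — a literal all-between-pairs reading is exposed
as `theta_prime_mode="all_pairs"`, and the two coincide under balanced
sampling); the minimum between-species distance; mean/SD over all defined
within-species pairs; theta (unweighted mean over species with >= 2
members of the species' mean within-species distance); and coalescent
depth (maximum within-species distance). SDs use the n-1 denominator.
When every species is a singleton the intraspecific parameters are
reported as not available, never as zero.

## Rank tests

The intra/inter separation is tested two-sided with a Wilcoxon two-sample
rank test (statistic = rank-sum of the first group, midranks for ties).
The p-value is exact — full enumeration of rank assignments — whenever
C(n_a + n_b, n_a) <= 10^6, otherwise a normal approximation with tie
correction and a 0.5 continuity correction. The exact and approximate
branches agree to ~0.01 at the largest enumerable sizes; their agreement
at the switch point is asserted in the tests. The median test dichotomises
at the pooled median, counting values equal to the median as "not above"
(a fixed convention; the alternatives differ only for heavily tied data),
and uses Fisher's exact test when any expected cell is below 5, else the
chi-square test with 1 df without continuity correction.

## Identification rules

Both rules treat the data set as its own reference database and always
exclude the query itself; identical conspecific sequences deliberately
remain, since shared haplotypes between species — not self-matches — are
the phenomenon of interest. The best-hit rule is a BLAST-style surrogate
that scores aligned-column identity on the fixed alignment; on equal-length
gap-free sequences it ranks candidates exactly as the distance rule does
(identity is a monotone transform of p-distance), which the tests verify.
The outcome is CORRECT if all co-optimal hits are conspecific, AMBIGUOUS
if several species including the right one tie at the optimum, INCORRECT
otherwise. At species level the worst outcome among a species' queries
wins (INCORRECT > AMBIGUOUS > CORRECT), so the three columns always sum to
the species count; percentages are over species, not samples.

## Trees and monophyly

Neighbor joining follows Saitou & Nei with the Studier–Keppler Q-criterion;
UPGMA is average-linkage agglomeration with node height equal to half the
merge distance (hence ultrametric output). Ties in either criterion break
deterministically to the first minimal pair in creation order (leaves in
label order), so trees are platform-independent. Negative NJ branch
lengths are clamped to zero with the deficit logged. Bootstrap resamples
alignment columns with replacement, rebuilds with the same method, and
annotates each internal edge of the original tree with the percentage of
valid replicates containing the same bipartition (bipartitions are matched
as canonical tip sets, not node indices); replicates whose resampled
matrix contains undefined entries are skipped and counted. A species is
monophyletic on a rooted tree iff some clade equals its tip set, and on an
unrooted tree iff some edge — including a tip edge — splits exactly its
tips from the rest. Singleton species cannot fail and count as successes
by default (`singleton_policy="exclude"` drops them from the rate).

## Diagnostic signatures

A candidate column must be fixed for one unambiguous base across all
target members. A single-site diagnostic additionally requires that no
non-target sequence can carry that base; a gap or ambiguity code in a
non-target sequence is conservatively treated as possibly matching, so
such columns are rejected — a signature must not misfire on incomplete
data. Multi-site signatures are found by exhaustive subset search in
(size, lexicographic) order up to `max_k` (default 3) over the candidate
columns that exclude at least one non-target sequence (columns excluding
nobody can never belong to a minimal signature, which keeps the search
space small); only minimal subsets are reported, and a combinatorial
ceiling refuses oversized searches with guidance. Positions are reported
1-based relative to the analysed alignment and are not portable across
alignments; reports carry the alignment name.

## Haplotype collapsing

Strict policy: identical uppercased residue strings, gaps significant,
ambiguity codes matching only themselves. The `ignore_gap_only_columns`
policy first drops columns that are gaps in every member of the collapsing
scope; within a full alignment this is usually a no-op, but after region
extraction it removes alignment padding shared by the whole group.
Haplotypes are ordered by decreasing member count, then first occurrence.

## Synthetic genus generator

The generator emulates the data structure of a recently radiated genus
sampled for barcode evaluation: a uniform-random ancestral sequence; one
founder per species on a star phylogeny (branches of expected length
`interspecific_depth`, default 0.010 substitutions/site); per species a
few haplotypes (default 3) evolved from the founder along branches of
expected length `intraspecific_theta/2` (default theta 0.008); 3-6 samples
per species assigned with one sample per haplotype first and the dominant
haplotype weighted heaviest thereafter; alignment length 235. Substitutions
are drawn per site from the exact finite-time K2P transition probabilities
with transition/transversion rate ratio `kappa` (default 2), total rate
normalised so branch lengths are expected substitutions per site. Expected
values are therefore closed-form: two tips of different species diverge by
2*depth + theta in expectation (~0.028 at the defaults), two haplotypes of
one species by theta; the realized transition:transversion count ratio
tends to kappa/2 at short branches. Because some sample pairs share a
haplotype, the pooled mean intraspecific distance sits somewhat below
theta (~0.7-0.9 of it under the default assignment), which matches the
few-haplotype structure the generator emulates.

With probability `haplotype_sharing_prob` a species replaces its last
haplotype with a verbatim copy of its sister species' dominant haplotype
(sisters are consecutive index pairs; specific species can be forced).
Sharing decisions come from a dedicated random stream of per-species
uniforms, so for a fixed seed the event set is nested as the probability
grows — probability series use common random numbers and identification
degradation is exactly monotone, not merely on average. Copies are made
after all sequences are generated, so raising the sharing probability
changes nothing else. The generator is deterministic: one config + seed
yields byte-identical output.

What the generator does *not* emulate: indels and length variation (an
optional gap-injection rate exists solely to exercise pairwise deletion),
rate heterogeneity across sites, recombination, and realistic coalescent
genealogies. Passing tests on synthetic data therefore demonstrate the
correctness of the statistics and algorithms under the stated model, not
the field performance of any particular barcode.

## Problem sizes and numerical choices

The test suite and the acceptance script run 47-species genera of ~200
sequences x 235 sites (distance matrices of ~20k pairs), 20 replicate
seeds for parameter recovery, 200 random additive matrices up to 12 tips
for NJ recovery, 1000 random pairs for the distance oracle, and exhaustive
rank-test enumeration up to pooled size 10 — sizes at which every check is
exact or has negligible Monte-Carlo error while the whole suite stays
under a minute. Distance ties in identification use a 1e-15 absolute
tolerance (exact ties arise only from identical sequences); UPGMA
ultrametricity and Newick round-trips are checked at 1e-9. All randomness
derives from explicit integer seeds via numpy `SeedSequence` streams.

## Known limitations

* The best-hit rule is an alignment-column surrogate, not a local aligner;
  on data with alignment error or large indels it can rank hits
  differently than BLAST would.
* Undefined K2P entries make NJ/UPGMA refuse the matrix rather than
  attempt repair; heavily saturated or sparse data need pre-filtering.
* The exhaustive signature search is exponential in `max_k`; the default
  ceiling favours refusing over silently truncating the search.
* Published diagnostic positions refer to a specific alignment; the
  fixture's column map (1->141, 2->152, 3->159) illustrates how reports
  should be translated between coordinate systems.
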