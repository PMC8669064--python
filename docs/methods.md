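# Methods

This note records the models, defaults, numerical choices, and known
limitations behind each stage of the package.

## Coordinates and binning

All coordinates are 0-based half-open, matching BED; 1-based formats
would be converted at the I/O boundary. A `GenomeLayout` fixes
chromosome order, so global bin numbering is reproducible. Partial
terminal bins are kept (and carry their true genomic length in all
size accounting); nothing in the default pipeline excludes them.
Overlap counting uses "any overlap ≥ 1 bp" — an interval spanning k bins
contributes once to each — rather than midpoint assignment.

## Matrix balancing and observed/expected

Balancing is iterative correction: `b_i ← b_i · rowsum_i / mean(rowsum)`
on the corrected matrix until the maximum relative row-sum deviation is
below 1e-8 (default; 500 iterations max). At convergence this agrees, up
to a global scale, with any other doubly-stochastic balancing of the
same matrix, which is why the unit tests can verify the bias vector
against an independent nonlinear solve of the balancing equations.
Non-convergence is flagged on the result, never silently ignored.

Low-coverage bins are masked before balancing: marginals of zero, or
below the 1st percentile of nonzero marginals (configurable). Masked
bins propagate as NaN through every downstream statistic.

Expected models: trans entries are divided by the mean of valid entries
of their chromosome-pair block (a genome-wide trans mean is available
behind `trans_expected="global"`; per-pair is the default because it
removes chromosome-size artifacts). Cis entries are divided by the mean
at their bin distance within their chromosome. The diagonal (distance 0)
is always masked. By construction the mean of valid O/E entries in every
stratum is 1, which the tests assert to 1e-9.

## Subcompartment calling

The stitched matrix has odd-chromosome bins serially as rows and
even-chromosome bins as columns (parity parsed from the chromosome
name, falling back to layout position). Rows or columns with more than
30% masked entries are dropped to NA; remaining masked entries are
imputed with the column mean. k-means uses Euclidean distance on the raw
O/E profiles (no log transform by default; a flag exists), k-means++
initialization, 10 restarts, and a fixed seed; k = 6 for the odd axis
and k = 5 for the even axis by default, with `k_scan` reporting inertia
over k = 2..10 without automating the choice.

Within each axis independently, clusters spanning less than 5% of that
chromosome set's genomic extent are discarded; the survivors are ordered
by decreasing genomic size and merged rank-by-rank across the axes.
Unequal survivor counts are a hard error — merging by rank is undefined
in that case and silently guessing would corrupt everything downstream.
Size-rank merging assumes the per-axis size ranks are unambiguous; when
two clusters are near-identical in size the merge can mispair them, so
callers working with near-tied cluster sizes should verify the merge
against the cluster-profile correlations.

Naming: a merged cluster whose fraction of bins overlapping a LAD is
less than 0.5 is class A, otherwise class B (exactly 0.5 is B); within
each class, numbering is 1, 2, … by decreasing genomic size. Matching a
labeling to a reference uses the 4×4 contingency of bin labels, Pearson
residuals under the independence model, and the bijection maximizing the
summed matched-cell residuals over all 4! assignments.

## Hotspots and association testing

The percentile is nearest-rank (value at 1-based rank ⌈q/100·n⌉ of the
sorted sample) over all valid bins, zeros included; "high" means
strictly greater than that value, so threshold ties are low. The RNA
variant (`mode="any_nonzero"`) marks any bin with a nonzero count.

The association test is the one-sided Fisher 2×2 exact test (upper
hypergeometric tail) per (label, feature); p-values are reported raw,
with Benjamini–Hochberg available behind a flag. Odds ratios apply a
Haldane 0.5 correction only when a cell is zero.

## Strain comparison and differential summaries

The reduced matrix keeps hotspot bins only; replicate samples are summed
entrywise without re-normalization (the summed O/E matrices are compared
as-is). The paired test uses all unordered off-diagonal pairs valid in
both matrices — both cis and trans by default, `trans_only` restricts —
drops zero differences, and uses the exact signed-rank null for ≤ 25
informative pairs and the normal approximation with continuity
correction above.

The 1-Mb roll-up assigns each window the label covering the largest
labeled extent; ties go to the label with the smallest genome-wide size;
fully unlabeled windows are NA. Residual expected counts use the
quadratic size model: for N contacts in one direction, the pair (X, Y)
expects N·2p_Xp_Y (X ≠ Y) or N·p_X² (X = Y), with p the label's fraction
of the labeled genome; a linear-marginal alternative sits behind
`expected_model="linear"`. Expected counts sum to N exactly, and
swapping the up and down inputs negates every residual difference.

## Neighbor permutation

Blocks are maximal same-label runs per chromosome; NA stretches break
adjacency, so no boundary is counted across them. The null shuffles
block order within each chromosome — preserving the per-chromosome
multiset of (label, length) blocks exactly, hence the null genome has
"equivalent proportions" of blocks by construction — and merges
same-label neighbors created by the shuffle before counting. 100
permutations by default; the empirical two-sided p is
(1 + #{|perm − mean| ≥ |obs − mean|})/(n_perm + 1), so it is bounded
below by 1/(n_perm+1). When the permutation distribution is degenerate
(e.g. a two-block chromosome) the z-score is undefined (NaN) while the
empirical p remains valid. A per-bin resampling alternative was
considered; the block-shuffle null was chosen because it also preserves
the block-length spectrum.

## Long-read insertion classification

The aligner is a banded affine-gap Smith–Waterman (Gotoh) compiled with
numba: match +1, mismatch −2, gap open 5, gap extend 2 (a gap of length
L costs 5 + 2(L−1)). For pairs up to 4×10⁶ cells the band spans the
whole matrix, so the alignment is exactly optimal — the test suite
checks equality with a brute-force dynamic program on short pairs. For
long reads the band is placed around the densest cluster of exact
13-mer seed diagonals with 100 bp of padding; at HiFi-scale error rates
(≲ 1% substitutions, few indels) the optimum lies inside the band. A
read with no seed cluster returns no hit. Bit scores are
(λS − ln K)/ln 2 with λ = 1.28, K = 0.46 fixed for the default scheme;
since both competing alignments (consensus vs masked reference) use the
same constants, the de-novo comparison is invariant to the common scale.
Exact parity with BLAST+ scores is not a goal; the arbitration only
needs a common monotone scale.

Classification: flank alignments are filtered at MAPQ exactly 60 by
default (a ≥ flag exists because aligners cap MAPQ at 60 and the intent
of an exact filter is ambiguous); a left flank anchors the insertion at
its end, a right flank at its start, and two passing flanks must agree
within 50 bp or the read is unresolved. Anchored coordinates overlapping
an annotated element site take precedence over scores (target family →
`annotated_element`, other family → `annotated_other`). Otherwise the
read is `de_novo` iff its consensus bit score strictly exceeds its
masked-reference bit score; ties are conservatively unresolved. The
full-length cutoff is the smallest integer strictly exceeding 0.9 × the
consensus length — 5833 for the 6481-bp IAPEzi internal consensus —
compared against the matched consensus length (aligned consensus
positions, gaps excluded). The consensus models the internal element, so
reads carrying only LTR-like sequence produce no consensus hit and are
excluded from calls.

Per-sample compartment enrichment is observed/expected with expected
proportional to label genome fractions; the all-calls vs
full-length-calls contrast per label uses the same paired signed-rank
machinery as the strain comparison.

## The synthetic generator

The generator defines the package's test bed; it makes no claim about
the generative process of real Hi-C or SMRT data.

Defaults: 8 chromosomes × 20 Mb at 250-kb bins (640 bins). Label
proportions A1 = 0.42, A2 = 0.28, B1 = 0.18, B2 = 0.12 — decreasing
within class, B2 smallest, and spaced widely enough that size-rank
merging is unambiguous on both chromosome parities. Blocks have
geometric lengths around per-label means (A1 4 Mb, A2/B1 3 Mb, B2 2 Mb —
B2 as megabase-scale "islands"), with per-chromosome label quotas so
realized genome-wide fractions land within ±2% of targets. Two small
satellite classes (2 bins/chromosome; 3 bins per odd chromosome for the
second) emulate the minor clusters real maps produce: they form their
own k-means clusters, fall under the 5% filter, and are discarded —
which is why the default k = 6 (odd; four labels plus two satellites)
and k = 5 (even; the second satellite is absent there) match the
calling defaults. Satellite bins are NA in the planted truth.

Contacts are Poisson (negative-binomial overdispersion is a possible
extension, not implemented): trans λ = 50·a[ℓᵢ,ℓⱼ], cis
λ = 200·a[ℓᵢ,ℓⱼ]·d⁻¹ with decay exponent α = 1, typical of Hi-C distance
scaling. The affinity matrix has same-label affinity 2.5 (B2–B2 3.0)
against a cross-label baseline of 1 — a contrast of at least 2 and
roughly 50+ counts per bin-pair stratum, which is the regime in which
the recovery tests assert ARI ≥ 0.9. Repeat families plant a 3-fold
per-bin Poisson density boost in one compartment each (the ERV2-like
family in B2, base rate 3 per bin); LADs cover B bins with sensitivity
0.95 and A bins at 1 − specificity = 0.05. The strain pair multiplies
intensities by 1.5 on hotspot-by-hotspot pairs only, leaving all other
pairs identically distributed.

Reads are left flank (1 kb) + consensus prefix fragment + right flank
with per-base substitution errors (default 0.1%, HiFi-like; indel errors
are not simulated). Junction bases are forced to mismatch the consensus
continuation so the aligned consensus span equals the planted fragment
length exactly; fragment lengths straddle the 5833 cutoff by
construction. Decoy reads carry an independent LTR-like sequence and no
internal-consensus homology; "reference-present" reads have their insert
un-masked in the reference window, exercising the not-de-novo branch of
the bit-score rule. The masked reference is represented as per-site
windows (flanks with the element absent) rather than a full genome
sequence — sufficient for the bit-score arbitration at desk scale.

What passing tests do and do not show: the generator's contacts are
Poisson with block-constant affinities, so recovery at ARI ≥ 0.9 shows
the procedure is correct and well-calibrated under its own model, not
that real maps separate this cleanly; real Hi-C has overdispersion,
translocation artifacts, copy-number structure, and continuous (not
block-constant) compartment strength. Likewise the read simulator's
substitution-only errors understate real indel-rich failure modes of
alignment anchoring.

## Problem sizes and runtime

The default test bed (640 bins, 200 reads, 100-replicate Monte-Carlo
checks, 1000-table calibration sweeps) was chosen so the full suite and
the acceptance script each complete in a couple of minutes on one CPU
while keeping every statistical check at a sample size where its nominal
behavior is measurable.
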