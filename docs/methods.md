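# Methods

## The model

A microinversion is treated as a point event on a dated phylogeny: in a
locus of (mean, among taxa) non-coding length L bp, the number of
inversions accumulating over a treelength of T MY is

    c ~ Poisson(lambda * E),    E = (L / 1e6) * T   [Mb * MY]

with lambda the genome-wide rate in inversions Mb^-1 MY^-1. The exposure E
is the Poisson offset; the MLE under rate homogeneity is the pooled
estimator sum(c_i)/sum(E_i), and per-locus plug-in rates are c_i/E_i.

Among-locus heterogeneity ("hotspot" loci) is modelled by a multiplicative
gamma rate: lambda_i = lambda * r_i with r_i ~ Gamma(shape k, mean 1).
Marginally the counts are NB2 negative binomial with mean mu_i = lambda*E_i
and variance mu_i + mu_i^2/k; Poisson is the k -> infinity boundary. The
homogeneity test is the LRT 2*(lnL_NB - lnL_Pois), referred to chi^2 with
1 df. Because the null sits on the parameter boundary, the chi^2(1)
reference is conservative (a 50:50 mixture of chi^2(0) and chi^2(1) would
be exact); the plain chi^2(1) reference is used deliberately so reported
p-values match standard practice for this test, and the calibration test
confirms the realised type-I error is below nominal. Exact rate CIs are
Garwood: [qchisq(a/2, 2c), qchisq(1-a/2, 2c+2)] / (2E), with lower bound 0
at c = 0.

Power questions are closed-form in the same model: P(>=1 event on a branch
of t MY in L Mb) = 1 - exp(-lambda*L*t), and the length needed for target
probability P over n candidate branches is L = -ln(1-P)/(lambda*t*n).

## Detection

Inverted tracts are found as local alignments between one sequence and the
reverse complement of another. For every unordered taxon pair the degapped
sequences are aligned by affine-gap Smith-Waterman against the reverse
complement (match +1, mismatch -2, gap open -5, gap extend -2); hits are
harvested best-first with masking, and kept when score >= 8, aligned span
>= 5 bp and identity >= 0.75. The paired coordinates are projected back to
alignment columns through per-row coordinate maps, and hits whose column
spans overlap or fall within 10 columns are single-linkage clustered into
candidate regions. Within a region, hits whose endpoints agree within 5
columns are treated as witnessing the same event, so independent
overlapping inversions in different lineages separate into distinct calls
that share an `overlap_group` id. Two such configurations are
distinguished in the simulator (type I: partially overlapping tracts;
type II: nested tracts); multiple overlapping events on a *single* branch
(type III) are not separable by this strategy and are deliberately not
generated.

Validation is by re-inversion. The hits of a region imply an
opposite-orientation bipartition of the taxa (a complementary-strand hit
means the two taxa disagree in orientation); the graph is 2-coloured, taxa
without hits are attached to the side they resemble, and the carrier side
is the one whose re-inverted tract best matches the other side. Because
re-inversion quality is symmetric between the two orientations (flipping
either side reconciles them), sides are compared with a 0.02 identity
tolerance and ties resolved by parsimony (the smaller carrier set), or by
an outgroup when one is supplied. The reported `validation_delta` is the
mean identity gain of the carriers' re-inverted tract over its as-is
identity to the non-carriers. A call is `validated` when delta >= 0.1 and
every carrier tract is 5-400 bp; `rejected` when delta <= 0 — the
signature of palindromes, which are additionally flagged whenever a
carrier tract matches its own reverse complement at >= 0.75 identity
(palindromes produce hits in *every* pair and a non-bipartite graph);
`candidate` otherwise.

Numerical notes. With match +1 a perfect hit must span 8 bp to clear the
score threshold, so detection is complete from 8 bp up; 5-7 bp tracts are
callable only through the manual-interval channel, mirroring the practical
difficulty of validating the very shortest inversions. At zero divergence
a chance complementary base adjacent to a tract boundary legitimately
extends the alignment by a column; endpoint accuracy is therefore exact
only when the flanks are non-complementary, and within +/-2 columns
otherwise. Ambiguity codes are kept verbatim and score as mismatches — a
conservative choice that cannot fabricate complementary hits. All-gap
columns are preserved so column indices remain stable; reports are 1-based
inclusive, internal coordinates 0-based half-open.

## Characters on the tree

Calls become binary characters (1 = inverted orientation; `?` for taxa not
sampled at the locus; calls carried by every sampled taxon have no
polarity information and are skipped). Minimum change counts use the
Sankoff/Hartigan dynamic programme with symmetric unit costs, which equals
the unrooted Fitch minimum for a two-state character and handles
multifurcations and missing states directly. Branch placements are
recovered by a preorder pass over the subtree cost tables; at
equal-cost choices DELTRAN keeps the parent state (changes pushed
tipward, the default) and ACCTRAN flips (changes pulled rootward); ties at
the root prefer state 0 (ancestrally uninverted). Both resolutions place
exactly the minimum number of changes; characters whose two resolutions
differ are flagged ambiguous so terminal/internal tallies carry a range.

The retention index per character is (g-s)/(g-m) with s the observed
minimum, m = 1 for a variable binary character, and g = min(#0, #1) among
non-missing states (the worst case, realised on a star tree); the ensemble
RI sums g, s, m over parsimony-informative characters. The terminal-bias
test compares the observed terminal/internal event split to the split of
treelength by a 1-df chi-square goodness-of-fit test: under a uniform
Poisson process, events fall on terminal branches in proportion to their
length share.

## The synthetic-data generator

The generator runs the rate model forward so that every downstream stage
can be tested against planted truth. A uniform-random root sequence
evolves down a dated tree; each branch of length t receives Poisson
substitutions (equal-rates single-parameter model, default 1.5e-3
subs/site/MY, a typical avian neutral rate), optional indels (geometric
lengths, mean 3 bp), and Poisson(lambda_MI * L_Mb * t) inversions with
uniform positions. Inversion lengths follow a discrete triangular
distribution on [5, 40] bp peaked at 22 — matching the observed avian
spectrum (minimum 5, maximum 38, median 22) without overfitting a small
sample. The default lambda_MI is 0.39, the pooled avian estimate; hotspot
simulations draw per-locus gamma(k, mean 1) multipliers so marginal counts
are NB2, the exact alternative the LRT tests. Every residue carries a
homology-column id: substitutions and inversions preserve ids (an inverted
tract still aligns positionally against its uninverted homologs — exactly
the signature detection exploits), only indels create or remove columns.
Leaf sequences therefore assemble into a truth-aware alignment without a
re-alignment step, and the registry records each event's branch, tract,
length and realized carrier leaves. One seeded generator stream is used
per locus, derived from (seed, locus index) via SeedSequence spawn keys,
so any locus is reproducible independently of execution order.

What the generator does *not* emulate: realistic base composition or
rate-class structure, selection, alignment error from an actual aligner,
and palindrome-driven inversion mechanisms. Passing the pipeline tests
therefore demonstrates correctness of the algorithms under the stated
stochastic model, not robustness to manual-alignment artefacts in real
data — the reason the manual-interval validation channel exists.

## Fidelity to the published survey, and known wrinkles

The packaged 17-locus avian table reproduces the published per-locus rate
column at 2 dp for 15 of 17 loci. Two printed values are not reproduced by
their own printed inputs (CLTCL1 prints 1.58, inputs give 1.5623; TPM1
prints 0.28, inputs give 0.2747) — most plausibly unrounded lengths
upstream of the published table; the fixture stores both printed and
computed values. The overall pooled rate prints 0.39 while sum(c)/sum(E)
on the printed inputs is 0.3951 (rounding to 0.40); the per-formula value
is reported and tested to within one unit of the printed last digit. Both
LRT statistics are reproduced to two decimals (27.55 all loci; 2.29
excluding the hotspots, p = 0.13 under chi^2(1)). The published 95% CI of
0.17-0.36 for the non-hotspot rate: the Garwood lower bound 0.17 is
reproduced exactly, but no standard method (Garwood ~0.353, Wald-log
~0.35) yields the printed upper 0.36; the CI construction actually used
for the upper endpoint is unknown, so the upper bound is guaranteed by a
coverage property test instead of a value check. The power figure of ~12
Mb per taxon corresponds exactly to P = 0.95 (ln 20/0.25 = 11.98); the
companion "~1.2 Mb for at least one informative inversion" figure is
consistent with spreading the requirement over ~10 candidate branches,
which is why `n_branches` is an explicit parameter rather than a baked-in
assumption.

## Problem sizes used in the test suite

Simulation-backed tests use 5-12 taxon trees, 300-800 bp loci and
200-2000 replicates for calibration checks (type-I error of the LRT,
exact-CI coverage, pooled-rate recovery); these sizes give Monte-Carlo
error comfortably below the tested margins while keeping the suite quick
to run. Detection tests plant events of 8-60 bp, spanning the validated
size range.
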