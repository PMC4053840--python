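# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `fourc`, and what the synthetic validation does and does not
establish about real data.

## Coordinates and the fragment map

All coordinates are 0-based half-open, internally and in BED/bedGraph
output.  The in-silico digest places fragment boundaries at every
`site_start + cut_offset` on the forward strand (HindIII `A^AGCTT` →
offset 1, DpnII `^GATC` → offset 0; both motifs are palindromic, so a
forward scan covers both strands, and `N` never matches).  Fragments tile
each chromosome exactly.  Non-palindromic or IUPAC-degenerate motifs are
out of scope.

Arm assignment and the centromere distance use the **fragment midpoint**;
this gives every fragment a single unambiguous arm even when it straddles a
centromere boundary.  Whether "distance to the centromere" should be
measured from the midpoint or the nearest edge is a genuine free choice;
midpoint was chosen and the difference is at most half a fragment length
(~2 kb at the default spacing), well below the 100 kb exclusion radius
that the distance feeds.  Exactly one centromere interval per chromosome is
required; fragmented assemblies must be pre-merged.

Secondary-site distances are measured from the fragment 5' end to the first
fully contained secondary site start, and from the 3' end to the last
site's end.  Absence is encoded as an infinite distance, which makes the
"both ends ≥ 1 kb from a secondary site" filter rule apply to site-free
fragments without a special case.

## Read geometry and end anchoring

Demultiplexing removes the primer and the **full** primary restriction
site before trimming to 30 nt.  Because fragment boundaries sit at cut
positions *inside* the motif, a forward-strand read therefore begins
`len(motif) − cut_offset` bp after its fragment's 5' boundary, and a
reverse-strand read ends `cut_offset` bp before the 3' boundary.
`count_fragment_reads` takes these two anchor offsets explicitly
(`end_anchor_offsets` derives them from the enzyme); with offsets 0 it
also accepts alignments that were trimmed to start exactly at fragment
boundaries, which is how imported external alignments enter.  Anchoring is
exact by default; `end_tolerance` relaxes it by ±k bp.

Multiread rescue follows the standard local-support strategy: each read
with 2–25 exact hits is distributed over its end-anchored candidate
fragments in proportion to the unique-read mass within ±50 kb of each
candidate's midpoint (50 kb being half the ~100 kb single-interaction
unit), and discarded when no candidate has unique support.  Reads with
more than 25 hits are dropped, mirroring the usual repeat cap.

The exact-match mapper 2-bit-packs every genomic 30-mer into a `uint64`
(a perfect hash for k ≤ 31) and resolves queries by binary search on the
sorted code array, looking the reverse complement up against the same
forward index.  It exists because the package replaces an external aligner
at desk scale; it is exact, not mismatch-tolerant.

## Interaction values and the shuffle null

The interaction value of a window is Σ log₂(count) over member fragments
with count ≥ 1 (zero and sub-unit fractional counts contribute 0, keeping
values non-negative and damping single hot fragments).  Windows are built
over **valid** fragments in arm order and never cross the centromere.

The null permutes counts among the arm's valid fragments only.  Per
shuffle, a normal distribution is fitted (sample mean and sd, ddof = 1) to
that shuffle's window values and each observed window receives its
upper-tail probability; the final P is the mean over 1,000 shuffles.  The
literal fit-per-shuffle-then-average reading is the default; a pooled mode
(one normal over all shuffles' values) is available via `pooled=True`.
Degenerate cases are defined, not errors: sd = 0 in a shuffle yields a
preliminary P of 1 when the value does not exceed the mean and 0 otherwise,
and arms with fewer than two windows keep P = NaN.  One master seed yields
per-arm spawned RNG streams, so results are bit-reproducible and arms
independent.

On exchangeable counts this construction is calibrated: with 10,000
independent (non-overlapping) windows and 1,000 shuffles, the observed
fraction of windows at P ≤ 0.01 falls within 3 binomial standard errors of
0.01 (the acceptance suite runs exactly this experiment).  The normal fit
is an approximation whose quality grows with window size and per-fragment
coverage; at windows of 100 fragments and mean counts ≳ 10 the tail error
at the 1% level is below the binomial band.

Prey calling is `P ≤ threshold` for a single track and `P < threshold` in
every replicate when two tracks are supplied, mirroring the two
conventions in use; both are overridable.  No FDR is applied to window
P-values (raw-P thresholding is the method's convention).

## Distance decay

Reads of one or more viewpoints are pooled into 41 log₁₀-distance bins.
The 1 kb–10 Mb range at 0.1 width arithmetically spans 40 intervals; the
implementation reads the count as fenceposts: bin centers at
log₁₀ d = 3.0, 3.1, …, 7.0 with edges at ±0.05, giving exactly 41.
Distances run from the **fragment midpoint** to the viewpoint position
(read positions within a fragment are not resolved by 4C anyway), on the
viewpoint's own arm and over valid fragments only.

Each bin's read total is divided by the number of fragments the bin
contains (pooled across viewpoints) before the grand normalisation to
Σ = 1.  This reads the binned curve as a **per-fragment contact
probability**: with ~constant fragment spacing, log-bins contain a number
of fragments proportional to d, so summing raw reads per bin would shift
the log-log slope by exactly +1 and the fitted exponent would no longer
estimate the per-fragment decay that the generator (and the field's
distance-decay convention, e.g. the human −1.08) defines.  The
per-fragment normalisation makes generator, estimator and the cross-genome
comparison mutually consistent.

The smoother is a hand-written local polynomial regression (degree 2,
tricube weights, span 0.75 — the installed lowess is degree-1 only and
offers no prediction interface at arbitrary points).  LOESS is fitted to
log₁₀(probability) over non-empty bins and predicted at **all** 41
centers, then an ordinary least-squares line through the predictions gives
the slope (the decay exponent) and regression P.  `use_loess=False` fits
the line to the raw non-empty bins directly; on clean power laws both
modes agree to < 10⁻³, and the slope is invariant to overall library
scaling.  The estimator carries a small attenuation bias (≲ 0.03 toward
zero at 10⁵ reads) from sparsely populated far bins; it stays within the
±0.05 recovery tolerance across generating exponents −0.5 … −1.0.

## Arm classes, dist₀.₅ and the regressions

rpm(arm) = 10⁶ × reads on the arm's valid fragments / library, with the
library defined as all reads on valid fragments, so rpm sums to 10⁶ per
viewpoint.  Classes are the viewpoint arm, the other arm of its chromosome
(cis) and all remaining arms (trans); class values are unweighted means
over member arms.  `viewpoint_masked` recomputes the viewpoint arm after
removing fragments within ±2 Mb of the viewpoint (same denominator; the
fragment exactly at the mask boundary is excluded).  The t-tests are
two-sided and **paired** across viewpoints — the same libraries appear in
both members of every comparison, so pairing is the appropriate design.

dist₀.₅ orders an arm's valid fragments by centromere distance and takes
the first fragment at which the cumulative read fraction reaches ≥ 0.5 (no
interpolation); dist₀.₅-rel divides by the arm length (centromere boundary
to chromosome end).  The viewpoint's own arm is excluded, zero-read arms
yield NaN sentinels and drop out of the regressions.  Regression (i) fits
arcsin√dist₀.₅-rel (the standard variance-stabilising transform for
proportions) against the viewpoint's relative centromere distance;
regression (ii) fits the RPKM over all arms except the viewpoint arm
(cis arm included; the denominator is the kb of valid fragment territory
on those arms) against the absolute viewpoint–centromere distance.  Both
report OLS slope/P and Spearman rho.

## Epigenome integration

EMD of a fragment is |union of covering intervals ∩ fragment| / fragment
length — intervals are merged before measuring, so overlapping input
never double-counts; window EMD is the unweighted mean over member
fragments.  (This matches a per-base boolean-mask computation exactly,
which the test suite asserts.)

Control regions are drawn uniformly without replacement from the eligible
pool (non-prey windows with defined P, outside a caller-supplied exclusion
such as the viewpoint's ±2 Mb); pools smaller than the requested 50 fall
back to sampling with replacement and warn.

The permutation test resamples 50 preys and 50 controls per viewpoint in
each of 1,000 repetitions, records RealDiff = |mean difference| of their
EMDs, pools the 100 values and re-splits them at random for RandDiff, and
reports p = Σ(RandDiff > RealDiff_mean)/(i·j).  The comparison is strict
as printed; an equality tolerance of 10⁻⁹ keeps exact ties from flipping
on float rounding, and a `gte` option turns the degenerate all-constant
case (p = 0 under strict >) into the conservative p = 1.

The GSEA-like test sorts a viewpoint's regions (non-overlapping
25-fragment windows off the viewpoint's arm) by EMD descending, stable
with ties broken by window index; test regions weigh (n−m)/m and the rest
−1, so weights sum to zero and the running sum returns to zero; ES is the
maximum absolute excursion, which makes it invariant to reversing the sort
direction.  The null draws 10,000 random m-subsets per viewpoint — since a
random subset occupies uniformly random ranks, the EMD values drop out and
the null depends only on (n, m).  Observed ES and matched null draws are
averaged across viewpoints and p is the fraction of null means ≥ the
observed mean.  Both tests are BH-adjusted across features
(statsmodels step-up).

PCA of the viewpoint × {prey, control} mean-EMD matrix is covariance-based
(centered, unscaled — the convention of the classical `princomp` route;
`scale=True` switches to correlation PCA), computed by SVD; a constant
matrix returns zero variance and zero scores rather than erroring.

## The synthetic generator

The generator's defaults are the standard study conditions used throughout
the validation suite: five 2 Mb chromosomes with centred 100 kb
centromeres; primary sites planted at ~4 kb mean spacing (the natural
6-cutter rate) and secondary sites at ~256 bp (4-cutter rate), with
accidental motif occurrences mutated away so the digest truth is exact;
two viewpoints (one euchromatic, one heterochromatic); cis contact decay
d^γ with γ = −0.73 (the pooled exponent the estimator is built to
recover) carrying half of each library, the rest uniform over the other
arms, plus a 5% self-ligation fraction at the viewpoint fragment; 20 prey
windows of 25 fragments planted at 8× sampling mass on arms other than
the planting viewpoint's own (renormalised multiplicative enrichment);
200,000 reads per viewpoint.  Reads are primer + site + the first 30 nt
past the anchor offset of the chosen fragment end, on a random strand.
One master seed feeds named sub-streams (genome / reads / EMD / preys /
controls), so each stage is independently reproducible and byte-identical
under the same seed.

Chromatin features are Beta-distributed per fragment with state-dependent
means (heterochromatic marks 0.6 in het domains vs 0.1 in eu, euchromatic
marks mirrored; concentration 20), over ~200 kb domains whose
heterochromatin probability is biased to 0.85 on a heterochromatic
viewpoint's home chromosome and 0.15 on a euchromatic one's.  The PCA
fixture draws each viewpoint's preys from same-state domains on other
chromosomes and its controls from its own (state-biased) chromosome —
encoding the observation that a viewpoint's chromosomal environment shares
its chromatin state, which is what makes prey *and* control rows of the
two viewpoint classes separate by sign on PC1.

What the generator deliberately omits: sequencing errors, PCR duplicates,
mappability structure beyond exact repeats, diploid/allelic effects,
biological replicate variation beyond resampling noise, and any
chromatin-state dependence of the *contact* model itself.  Passing the
synthetic suite therefore demonstrates correctness of the computations and
calibration of the statistics under the stated model, not robustness to
real-library artefacts.

Planted-prey recovery is evaluated on windows outside each viewpoint's own
arm — preys are planted there by construction, and the viewpoint arm's
power-law proximity signal is *true* local interaction which the
long-range analyses remove with the ±2 Mb viewpoint exclusion; counting
those windows as "false" calls would mislabel genuine signal.  Under the
default conditions the pipeline recovers 100% of planted preys at
P ≤ 0.01 with zero false calls off the viewpoint arms.

## Problem sizes

The validation suite runs at deliberately small scale, chosen so the whole
suite completes in a couple of minutes on one CPU while keeping every
statistical check adequately powered: a 10 Mb single-arm genome with 10⁵
reads for decay recovery, 10⁶ synthetic fragments / 10⁴ windows / 10³
shuffles for the null calibration, the default 10 Mb five-chromosome study
with 2 × 10⁵ reads per viewpoint for end-to-end prey recovery, and
enumeration oracles at n ≤ 8.  All sizes are configurable upward.

## Known limitations

- The shuffle null assumes exchangeability of fragment counts within an
  arm; systematic coverage gradients (GC, mappability) would need to be
  removed upstream or they will inflate the null's spread.
- The normal approximation inside the P-value machinery is poor for very
  small arms (few windows) — P-values there are noisy and conservative
  rather than wrong, and arms below two windows are reported as NaN.
- The decay estimator extrapolates the LOESS into empty low-distance bins;
  with a single viewpoint the first ~5 bins often contain no fragment, and
  the fitted exponent carries a small attenuation bias (see above).
- The exact-match mapper requires error-free 30-mers; real libraries
  should be aligned externally and imported.
- dist₀.₅ uses a first-crossing convention; for arms dominated by a single
  fragment it equals that fragment's centromere distance exactly.
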