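# Methods

## The problem setting

A female heterozygous for a paracentric inversion (the *dl-49* X
inversion, breakpoints at 4,897,260 bp and 13,427,212 bp of the 23.5 Mb
dm6 X chromosome, is the default parameterization) is crossed so that
each male offspring reports one maternal chromatid.  Two isogenized
parental haplotypes differ at diagnostic SNVs — roughly one per 367 bp
in the dense parts of the chromosome — so the parental origin of every
site in an offspring is readable from its genotype.  A crossover (CO)
appears as a persistent origin switch; a noncrossover gene conversion
(NCOGC) as a short island of the other parent's origin flanked by the
original; nondisjunction (NDJ) as an offspring carrying both maternal
homologs, diagnosed by missing Y-chromosome coverage in male-expected
offspring.

## Event calling

After dropping UNKNOWN sites (missing or non-parental alleles), the
origin vector is run-length segmented and scanned left to right with a
current *background* origin (initially the first run's origin):

* a departure run that reverts to the background and whose switched
  sites span at most `max_ncogc_span` (default 10 kb — generous against
  the ~400 bp expected tract but far below typical double-CO
  separations) is an NCOGC; single-site tracts are called but flagged
  `low_support`;
* a departure too wide for a tract is a double CO (both boundary COs
  reported); a departure that persists to the end of the informative
  region is a CO;
* a CO boundary requires support on both sides: the background-side
  flank run needs `min_support_co` sites (default 2) *or* to be the
  first run of the informative region; the departure run itself always
  needs `min_support_co` sites.  Under-supported switches are recorded
  as unresolved, never called — this is the guard against isolated
  genotyping errors.

Equivalent formulation used by the test oracle: origin-switch
boundaries form a path; pairing two adjacent boundaries turns the
enclosed run into a tract, and among all valid pairings the
maximum-cardinality, lexicographically earliest one is chosen (events
are parsimonious and assigned left to right).  The left-to-right scan
above provably selects the same pairing; the test suite verifies the
equivalence exhaustively on all 4,096 binary vectors of length 12.

CO uncertainty intervals are `(left_flank, right_flank]` over the
nearest informative markers; the midpoint of this interval is the point
used for window binning.  Events are compared across offspring by their
converted-site sets: identical sets in two or more offspring define a
jackpot group (a pre-meiotic conversion propagated to several gametes).
In recombinant-selected offspring, COs whose uncertainty interval lies
wholly outside the selected marker interval were never selected for and
are flagged excluded from frequency analyses (NCOGCs never are).

NDJ calling is a strict less-than on normalized Y coverage (default
threshold 0.1× autosomal); coverage exactly at the threshold is not
flagged, and missing coverage yields an undetermined status rather than
an error.

## The meiosis model

One transmitted chromatid is simulated per meiosis (no four-strand
bookkeeping).  Per candidate:

* **DSB count** — mean 1.42 per chromatid, by default *regulated*:
  `floor(mean)` plus a Bernoulli remainder.  Meiotic DSB numbers are
  tightly controlled, and the underdispersed count matters
  qualitatively: it couples CO and NCOGC numbers through fate
  competition.  With an exactly Poisson count the per-chromatid CO and
  NCOGC counts are independent (Poisson thinning), and eliminating
  CO-bearing chromatids could not enrich conversions — transmission
  distortion would be invisible by construction.  A `poisson` mode is
  available for comparison.
* **DSB fate** — at position x, CO with probability c(x), NCOGC with
  constant probability `p_nco` = 0.53, otherwise invisible (intersister
  repair).  The constant conversion probability encodes the central
  modeling commitment: inversion breakpoints alter repair *outcome*,
  not DSB formation, so conversions are generated evenly along the
  chromosome whether or not the inversion is present.
* **CO probability** — `p_co` = 0.47 in unsuppressed regions.  With
  1.42 DSBs per chromatid this gives 0.667 COs per chromatid (a ~67 cM
  X, matching the classical map) and 0.753 conversion tracts per
  chromatid (the rate that predicts ~50 detectable NCOGCs per 100
  offspring at 367 bp marker spacing).  Outside the inversion, c(x) =
  `p_co`·f(d) with d the distance to the nearest breakpoint: f = 0
  within 500 kb, rising linearly to 1 at 3 Mb on the proximal side.
  The distal side uses a 10 Mb ramp so it stays strongly suppressed
  throughout — emulating the observed near-absence of distal COs, which
  the data attribute to combined telomere + breakpoint effects.  The
  functional form is a declared package choice (the true shape of
  distance-dependent suppression is unknown); both radius and ramp are
  configurable, as is the whole profile.
* **Inside the inversion** — flat CO probability `p_co_intra` = 0.246,
  calibrated (see `calibrated_p_co_intra`) so that ~12% of
  pre-selection chromatids carry exactly one intra-inversion CO, the
  classical compound-X estimate for *dl-49* heterozygotes.
* **Transmission** — a candidate carrying an odd number of
  intra-inversion COs is acentric/dicentric; it is rejected and the
  meiosis redrawn (polar-body elimination, bounded attempts).
  Offspring therefore never carry a single intra-inversion CO, and the
  accepted pool is conversion-enriched: conditioning on "no odd intra
  CO" shifts intra-inversion DSB fates toward conversion.  With default
  parameters the transmitted fraction carrying ≥1 tract rises from
  ~0.635 (inversion off) to ~0.676 (on) — generation rates identical.
* **Tracts** — geometric lengths, mean 400 bp, truncated at 1 bp,
  placed uniformly over the initiating DSB.  NDJ offspring are injected
  at a configurable rate; they phenotypically mimic recombinants (the
  cross-2 scenario), carry near-zero Y coverage, and their genotypes
  are rendered as an arbitrary per-site collapse of the heterozygous
  diplo-X genotype.  Jackpot clones share one tract, anchored on an
  unmasked marker so the shared event is detectable, across k ≥ 2
  offspring.

CO interference is not modeled (DSB fates are independent given
positions), and the marker loci used for phenotypic selection
(y ≈ 0.25 Mb, cv ≈ 5.80 Mb, wy ≈ 13.14 Mb, f ≈ 17.43 Mb; approximate
dm6 coordinates) act as pure readouts of chromatid origin.

## Synthetic panels

Marker positions follow a Poisson process at one per 367 bp, with a
configurable low-density span (default: the distal segment up to the
distal breakpoint, one marker per 81,540 bp) emulating the shared
ancestry that strips diagnostic SNVs from part of a real cross.
Density is profiled in 50 kb windows at 25 kb steps; a site is masked
when *any* window containing it falls below the threshold
(conservative, so whole sparse spans drop out of event calling, which
is how regions unable to reveal ~400 bp tracts must be treated).  What
the generator does **not** emulate: sequencing-depth variation along
the chromosome, clustered genotyping errors, reference bias, and
non-uniform real recombination landscapes.  Passing round-trip tests
therefore demonstrate correctness of the calling logic under the stated
noise model, not robustness to every artifact of real short-read data.

## Recovery scoring

Round-trip tests compare caller output to simulator truth under
explicit resolvability rules (these are properties of any
marker-based method, not of this implementation): a CO needs
`min_support_co` unmasked markers on each side, untouched by conversion
tracts, and no second CO either in the same informative gap (the pair
is invisible) or separated by markers spanning ≤ `max_ncogc_span` (the
pair is definitionally a tract pattern); a tract must cover an unmasked
marker and have unmasked flanks free of other events.  A called CO
matches truth when its uncertainty interval contains the true
breakpoint; a called NCOGC when its converted-site set equals the
tract's covered markers.  Calls explained by no truth at all are
spurious.  At error rate 0 the scorer reports 100% / 100% / 0 spurious.

## Statistics

* Map length: cM = 100·r/n with Clopper–Pearson 95% CI (beta-quantile
  inversion of the binomial tails; lower bound 0 at r = 0, upper 1 at
  r = n), scaled by 100.
* Fisher exact test: two-sided by the point-probability method (sum of
  same-margin hypergeometric probabilities ≤ the observed table's) —
  the definition used by the common online calculators these analyses
  are reported with; scipy implements it and the suite cross-checks it
  against an independent enumeration oracle.
* Spearman correlation of window frequency vs distance-to-breakpoint:
  average ranks for ties, two-sided p from the t approximation on n−2
  df (appropriate at the ~17–28 windows these analyses use); constant
  inputs return an explicit undefined (NaN) result.
* KS two-sample comparison of CO position distributions with the
  asymptotic p-value.
* Window maps: 150 kb non-overlapping windows anchored at the analysis
  interval start (the anchor is configurable since it is an arbitrary
  convention), events assigned by uncertainty-interval midpoint,
  half-open on the right; frequencies normalized by the total event
  count of the analysis set (they sum to 1 exactly), each with an exact
  CI on count/total.
* Detection power: with Poisson marker placement at mean spacing d̄, a
  fixed-length-L tract covers ≥1 marker with probability 1 − e^(−L/d̄)
  (0.664 at L = 400, d̄ = 367); for geometric tract lengths the same
  average is taken through the geometric law's MGF, giving ~0.52 — the
  fixed-length form is the one used for the ~50-per-100-offspring
  prediction, and both have Monte-Carlo cross-checks.  Expected yield
  is n·λ·P(detect) with λ the tracts per meiosis.
* Reporting: cM to 1–2 decimals, p-values to 2 significant figures,
  floored as "< 0.0001" below 1e-4.

## Numerical and design choices

* Positions are 1-based throughout the in-memory types (VCF
  convention); BED output and window arithmetic convert at the boundary
  via documented converters.  A CO interval `(left, right]` 1-based is
  numerically identical to its 0-based half-open BED rendering.
* Degenerate inputs: an all-UNKNOWN offspring raises an explicit
  "uninformative" error; empty panels are valid with a warning; empty
  event sets produce NaN-flagged window frequencies; zero-margin
  contingency tables are rejected.
* Determinism: every stochastic routine takes a seed or Generator;
  the pipeline derives per-stage seeds from one master seed via
  `SeedSequence`, and identical config + seed reproduce byte-identical
  stage outputs (checksummed in the run manifest).
* Problem sizes: the test suite and the acceptance script run the
  simulator round trip at 1,000 offspring on the full-density panel,
  the transmission-distortion comparison at 10⁴ meioses per arm, the
  caller–oracle equivalence over all 4,096 length-12 vectors, interval
  coverage at 2,000 replicates × 3 scenarios, and detection-power
  Monte Carlo at 2×10⁵ tracts — sizes at which every stochastic margin
  in the tests is several standard errors wide while the whole suite
  stays in the seconds-to-a-minute range.

## Known limitations

* Single-chromatid simulation with whole-meiosis redraw approximates
  within-meiosis chromatid redistribution; it reproduces the
  transmission-level signatures (no single intra-inversion COs;
  conversion enrichment) but not per-tetrad correlations.
* Uniform DSB placement ignores real intra-chromosomal rate variation
  (centromere/telomere effects enter only through the suppression
  ramps), so absolute simulated map lengths for the inversion
  chromosome run above the observed ones even though the distributional
  properties under study are preserved.
* NDJ genotype rendering is a caricature (random per-site collapse);
  it is adequate because NDJ offspring are excluded from event calling
  as soon as the Y-coverage detector flags them.
* The caller's minimum-evidence defaults are declared, configurable
  choices; single-site tracts are called but carry a `low_support` flag
  so downstream analyses can require independent confirmation.
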