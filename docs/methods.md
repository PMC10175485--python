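# Methods

`uvhotspot` implements the computational analysis of targeted UV-damage
sequencing (CPD-capture-seq): mapping cyclobutane pyrimidine dimers
(CPDs) at single-nucleotide resolution over a capture panel of genomic
regions, quantifying damage induction by bound transcription factors,
relating damage to recurrent somatic mutations in melanoma, and
separating recurrent *passenger* mutations (explained by locally
elevated damage) from *candidate drivers* (not explained by damage).
Because the real experiment requires sequencing data, a somatic-mutation
cohort and a reference genome, the package ships a first-class
synthetic-data generator whose defaults encode the study conditions, so
every stage is exercised and validated end to end without external
data.

## Lesion calling

CPD-seq-style libraries cleave at the dimer and ligate the adapter to
the free 3'-OH immediately 5' of the lesion, so sequencing starts next
to the lesion and reads away from it.  We therefore place the candidate
lesion dinucleotide on the strand opposite the read's mapped strand, on
the two genomic positions immediately past the read's 5' end: for a
'+' read with leftmost aligned coordinate `p`, positions `(p-2, p-1)`
on '-'; for a '-' read with rightmost coordinate `q`, positions
`(q+1, q+2)` on '+'.  The exact offset is inherited from the underlying
damage-sequencing chemistry and is kept as a single module constant
(`lesions.LESION_OFFSET`), so an alternative convention is a one-line
change.  A read is retained iff both candidate bases on the lesion
strand are pyrimidines; each retained read contributes one count to
*both* dipyrimidine positions.  Duplicate reads are kept; no
mapping-quality filtering is applied (alignment is out of scope — the
caller consumes aligned BED6).  Coordinates are 0-based half-open
internally and in BED/bedGraph; TSV reports are 1-based.

## Scaling, induction and the flanking null

The naked-DNA control (purified genomic DNA irradiated in vitro)
measures sequence-intrinsic photochemistry.  It is scaled by one global
factor so that its dipyrimidine-associated read total inside the
capture regions equals the cellular library's.  Induction at a position
is `cellular - scaled naked`; by construction induction sums to zero
over the panel, so concentrated positive induction at bound motifs is
balanced by a slightly negative flanking baseline.  The flanking null
(mean and SD of induction per CPD-forming position 6–180 bp from the
site midpoints, both sides, positions deduplicated) turns per-site
induction into Z-scores.  Per-site analyses exclude sites with low
capture efficiency, defined as a mean cellular lesion count per
flanking bp below 1; we read "lesion site per base pair" as read counts
per bp rather than distinct positions per bp, because the latter
saturates at 1.  The cluster-matrix ordering key is the summed
induction at motif offsets {-4, -3, -1, 0, +1}.

## ETS motif annotation

The scanner searches the fixed pentamers TTCCG and CTTCC on both
strands.  The site midpoint is the first C of the TTCC core on the
pyrimidine strand; with that convention the TC step is at offsets
-1/0, the CC step at 0/+1, and the damage-hypersensitive variant
dipyrimidine at -4/-3 (a site is *variant* when both -4 and -3 bases
are pyrimidines).  Matches of both pentamers around a single core
(CTTCCG) merge into one site; sites with an N anywhere in offsets
-4..+2 are dropped and tallied.  A mutation overlaps an ETS motif when
its position equals the midpoint plus one of {-4, -3, 0, +1}
(strand-aware); ties between equally distant sites resolve
deterministically ('+' pyrimidine strand first, then lower midpoint).
Position-weight-matrix scanning is deliberately out of scope; the motif
list is configurable.

## The damage→mutation regression

One observation per variant ETS site: `y` is the melanoma mutation sum
(tumor-count weighted) at the site's two -4/-3 positions, and the
covariates are the cellular and scaled-naked CPD sums at the same
positions (summing the covariates over the two positions mirrors the
summing of the response).  The model is Poisson with log link,

    log E[y] = b0 + b_cell * C + b_naked * N,

fitted by IRLS (statsmodels GLM) with Wald 95% CIs from observed
information.  The naked-only model is the null; the likelihood-ratio
test on 1 df asks whether cellular damage adds predictive value, and
McFadden's pseudo-R² (1 − ℓ_model/ℓ_intercept) summarises fit.  A
positive `b_cell` together with a negative `b_naked` is the regression
form of "induction predicts mutation".

## Trinucleotide enrichment, accessibility, rank tests

Expected mutation counts at query positions are built from
pyrimidine-strand-collapsed trinucleotide contexts (32 classes, the
standard mutation-signature convention): background rate = background
mutations in a context ÷ background occurrences, summed over query
positions; query positions are excluded from the background so the
statistic is an out-of-set enrichment.  Accessibility density per site
is the mean per-bp count within 50 bp of the midpoint per dataset,
summed over the three datasets, correlated with induction by Spearman's
rho with a Fisher-z 95% CI (SE = 1/sqrt(n−3)).  Group comparisons use
the two-tailed Mann-Whitney U: exact enumeration when nA+nB ≤ 20 and
tie-free, otherwise the normal approximation with mid-ranks, tie
correction and continuity correction.

## Hexamer screen

Each retained read contributes one count to the hexamer centred on its
lesion dinucleotide (2 nt 5' flank + dinucleotide + 2 nt 3' flank on
the lesion strand); lesions within 2 bp of a contig end lack a full
hexamer and are skipped.  Enrichment per hexamer is a two-sided test of
the cellular count against the scaled-naked-implied expectation (exact
binomial below 10⁴ reads, normal approximation above), BH-corrected
across hexamers; flags require q < 0.05 and |log2 ratio| ≥ 1.  The
thresholds are configurable — the screen is a discovery device, not a
calibrated test.

## Passenger-vs-driver classification

A mutation site is *elevated* when cellular ≥ 2 × scaled naked AND
cellular − scaled naked ≥ 50 reads, both inclusive ("at least"), read
at the single mutation base summed over strands (window configurable).
Elevated + ETS overlap → `likely_passenger`; not elevated →
`candidate_driver`; elevated without an ETS motif → `ambiguous` (a
state the analysis logic implies but rarely names).  Sites outside the
capture panel are reported as uncovered and excluded from summary
fractions.

## The synthetic-data generator

The generator emulates the capture experiment, not the sequencer: no
per-base read sequences, error models or alignment (non-goals), just
aligned read positions with the statistical structure the analysis
assumes.

* **Panel.** `n` regions of 720 bp (the capture-region size), one
  planted motif per region at the centre, strands alternating.  Background
  sequence is i.i.d. with GC fraction 0.45.  Planted ETS contexts carry
  purine separators so the motif's dipyrimidine steps are isolated from
  the random flanks; variant sites draw their -4/-3 dinucleotide from a
  mix (TC 0.35, TT 0.20, CC 0.20, CT 0.25) so naked-DNA covariates vary
  across sites as they do across real binding sites.
* **Reads.** Every dipyrimidine step receives a Poisson count with mean
  ∝ depth × class rate (TT 1.0, TC 0.5, CT 0.2, CC 0.3 — dominance
  ordering of CPD photochemistry) × a per-region capture-efficiency
  scalar (unit-mean lognormal, σ = 0.25, shared between matched
  libraries) × an induction factor applied only in the cellular
  library at bound sites (bound fraction 0.65, "two-thirds or fewer").
  Each lesion is emitted as one read whose 5' end sits exactly where
  the caller expects it, so `call_lesions` inverts the generator.  A
  no-UV library contains only uniform background reads
  (0.05 reads/bp), which also contaminate the UV libraries at the same
  low rate.
* **Calibration.** The induction factors and depth are calibration
  constants solved against the package's analytic expectation functions
  (`synthetic.pair_lambdas`, `expected_position_lambda`) so the default
  cohort reproduces the observed aggregate behaviour: -4/-3 pair ×16.6,
  CT(-3/-2) ×0.3, TT(-2/-1) ×0.05, TC(-1/0) ×2.6, CC(0/+1) ×1.15, and
  16,650 expected naked dipyrimidine reads per region.  These jointly
  yield a ~7-fold cellular:scaled-naked ratio at -4/-3, a ~4-fold
  -4/-3 : -1/0 cellular ratio, and a flanking induction mean near
  -1.5 reads/position.  The strong TT/TC-step suppression inside the
  core is a modelling device for those aggregate ratios; the real
  profile's step-level detail is not claimed.
* **Mutations.** Per variant site, the -4/-3 mutation sum is Poisson
  with log-rate `b0 + 0.001182·C − 0.01532·N` (the published
  coefficients); `b0 = 2.0` puts per-site counts in the single digits
  at the calibrated depth.  Background mutations scatter over all other
  positions with C>T-dominant trinucleotide weights at intensity
  0.0925 per weight unit, calibrated so the variant-site -4/-3
  positions are ~60-fold enriched over the context expectation.
* **Accessibility.** Per-site densities come from a Gaussian rank
  copula anchored on measured per-site induction, with the copula
  correlation 2·sin(π·ρs/6) chosen so the *population* Spearman
  correlation equals the target (default 0.41).  Three replicate tracks
  with fixed relative depths (0.45/0.35/0.20) spread each density
  uniformly over ±50 bp, so the pipeline's summed within-window means
  reconstruct it.

What the generator does **not** emulate: linked read pairs, PCR
duplicates, mappability, probe-level capture chemistry (only a
per-region scalar), CC→TT tandem mutations, strand asymmetry of repair,
or inter-site sequence correlation.  Passing tests therefore show that
the *analysis* is correct and internally calibrated, not that these
real-data complications are handled.

## Numerical and design choices

* Dense per-contig track arrays (capture panels are a few Mbp; every
  window operation becomes a vectorised gather).
* GLM convergence: IRLS, tolerance 1e-10, 100 iterations;
  non-convergence raises (no silent partial fits).  All-zero responses
  and <3 sites are rejected.
* Flank null requires ≥100 CPD-forming positions and positive variance.
* The flank null defaults to variant-site flanks; any site set can be
  passed (the panel-wide null gives similar values by construction).
* `simulate_dnase` refuses fewer than 10 sites (a rank correlation on
  fewer is noise).
* Seed fan-out: one global seed derives independent per-stage streams
  by a stable label hash, so adding a stage never perturbs existing
  streams; everything is reproducible byte-for-byte from one integer.
* Recovery experiments (`uvhotspot.experiments`) use 100 replicate
  300-site cohorts for the regression, 5 cohorts for the aggregate
  statistics, and 200 accessibility replicates on one 324-site cohort —
  sizes chosen to estimate medians and CI-coverage rates stably.

## Known limitations

* The elevated-CPD rule reads counts at a 1 bp window by default; real
  analyses may prefer a small window around the mutation base
  (configurable, results at hotspot sites are insensitive).
* The hexamer screen's significance machinery assumes independent
  counts; overlapping occurrences of a hexamer are rare but not
  impossible in repetitive sequence.
* Fixed-string motif scanning misses degenerate ETS cores by design;
  supply a custom pentamer list for a broader scan.
* With real data (aligned BED from a capture experiment, a recurrent-
  mutation catalog and a reference FASTA) the same pipeline applies
  unchanged via the `paths:` block of the config; the synthetic
  calibration constants then play no role.
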