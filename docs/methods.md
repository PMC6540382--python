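# Methods

## The processing model

A spontaneous report is (identifier, year, vaccines, symptoms), where both
the vaccine and the symptom field are multi-valued as filed.  The pipeline
makes three modelling commitments:

1. **Neighboring counting.**  Because a multi-listed report cannot
   attribute symptoms to vaccines, every listed symptom is counted once
   under every listed vaccine.  There is deliberately no attribution model
   and no per-report weight normalization: a 2-vaccine × 3-symptom report
   contributes mass 6.  Vaccines and symptoms repeated *within* one report
   count once (configurable via `expand_report(dedupe=False)`); symptom
   terms are trimmed and case-folded before any matching or counting, with
   no spelling correction or ontology mapping — terms are treated as given
   nominal categories.

2. **Counts, not rates.**  A missing (year, vaccine, symptom) cell is a
   true zero (zero reports listed the pair), not missing data.  No
   denominators (doses administered) enter anywhere; all statements are
   about reporting counts.

3. **Correlation across nominal categories.**  All structure is captured
   by sample Pearson correlations between count columns — across vaccine
   rows (which symptoms co-vary over vaccines) or across year rows (which
   (vaccine, symptom) pairs co-vary over time).  The year-stratified matrix
   is organized vaccine-major, so it decomposes into vaccine-pair blocks
   M_ij with M_ijᵀ = M_ji exactly.

### Choices where the procedure was open

* **Year definition.**  The canonical reader takes the year column as
  given; the surveillance-triplet adapter uses the receipt date by default
  (reports are counted by filing year), configurable to the vaccination
  date.
* **Ranking population.**  Symptom frequencies FQ are computed on
  unknown-vaccine-excluded records by default, matching the population
  used by the year-stratified analysis; the all-events constructions keep
  the unknown sentinel as the last vaccine row.
* **Ties.**  Equal frequencies rank alphabetically; determinism over any
  claim about real tie behaviour.
* **Malformed rows** are skipped and tallied in a read summary, never
  fatal: spontaneous-report data contain erroneous and incomplete records,
  and a reader that aborts on them is useless in practice.

## Numerical choices

* **Correlation core.**  Columns are centered and scaled by their root
  sum of squares; the Gram product of the standardized matrix is averaged
  with its transpose (exact symmetry despite BLAS rounding), clipped to
  [−1, 1], and the diagonal of defined columns set to exactly 1.  Columns
  with zero variance have undefined correlations: they are stored as 0 and
  flagged in `defined_mask` (including their diagonal), so classification
  and rendering can distinguish "no information" from "uncorrelated".  The
  7368² all-events case is dense float64 (~0.4 GB) and computes in seconds.
* **Entry classification.**  `classify_entry` partitions [−1, 1] exactly:
  positive above t, negative below −t, negligible in between with the
  boundary |ρ| = t negligible.  The default t = 0.01 is the display-map
  convention (red/white/blue pixel maps).
* **Inference threshold.**  For *labelling* blocks on the year-stratified
  matrix, 0.01 is far below the sampling noise: with n = 24 year rows the
  sample correlation of two independent columns has standard deviation
  ≈ 1/√23 ≈ 0.21, so a truly uncorrelated block would still show ~96 % of
  entries outside ±0.01.  `patterns.significance_threshold(n)` therefore
  returns the two-sided 5 % critical value of Pearson's r
  (r = t₀.₉₇₅/√(df + t₀.₉₇₅²), df = n − 2; 0.404 at n = 24), and the
  pipeline uses it as the default block-labelling threshold.  The display
  threshold remains available by passing `t=0.01`.
* **Block labels.**  Fractions are computed over defined entries only,
  excluding the unit diagonal for self-blocks.  The dominance default
  τ = 0.5 is the weakest reading of "mostly"; because the claim of
  interest for bacteria blocks is compound ("uncorrelated *or* negatively
  correlated"), the profile also reports f_zero + f_neg.
* **Binned rendering.**  20 equal-width bins over [−1, 1] on a
  green-centered diverging palette, linearly interpolated from green at 0
  toward red (+) and blue (−), with the extreme bins fully saturated.
  With an even bin count, "around 0" spans the two central bins (|ρ| ≤ 0.1).
  Undefined entries render white in both modes.  Rendering is a pure
  function of (matrix, spec): byte-identical PNGs across runs.

## The synthetic-report generator

The generator supplies the study conditions: a 24-year stream of ~50,000
reports (Poisson volumes around 2,100/year) over a 200-term symptom
vocabulary and the full 72-vaccine taxonomy.  What it emulates:

* **Multi-listing.**  Each report lists a primary vaccine plus
  Geometric(p=0.77)−1 co-administered extras (mean 0.3, so ~1.3 vaccines
  per report), and min(Geometric(0.5), 10) background symptoms plus
  Poisson(1) draws from a co-reporting cluster (~3 symptoms per report).
  2 % of reports carry the unknown-vaccine sentinel.
* **Heavy-tailed symptom popularity.**  Symptoms follow a Zipf law with
  exponent 0.8, the decay matching a frequency ratio of ~36 between ranks
  1 and 100 as seen in real top-100 frequency tables.  Seven non-adverse
  administrative terms sit at head ranks (3, 8, 14, 21, 27, 34, 40); after
  the cluster boost of adverse terms they realize inside the top ~90, so
  the top-100 adverse selection consumes a ranking head of exactly 107.
* **Taxonomy.**  24 bacteria, 38 virus and 9 combined codes
  (alphabetical within class) plus `UNK`; 23 live / 47 inactivated / 1
  unclassified attenuation.  The curated code lists put MNQ 16th and PPV
  21st among bacteria and the four flu vaccines 3rd–6th among virus codes,
  reproducing the reference geometry.
* **Planted year factors.**  Every vaccine has a mean-one yearly intensity
  trajectory that multiplies its Poisson report volume (and hence every
  one of its count cells).  The trajectory's *values* are the quantile
  template of a log-normal with log-sd 1.5 — a design constant, so the
  planted relative amplitude is identical in every run — and only their
  assignment to years is random (one independent permutation per latent
  group).  All virus vaccines share one trajectory; every bacteria and
  combined vaccine gets its own.  Co-administered extras are drawn with
  the same year-modulated weights, so co-listings track what is actually
  being administered in a given year.  The amplitude mirrors real
  surveillance streams, where epidemic seasons and schedule introductions
  or withdrawals swing a vaccine's yearly report count by an order of
  magnitude or more.  With `anomaly=True` the bacteria pair MNQ/PPV is
  wired to the virus trajectory, planting one anomalous positive bacteria
  block (and positive MNQ×virus blocks, the analogue of a bacteria vaccine
  behaving like the virus class).
* **Expected structure.**  `expected_structure(config)` returns the truth
  table the pipeline should recover — virus×virus `mostly_positive`, all
  other class pairs `mostly_uncorrelated`, the anomaly pair
  `mostly_positive` — together with the significance threshold appropriate
  for the configured number of year rows.  With zero factor amplitude
  nothing is planted and all pairs are expected uncorrelated.

What the generator does **not** emulate: secular growth of reporting
volume, age/sex/onset covariates, MedDRA coding eras or term drift,
vaccine-specific symptom profiles beyond the shared cluster, and any
numerical agreement with a real database.  Passing tests therefore show
that the pipeline recovers the structural features above at realistic
scale and noise — not that any particular real-world correlation is
reproduced.

Two estimator-level facts matter when interpreting results at this scale
and are verified by the test suite rather than assumed:

* with 24 observations, only |ρ̂| above ≈ 0.4 is distinguishable from
  noise at the 5 % level, which is why block recovery is evaluated at the
  significance threshold;
* the sample correlation of near-empty count columns is mean-zero but
  median-negative (skewed), so the zero-signal symmetry of positive vs
  negative shares at ±0.01 is evaluated on the dense head of the ranking,
  where cells are well populated.

## Problem sizes used by the checks

The default synthetic study (~50,000 reports, 200 symptoms, 72 vaccines)
drives the full pipeline in a few seconds.  The paper-scale all-events
geometry (7368 symptoms over 72 vaccines) is exercised with a sparser
stream (~12,000 reports over the full vocabulary); unobserved symptoms
yield masked zero-variance columns, and the 7368×7368 matrix is still
computed densely.  These sizes were chosen so the whole validation cycle
runs comfortably on a laptop-class single CPU.

## Known limitations

* Correlation across 24 year rows is a coarse instrument: it detects
  shared temporal profiles, not causal or mechanistic association, and a
  strong shared secular trend would color every block positive.
* The neighboring method deliberately spreads counts across co-listed
  vaccines; a vaccine frequently co-administered with a reactogenic one
  inherits part of its signal.  This is a property of the method, not a
  bug of the implementation.
* No shrinkage or multiple-testing machinery is applied to the
  correlation matrices; the block statistics are descriptive, and the
  significance threshold is used for labelling, not for formal inference
  over 25 million entries.
* The surveillance-triplet reader maps the public column layout but is
  validated only against synthetic fixtures.
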