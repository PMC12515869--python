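# Methods

## The quantification model

A modification-site intensity in a label-free experiment is, to first
order, multiplicative:

    I_site(i, j) = loading(j) · protein(p(i), j) · stoichiometry(i, j) · ε

where `j` indexes samples, `p(i)` is the parent protein of site `i`,
`loading(j)` is the per-sample amount of material and `ε` is log-normal
measurement noise. The quantity of biological interest is the
stoichiometry — the fraction of the protein carrying the modification. The
pipeline isolates it in three multiplicative steps:

1. **Median normalization.** Each sample column is rescaled so its median
   (over present values) equals the median-of-medians. Factors for the
   site table are derived from the *protein* table: the global proteome's
   medians estimate `loading(j)` robustly, whereas the modified-peptide
   table's own medians are biased whenever true modification changes are
   one-directional (with 10% up-spikes at FC 2 the self-normalized site
   table shrinks every fold change by ~13%). Because the same factors are
   applied to both tables, they cancel exactly in step 3; the corrected
   output is therefore invariant to any per-sample scaling of the inputs.
2. **Centering.** Each feature row is divided by the mean of its present
   values, giving relative quantifications with row mean 1 (an invariant
   the test suite asserts after every stage). Division — not
   subtraction — keeps values positive so the downstream fold change
   remains a ratio.
3. **Protein correction.** Each site's relative value is divided by its
   parent protein's relative value, sample by sample; `protein(p, j)`
   cancels. Cells missing in either operand stay missing; sites without a
   quantified parent protein ("orphans") are dropped with a logged count
   rather than passed through uncorrected. Rows are re-centered afterwards.

The order of centering and division is arbitrary for fold-change purposes
(both compose to the same group-mean ratio up to a row constant); the
implemented order — center both tables, then divide, then re-center — is
the documented convention.

## Differential testing

Fold change is the ratio of group means of the corrected values on the
linear scale; testing happens on log2 values, which the multiplicative
model renders approximately normal. Per feature:

* **Assumption gate.** Shapiro–Wilk on each group's log2 values and
  Brown–Forsythe (median-centred Levene) across groups, each at
  `gate_alpha = 0.05`. Student's t-test is used only when all three pass;
  otherwise Welch's. With `n = 3` the gate has little power and mostly
  selects Student's test; with 2 present values Shapiro–Wilk is undefined
  and is treated as non-rejecting. Under the null the three 5%-level gates
  select Student's test ~86% of the time (≈ 0.95³) — a property the test
  suite checks by simulation.
* **Degenerate inputs.** Features with fewer than `min_per_group = 2`
  present values in a group, or with exactly constant values in both
  groups, are reported `untestable` with `p = 1` instead of being dropped,
  so the output has one row per corrected site.
* **Multiplicity.** Benjamini–Hochberg q-values are reported for every
  feature; significance *calls* use the raw `p < 0.05` together with the
  fold-change window `FC > 1.5` or `FC < 1/1.5` (thresholds exclusive),
  mirroring how such studies phrase their cutoffs while still publishing
  q-values.

The stage is exposed as `DifferentialModel` (data + thresholds) whose
`fit()` returns `DifferentialResults` (per-feature table, gate reports,
summary counts, volcano plot). Swapping the group labels maps `FC → 1/FC`,
leaves p-values unchanged and exchanges up/down calls — asserted as a
property test.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* the analysis assumes, at the scale
of the motivating study: a 3-vs-3 design; ~48% of a 1,000-protein proteome
modified (~477 proteins, ~1,900 sites); a truncated-Zipf sites-per-protein
law whose exponent is calibrated so the expected single-site fraction
matches the 44% target, with truncation at each protein's lysine count so
only lysine-rich (long) proteins carry large counts; log-normal protein
abundances (ln-sd 1.2) with per-sample scaling (ln-sd 0.25) and residual
noise (ln-sd 0.15); site stoichiometries uniform on (0.05, 0.5), which
cancel in the correction; spiked fold changes of 2.0 on 10% of sites and,
independently, on 10% of proteins; and 5% missing values, completely at
random by default (an intensity-dependent MNAR option exists but is off —
the missing-data structure of real tables is rarely known). Sites inherit
their parent protein's *realized* per-sample intensity, so the correction
cancels protein-level variation exactly; the site-level noise term is what
remains.

Defaults were chosen once from the study conditions or, where no value is
stated (dispersion, missingness), at conventional magnitudes for label-free
tissue data.

What passing the synthetic benchmark does **not** show: real acquisitions
have peptide-level effects (digestion, ionization), intensity-dependent
missingness, correlated noise across sites of one protein, batch structure,
and protein inference ambiguity — none of which are simulated. Recovery
rates measured here (sensitivity ≈ 0.8, FDP ≤ 0.01 at the default
conditions) are an upper bound on real-data performance, not an estimate of
it.

## Motif analysis

Foreground windows are the 21-mer flanks of modified lysines ('_'-padded at
termini); the background is every lysine-centred 21-mer of the proteome
(matching the central residue, the motif-x convention, rather than bulk
composition). Per (position, residue) cell the enrichment p is the exact
binomial upper tail of the foreground count at the background frequency;
ratios add a pseudo-frequency of 0.5/n on both sides so empty background
cells stay finite (p-values use raw counts; an empty background cell with
foreground hits substitutes 0.5/n_bg and is flagged). The iterative search
greedily fixes the smallest-p cell when `p < 1e-6` and at least 20
foreground windows support it (published motif-x defaults), restricts both
window sets to matches, recurses to depth 5, then removes the motif's
matches and restarts. Ties break lexicographically; padding never matches.

## Network clustering

MCODE as published: vertex weight = core order × density of the highest
k-core of the closed neighbourhood; seeds processed in descending weight;
breadth-first expansion includes unvisited neighbours whose weight is at
least `(1 − node_score_cutoff)` × seed weight (default cutoff 0.2, depth
limit 100); candidates without a 2-core are dropped; haircut (on by
default) removes singly-connected members, and nodes it shaves off return
to the available pool; fluff (off by default) adds boundary neighbours with
closed-neighbourhood density above 0.8. Cluster score = induced density ×
size. Two caveats the test suite documents rather than hides: the weight is
not edge-monotone (an added edge can dilute the top core), and expansion
crosses direct bridge edges between equally-weighted dense regions, merging
them — the algorithm separates planted blocks cleanly only when bridges are
absent or pass through low-weight nodes.

## Enrichment

ORA uses the exact hypergeometric upper tail of the hit/set overlap within
the supplied universe, BH-adjusted across sets. Preranked GSEA implements
the weighted Kolmogorov–Smirnov running sum (hits add `|metric|^1`
normalized by the hit total, misses subtract `1/(N − N_hits)`), with a
*gene-label* permutation null — random same-size id sets — rather than
phenotype permutation, which is unavailable for a preranked list. NES
divides ES by the mean |null ES| of matching sign; p is the matching-sign
permutation tail with floor `1/(B + 1)`; FDR follows the standard pooled
positive/negative NES procedure. Rank ties break by id so results are
deterministic at a fixed seed. The pipeline ranks proteins by the
largest-magnitude site log2FC (the ranking metric is a user choice; this
default favours proteins with any strongly changed site).

## Numerical conventions

* Missing values are propagated, never imputed.
* TSV with '#' metadata headers, UTF-8, '.' decimal, empty cell = missing
  ("NA" accepted on read); floats written at %.6g so reruns are
  byte-identical.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and the permutation test are pure functions of their arguments
  including the seed.
* Ranking ties (top proteins, MCODE clusters, motif cells, GSEA ranks)
  break lexicographically.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at: 400–1,200
proteins (≈ 850–2,500 sites) for recovery and calibration runs, 60-node
planted-partition graphs for clustering, 200/600 windows for motif
searches, and 1,000-gene ranked lists with 200 permutations for GSEA —
sizes at which every check completes in seconds while keeping the
statistical targets (type-I rate, sensitivity bands, permutation floors)
well resolved.

## Known limitations

* The assumption gate is nearly powerless at n = 3; it exists to mirror
  the analysis convention, not to guarantee normality.
* Calls use raw p with an FC window; q-values are reported but not used
  for calling, so the published-style call counts do not control FDR.
* MCODE cluster memberships on dense graphs depend on the documented
  bleeding behaviour; STRING-style confidence filtering is the caller's
  responsibility (`--min-score`).
* The GSEA FDR is the permutation-pooled estimate, which is conservative
  for small set collections.
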