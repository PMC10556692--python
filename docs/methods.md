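# Methods

## Pipeline overview

Input is a spot-level intensity table (one row per printed spot: slide,
protein, replicate index 1–4, foreground/background median RFU, control
flag) plus a manifest assigning each slide — one serum sample per slide —
to the case or control group. Processing stages:

1. **Replicate collapse.** Each protein is printed in quadruplicate per
   slide; replicates are collapsed to their median (for four values, the
   mean of the two middle order statistics). Background medians are
   collapsed the same way before subtraction, mirroring the foreground
   treatment.
2. **Background subtraction.** Collapsed background is subtracted from
   collapsed foreground, floored at 1.0 RFU so that downstream ratios and
   logarithms are always defined. The floor only engages for spots whose
   signal is at or below local background, where the measurement is
   effectively "no reactivity" anyway.
3. **Positive-control inspection.** Per slide, the median intensity of the
   spotted-IgG controls (reports secondary-antibody labelling) and of the
   Cy3-BSA controls (reports scanner response) is compared with thresholds
   (default 5,000 RFU each — a config value, since acceptable control
   levels are platform-specific). A failing slide is flagged, not dropped;
   exclusion is an explicit user decision.
4. **CV% summaries.** Replicate variation is reported as coefficients of
   variation (sample SD, n−1, over mean; a zero mean defines CV = 0) at
   three levels: per protein within a slide, averaged per slide, and per
   protein across slides on the background-subtracted values.
5. **Quantile normalization, controls excluded.** Control spots measure
   assay chemistry, not serum reactivity, so they are removed before the
   target distribution is computed and stay excluded from all statistics.
   Each sample column is mapped onto the rank-wise mean of the sorted
   columns; ties within a column receive the average of the rank-means
   their block spans (midrank convention). With tie-free columns this makes
   every sample's value multiset identical and the map idempotent; tied
   blocks relax that identity slightly, which the test suite acknowledges
   by asserting the distribution-identity properties on tie-free inputs.
   No log transform is applied before normalization.

## The penetrance fold-change statistic

For protein *p* with normalized values X[p, s]: m_p is the mean over all
samples and h[p, s] = X[p, s] / m_p, so mean(h) = 1 per protein by
construction. A sample is *penetrant* when h ≥ θ. Group penetrance
frequencies are the percent of each group's samples that are penetrant
(inclusive comparison). H̄_group is the mean of h over the group's
penetrant samples; when a group has none, it falls back to the mean over
all of the group's samples, which keeps PFC_case = H̄_case / H̄_control
finite and makes the statistic antisymmetric under swapping group labels.
PFC_control is the exact reciprocal of PFC_case, so their product is 1 and
the ranking statistic, the difference PFC_case − PFC_control, is a strictly
increasing function of PFC_case. The overall fold change is the plain ratio
of group means, and the p-value comes from a two-sided pooled-variance
Student t-test on the normalized values (equivalent to a t-test on h, since
m_p is a common factor). Zero pooled variance with equal means yields
t = 0, p = 1; with unequal means the row is flagged degenerate with p = 0.

### Classification rules

Increased: p < α AND PFC difference ≥ 2 AND frequency differential ≥ 1
percentage point AND Frequency_case ≥ 10%. Decreased mirrors this with the
control group enriched. All boundary comparisons are inclusive. Design
choices worth noting, each configurable:

- **θ = 2.0.** The penetrance cutoff is not a community standard; 2× the
  cohort mean is the natural "clearly reactive" scale for fold-change data
  and is reported in the run metadata.
- **Frequency differential in percentage points** (case% − control%),
  threshold 1 pp; a ratio convention (case%/control% ≥ cut) is selectable
  via `frequency_diff_as_ratio` since a unitless threshold of 1 is
  ambiguous between the two readings.
- **Minimum-frequency rule applied to the enriched group** (cases for
  increased, controls for decreased). Requiring *both* groups to reach 10%
  penetrance would exclude exactly the cleanest markers — those absent in
  one group — so the directional reading is used.
- **No multiple-testing correction in the classifier** (raw p < 0.05, as
  is common in discovery-stage seroreactivity screens); a
  Benjamini–Hochberg column is emitted alongside for the reader but never
  drives classification.
- A volcano-style screen (|log2 overall FC| ≥ 0.58, i.e. 1.5-fold,
  inclusive) is computed independently of the classifier; the two screens
  answer different questions and neither implies the other.

## Exact association tests

IHC panels of ~25 cases are far too small for chi-square asymptotics, so
associations between staining positivity (positive when > 5% of cells
stain) and categorical clinicopathological parameters are tested exactly.
For 2×2 tables the null distribution of the top-left cell given fixed
margins is hypergeometric (scipy supplies the pmf); the two-sided p sums
the probabilities of all tables no more likely than the observed one
(probability ordering, as in R's `fisher.test`), with a relative tolerance
of 1e-7 on the ≤ comparison to absorb floating-point ties; one-sided tails
are the usual cdf/sf. For r×2 tables the Freeman–Halton extension
enumerates all column-1 count vectors compatible with the margins
(depth-first with feasibility bounds), scores each table with the
multivariate hypergeometric probability computed in log space (log-gamma),
and sums those within the same tolerance of the observed probability. The
enumeration refuses tables whose bound exceeds a configurable budget
(default 10⁷) rather than stalling. Sidedness is an explicit argument
because published panels do not always follow one convention: a left-tail
reading can match a printed value that the two-sided convention does not.
For r = 2 the Freeman–Halton path reproduces the two-sided Fisher p
exactly, which the test suite checks on 200 random tables.

## Synthetic cohorts

The generator emulates the structure the analysis assumes — it is the
package's ground-truth instrument, not a model of any particular scanner.
Defaults: 20 cases vs 20 controls, 1,631 non-control proteins in
quadruplicate, two positive-control species (IgG at 40,000 RFU, Cy3-BSA at
25,000 RFU). Signal is multiplicative log-normal: per-protein baseline
LogNormal(ln 500, 0.8) spanning roughly 50–5,000 RFU as scanner data do;
per-sample scale factor LogNormal(0, 0.2), the ±20% loading/labelling
spread that quantile normalization exists to remove; replicate spot noise
with σ chosen so the replicate CV is 0.08 (typical of a well-behaved
quadruplicate array); background LogNormal(ln 80, 0.3). Planted markers
multiply the signal by `effect` (default ×4) in a randomly chosen
`penetrance` fraction (default 0.5) of the enriched group — cases for "up"
markers, controls for "down" — which is precisely the subset-reactivity
pattern the penetrance statistic targets.

Randomness flows from one root seed through per-protein
`SeedSequence(seed, spawn_key=...)` substreams, so adding proteins never
reshuffles existing proteins' draws and a fixed config is byte-reproducible
through the text writers (6-significant-digit serialization).

What the generator does **not** emulate: spatial slide artifacts, spot
morphology, isotype cross-reactivity, batch effects beyond a scalar
per-sample factor, and any dependence structure between proteins. Passing
recovery tests therefore show the statistic detects planted subset
reactivity under realistic noise magnitudes — not that it is robust to
every failure mode of real arrays.

## Validation studies and problem sizes

- **Null calibration:** 2,000 proteins, 20 vs 20, nothing planted. The
  fraction of proteins with p < 0.05 should sit near α (the t-test is
  well calibrated for log-normal-ish data at n = 40), and the classifier —
  which stacks three further screens on top of the t-test — should call
  no more than that fraction. Observed at seed 1: 0.054 significant,
  0.0005 classified.
- **Recovery:** the default cohort with 50 up + 50 down markers planted.
  With a ×4 effect at 50% penetrance the affected samples sit at
  h ≈ 4/1.75 ≈ 2.3, comfortably above θ = 2, so sensitivity is expected to
  be high; observed at seed 1: 100% of planted-up recovered, 98% of
  planted-down, with 0.07% false discoveries among nulls.
- **Desk checks:** two 4-vs-4 fixtures small enough to verify every
  quantity by hand (PFC_case 4.0, PFC difference 3.75, overall FC 2.5 and
  3.0, t = 1.7321 and 3.4641), and a brute-force plain-Python oracle the
  vectorized implementation must match on random matrices.

These sizes keep the full suite and the acceptance script each within a
few seconds while leaving the studies statistically meaningful (binomial
SE on the null fraction at 2,000 proteins is ≈ 0.5 pp).

## Known limitations

- The penetrance statistic has no closed-form null distribution here; the
  p-value gatekeeping comes from the t-test alone, and the PFC thresholds
  are screens, not calibrated tests.
- Quantile normalization assumes most proteins are non-differential;
  cohorts where a large fraction of the proteome shifts would violate it.
- The Freeman–Halton enumeration is exact but exponential in rows; large
  sparse tables need a Monte Carlo p-value, which is not implemented.
- PCA/k-means summaries use log2 intensities with a fixed sign and seed
  convention for determinism; they are descriptive, not inferential.
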