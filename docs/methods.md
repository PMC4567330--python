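# Methods

This note documents the models and procedures implemented in `cnamcr`,
the defaults chosen where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations. No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All genomic intervals are 0-based, half-open (BED convention). An array
platform is an ordered probe set (`ProbeDesign`); a sample's measurement is
a vector of log2 tumor/normal intensity ratios aligned to it
(`ArrayProfile`). Sex chromosomes are excluded from synthetic genomes:
the frequency analyses the package supports are autosome-focused, and a
mixed-ploidy baseline would complicate the copy-neutral-at-zero convention
without adding coverage.

## Normalization

Three stages, in the order a two-channel workflow applies them:

1. **Within-array lowess** (`lowess_correct`): the locally weighted
   regression of log2 ratio on the intensity covariate (log10 channel
   intensity) is subtracted, after removing the fitted curve's mean so the
   stage never changes the array's global level. Span default 0.3 (a
   conventional two-channel choice; the smoother tolerance of ±0.05 on a
   planted quadratic in the tests reflects this span). Inputs without an
   intensity covariate skip the stage by flag.
2. **Between-array quantile normalization** (`quantile_normalize`), per
   platform: each array's sorted values are replaced by the across-array
   arithmetic mean of order statistics; ties share the average target via
   average ranks. Quantile normalization of log-ratio profiles is
   rank-based and therefore *attenuates* aberration amplitudes when the
   aberrant genome fraction is large or cohorts are small — on the
   desk-scale synthetic genome this visibly shrinks planted amplitudes.
   This is a property of the method, not a defect of the implementation;
   amplitude-class analyses are most reliable on segmentations performed
   without it (the validation experiments segment un-quantiled profiles).
3. **Centralization** (`centralize`): the mode of a Gaussian KDE of the
   ratios (Silverman bandwidth by default) is subtracted, putting the
   modal, copy-neutral state at log2 = 0. Candidate modes are the local
   maxima of the density; near-ties (within 2% of the peak density) are
   broken toward the mode nearer 0 with a warning, so a heavily aberrant
   chromosome arm cannot silently re-center the array on an aberrant
   state. The subtracted offset is recorded.

**Noise estimation** (`estimate_probe_noise`): the derivative log-ratio
spread, σ = 1.4826 · MAD(d) / √2 with d the successive probe differences
taken within chromosomes, floored at 1e−6. It is robust to a small
fraction of true copy-number steps (each step contributes two outlier
differences) and underlies the interval score.

## Segmentation

The interval score of probes [i, j] is |Σ r_k/σ| / √(j−i+1): the
noise-standardized mean scaled by the square root of the probe count, the
form used by interval-scoring aberration detectors. A single per-array σ
replaces the vendor's proprietary per-probe error model — a documented,
reproducible substitution.

Extraction is greedy and recursive per chromosome: find the maximum-score
interval; if its score reaches the threshold (default 6.0), emit it and
recurse on both flanks. Ties on score break leftmost-then-shortest.
Gains and losses are handled symmetrically through the signed sum.

- **exact mode** evaluates all O(n²) intervals with vectorized prefix
  sums (the default; ~25 ms at n = 3,300).
- **fast mode** scans a multi-resolution candidate family (geometric
  lengths, half-overlapping starts), then polishes the strongest
  candidates by an exact search in a window of ±2–3 scale steps. It is a
  heuristic intended for very long chromosomes; the test suite verifies
  agreement with exact mode on random profiles with planted signals.

**Fuzzy-zero filter**: each segment is re-tested with quality
|mean|/√(σ²/n + ν²) against the same threshold. ν inflates the variance
floor so very long, faint segments (whose nominal score grows as √n) are
suppressed. The pipeline defaults ν to the robust SD of the per-array
centralization offsets across the cohort — the natural scale of baseline
uncertainty; ν = 0 disables the filter. Housed as a segment filter, not a
probe correction, because it acts on segment significance.

**Call filters** (all inclusive, matching their stated "≥" forms):
≥3 probes, |mean log2| ≥ 0.25; |mean log2| ≥ 0.8 labels the call
amplification (gain side) or deletion (loss side).

## Common aberrations (context correction)

The "context" of sample s is its genome-wide direction-specific aberrant
probe fraction g_s. Under the null that samples aberrate probes
independently with their own g_s, the carrier count at a probe follows the
Poisson-binomial distribution with parameters (g_1…g_S), computed exactly
by sequential convolution (O(S²) once per direction). A probe is
significant when the upper tail P(K ≥ K_j) < α (default 0.05, no
multiple-testing correction by default, mirroring the raw-p reporting
convention; a Benjamini–Hochberg option would be a one-line addition to
the caller). Maximal significant runs become candidates; samples join as
members only when one of their calls has reciprocal overlap ≥ 0.9 with
the candidate, and candidates need ≥2 members. Vendor implementations of
context correction are undocumented; only the thresholds (0.05, 0.9) are
taken as given, and the operationalization of "context" as the marginal
aberrant fraction is this package's documented choice.

## CNAR / MCR region algebra

Reciprocal overlap of intervals A, B = min(|A∩B|/|A|, |A∩B|/|B|).

- **CNAR**: connected components (transitive closure) of same-direction
  calls under the relation "reciprocal overlap *strictly greater* than
  0.9"; components need ≥2 distinct samples; the CNAR interval is the
  union hull. Transitive closure is used because pairwise grouping of
  more than two segments is otherwise ill-defined and order-dependent.
- **MCR**: cross-platform CNARs of the same direction are grouped by any
  positive overlap (transitively); groups present on *all* required
  platforms yield an MCR equal to the intersection of every member
  segment ("100% overlapping common region"); empty intersections are
  dropped. Segment-wise intersection (rather than probe-wise) is the
  implemented reading; both conventions coincide when probes tile the
  segments. MCR frequency counts distinct samples whose call fully covers
  the MCR against the full cohort; a per-platform breakdown is also
  emitted because per-platform denominators are a plausible alternative
  convention.
- **Recurrence**: >20% (strict) for the main recurrent-region table,
  ≥10% (inclusive) for the amplification/deletion table — the two filter
  forms are kept distinct because their stated inequalities differ.

## MLPA

Each probe's peak height is divided by the sample's mean control-probe
height (removing input-DNA and amplification scale), then by the median of
the same quantity across a reference population of normal-tissue profiles.
Ratios < 0.75 call deletion, > 1.25 amplification; the closed interval
[0.75, 1.25] is normal (the abnormal classes are stated strictly, so
boundary values fall to normal). The exact vendor normalization is not
public; the control-probe/median scheme is a documented stand-in with the
required invariances (global per-sample scaling cancels exactly).

## Expression and clinical statistics

- Fold change by ΔΔCt with efficiency 2.0: FC = 2^−ΔΔCt, ΔΔCt =
  (Ct_g,T − Ct_ref,T) − (Ct_g,N − Ct_ref,N).
- Direction labels: two-sided one-sample t-test of log2 FC against 0
  (performed on the log2 scale); Up/Down at p < 0.05, else "-". Strata
  with n < 2 report missing p. Zero-variance nonzero-mean samples take
  the degenerate p = 0 with a warning.
- 2×2 association: Pearson chi-square with continuity correction when all
  expected counts ≥ 5, else two-sided Fisher exact. Mixed-type samples
  are excluded from diffuse-vs-intestinal tables (they belong to neither
  margin).
- Bonferroni: p × number of tested genes, capped at 1.
- Clustering: agglomerative, Euclidean distance, average linkage (an
  unspecified choice fixed here and exposed as parameters); rows sorted
  by sample id before linkage for order invariance; missing values
  imputed as 0 (copy-neutral) with a flag; k-cluster cut on request.
- Survival: Kaplan–Meier product-limit curves and the standard 1-df
  log-rank test (via lifelines); all-censored inputs report a missing p.
- Platform comparison: loss calls binned by size (1–5, 5–10, 10–50,
  50–100, ≥100 kb) and cross-tabulated platform-group × in-bin/not-in-bin
  with the same chi-square/Fisher switch.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-platform aCGH study:

- three platform densities over a 3 × 10 Mb autosomal mini-genome
  (10,000 / 5,000 / 1,500 probes by default — desk-scale stand-ins for
  400K/244K/60K arrays);
- a catalog of planted gain/loss events with per-Lauren-type carrier
  probabilities (gains more prevalent in intestinal-type samples, losses
  shorter than gains, one event above the ±0.8 class cut);
- per-probe noise (default SD 0.15), an array-level baseline offset
  (target of centralization), and an intensity-dependent curvature term —
  a zero-mean quadratic in log10 of a lognormal channel intensity — that
  gives the lowess stage something real to remove;
- cohort composition 30 + 10 + 48 samples and a Lauren mix of
  43 diffuse : 41 intestinal : 4 mixed;
- matched expression (Ct tables with expected log2 FC = β × true dosage),
  MLPA peak heights (tumor peaks scaled by 2^dosage, plus controls and a
  per-sample scale factor), and clinical covariates (age ~ N(60, 11),
  exponential survival censored at 80 months).

It does **not** model tumor purity, subclonality, allele-specific copy
number, probe-specific affinity, spatial array artifacts beyond the
intensity trend, or waviness (GC) effects. Passing recovery tests
therefore demonstrate algorithmic correctness under the stated noise
model, not performance on raw clinical arrays.

## Problem sizes in the validation experiments

Chosen as the package's own desk-scale study conditions: 200 random
profiles (n ≤ 300) for the maximizer oracle; 20 samples × 10,000 probes at
noise SD 0.15 for breakpoint recovery (events ≥ 10 probes, |log2| ≥ 0.6);
200 replicates × 20 samples × 1,000 probes for the Poisson-binomial null;
500 random instances for the MCR oracle plus a 90-sample three-platform
cohort with a prevalence-0.25 planted event (30 per platform, enough that
every platform almost surely contributes ≥2 carriers — the minimum for a
CNAR); 100 cohorts of 30 samples for the expression dichotomy. The
dichotomy criterion is evaluated per stratum (each stratum's expected
correct-label rate is 95% at α = 0.05, so the ≥90% bar has real margin;
the joint "both strata correct" event would sit exactly at its expected
value and test nothing).

## Numerical choices and degenerate inputs

- Interval-score ties: leftmost, then shortest.
- KDE mode near-ties: toward 0, warning.
- Quantile normalization ties: average rank.
- DLRS floor 1e−6; constant profiles yield the floor, not zero.
- Constant intensity covariate: error by default, identity by flag.
- Empty 2×2 margins, all-censored survival, single-observation strata:
  missing values with warnings, never silent zeros.
- Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives stage seeds from one master seed.

## Limitations

- The vendor's exact interval weighting, nested-interval reporting, and
  context-correction null are proprietary; this implementation states its
  substitutions (single per-array σ, greedy extraction, marginal-fraction
  context) and should be expected to approximate, not reproduce,
  vendor-software call lists on real arrays.
- Real scanner exports are ingested only through the documented
  probe-table contract (TSV with probe id, coordinates, log2 ratio,
  optional intensity); no Feature Extraction parser is bundled.
- MCR frequencies depend on the full-coverage membership convention;
  the per-platform breakdown is provided so either convention can be
  compared.
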