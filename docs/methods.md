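# Methods

`sedsip` implements the two quantitative procedures used to identify
DNA-foraging bacteria in marine sediments: (1) detection of
¹³C-labelled amplicon sequence variants (ASVs) from DNA stable isotope
probing (DNA-SIP) CsCl density-gradient profiles, and (2) single-cell
¹³C quantification from NanoSIMS ion-count image stacks. Because the
procedures are defined on raw gradient and image data, the package ships
generators that emulate both experiments with known ground truth; every
pipeline stage is validated against that truth or against an independent
oracle.

## 1. Gradient labelling detection

### Model

DNA banded in a CsCl equilibrium gradient sits at a buoyant density set
by its GC content and heavy-isotope content. ¹³C incorporation during
replication shifts a taxon's DNA toward heavier fractions, so a labelled
taxon's *relative abundance* rises in heavy-density fractions of the
¹³C-substrate gradient relative to the same densities of a ¹²C control
gradient. The detection procedure is categorical (labelled / not
labelled), not a quantitative atom-fraction-excess estimate.

For each time point and each heavy-density *window*, the fraction
samples of the ¹³C arm falling in the window are compared to those of
the ¹²C arm with a two-sided rank-sum (Mann–Whitney) test per ASV,
after prevalence/abundance filtering. An ASV is *significant at a time
point* if, in at least one window (configurable to "all windows"), the
two-sided p ≤ α **and** the treatment mean exceeds the control mean
(enrichment only; a two-sided p with a one-sided direction requirement).
An ASV is *labelled* when significant at ≥ `min_timepoints` time
points. Microcosm substrate-response detection uses the same machinery
with substrate vs no-substrate replicate microcosms in place of density
windows.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| windows | 1.725–1.741, 1.735–1.746 | g/ml | heavy-fraction windows of the gradient design; both bounds inclusive, overlap allowed |
| fractions per window | 3–5 | – | surplus fractions trimmed to the 5 closest to the window midpoint, ties toward higher density |
| α | 0.05 | – | raw per-comparison level; Benjamini–Hochberg per time point × window available via `fdr=True` |
| `min_timepoints` | 3 (gradient), 2 (microcosm) | time points | multi-time-point replication requirement |
| `abundance_cutoff` | 0.001 (gradient), 0.05 (microcosm) | relative abundance | an ASV must exceed this in ≥ `ceil(prevalence_cutoff · n_samples)` pooled samples |
| `prevalence_cutoff` | 0.1 | fraction of samples | ceiling rule over the union of both groups |
| `max_median_cutoff` | 0.001 | relative abundance | group-wise median must exceed this in ≥ 1 of the two groups |
| `replace_zero` | False | – | zeros enter medians unchanged; `True` substitutes half the smallest non-zero value |

Cutoffs are fractions of 1 on relative abundances; prevalence is pooled
over both groups. These semantics are configurable because serial
group-comparison implementations differ on per-group vs pooled
prevalence and percentage vs fraction cutoffs.

### The p-value flavours

Three flavours are exposed, because two incompatible conventions are in
field use:

- `auto` (default for gradient detection): the exact Mann–Whitney null
  distribution for combined n ≤ 20; with ties, the full permutation
  distribution over all C(n, n₁) group assignments of the midranks
  (deterministic — the resample cap exceeds C(20,10)); beyond n = 20 the
  normal approximation with tie and continuity corrections.
- `normal` (default for microcosm responder detection): the
  tie-corrected normal approximation *without* continuity correction.
  This is the flavour used by common serial group-comparison tooling; at
  triplicate group sizes it is the only one that can reach significance
  (the extreme 3 vs 3 configuration gives z = 4.5/√5.25, p = 0.0495,
  whereas the exact two-sided minimum at 3 vs 3 is 0.1). Triplicate
  designs therefore *require* this flavour; its anticonservatism at
  n = 3 is the price of any inference at that size.
- `paired`: Wilcoxon signed-rank for sensitivity analysis only;
  fractions from different gradients are not actually paired.

Degenerate input (all values identical) returns p = 1 and no direction.

### Null behaviour and calibration

Two structural facts about gradient data shape the null tests:

1. Exact rank-sum p-values are discrete, so their null distribution is a
   step function below Uniform(0,1), never above it.
2. The pooled window values are **not** fully exchangeable even with no
   labelling: the window fractions differ in expected composition (band
   structure plus compositional renormalisation per fraction), so the
   two-sample rank test is conservative for taxa with density structure
   inside the window. The exact symmetry of the design is the
   ¹³C/¹²C arm swap within each fraction.

The calibration test therefore applies a seeded randomized probability
integral transform of the rank statistic over the 2⁴ pairwise-swap
group — exactly uniform under no labelling — followed by a
Kolmogorov–Smirnov test, and separately bounds the real test's
rejection rate at α with a binomial 99% bound. Both views are what
"uniform p under the null" defensibly means for this design.

## 2. NanoSIMS single-cell quantification

### Pipeline

Order of operations is fixed: **dead-time correction → drift alignment →
plane accumulation → isotope ratio**. Dead time is a per-dwell physical
effect, so it is corrected per pixel per plane before any pixel is
moved; alignment afterwards never mixes corrected and uncorrected
counts.

1. **Dead-time correction.** Non-paralyzable pulse-counting model:
   corrected = m/(1 − m·τ/T) with observed count m, dead time τ (44 ns
   default) and dwell time T (10 ms default). m·τ/T ≥ 1 is a saturation
   error; re-correcting a corrected stack is an error. The correction is
   strictly increasing and > m for m > 0, → m as τ → 0.
2. **Drift alignment.** Integer-pixel shift per plane maximizing the
   cross-correlation of the reference species (¹²C¹⁴N⁻, the biomass
   channel) against plane 0. All species shift identically;
   out-of-frame pixels are flagged invalid, counts are never wrapped.
   Integer shifts keep raw counts integer-preserving; subpixel
   interpolation is deliberately excluded. Shifts ≥ half the frame are
   an alignment failure.
3. **Accumulation.** Pixel-wise sum over planes restricted to pixels
   valid in every plane.
4. **Isotope ratio.** The detector set contains ¹²C₂⁻ and ¹³C¹²C⁻ but
   not ¹³C₂⁻. Atomic-equivalent counts are n¹²C = 2·C₂ and
   n¹³C = ¹³C¹²C, giving
   at%¹³C = 100 · ¹³C¹²C⁻ / (2·¹²C₂⁻ + ¹³C¹²C⁻).
   Under random pairing of carbon atoms at atom fraction x the species
   rates are (1−x)², 2x(1−x), x², so the expected ratio is
   2x(1−x) / (2(1−x)² + 2x(1−x)) = x: the ratio is *exactly unbiased*
   for x although ¹³C₂⁻ is discarded. (The superficially natural
   alternative n¹²C = 2·C₂ + ¹³C¹²C, n¹³C = ¹³C¹²C with
   at% = n¹³C/(n¹²C+n¹³C) estimates x/(1+x) — 7% low at 7.5 at% — and
   is not used.)
5. **ROI statistic.** Counts are summed over the cell's pixels first and
   the ratio taken of the totals (ratio of sums, *not* mean of per-pixel
   ratios): the counting-error model operates on whole-object totals,
   and per-pixel ratios are undefined on zero-count pixels. Pixels
   invalidated by drift are excluded and the excluded fraction recorded.
6. **Poisson error.** σ_Pois = √(n¹²C²·n¹³C + n¹³C²·n¹²C)/(n¹²C+n¹³C)²,
   ×100 for at% units — the delta-method standard deviation of the
   isotope fraction for independent Poisson counts. Caveat: under the
   pair-formation model Var(n¹²C) = 4·Var(C₂), so the formula
   understates the true at% spread by ≈ x/4 in relative terms (≈2% at
   7.5 at%) — inside the 5% band the Monte-Carlo agreement test allows.
7. **Enrichment call.** A cell is ¹³C-enriched iff (i) its at% exceeds
   the upper bound of the two-sided 99.9% confidence interval of the
   natural-abundance control population and (ii) 3·σ_Pois is smaller
   than the distance between the cell and the control mean. The control
   bound defaults to the Student-t CI of the control *mean*
   (mean + t(0.9995, n−1)·sd/√n); a "population" mode
   (mean + z·sd) is provided because "confidence interval of the
   values" is ambiguous between the two readings — the mean-CI default
   is the stricter (lower) bound, i.e. the more sensitive call, while
   the dual σ-criterion guards its specificity.

δ¹³C (‰ vs VPDB, reference ratio 0.0111802, configurable) converts to
atom percent via R = R_VPDB·(δ/1000 + 1), at% = 100·R/(1+R); δ = 0
corresponds to 1.10566 at%.

## 3. What the generators emulate — and what they do not

**Gradient generator.** Each taxon's DNA mass is a Gaussian over an
evenly spaced density grid (default 20 fractions over 1.690–1.760 g/ml,
the recovered range of the fractionation; band σ = 0.004 g/ml), centred
at ρ = 1.660 + 0.098·GC + 0.036·(x − 0.0107)/(1 − 0.0107) g/ml — the
standard linear GC/density convention with a 0.036 g/ml full-labelling
shift, exposed in `DensityModel` and never asserted as a measured value.
A configurable uniform carryover term (default 1–2% of each taxon's
mass) emulates smearing so heavy control fractions are not empty.
Fraction compositions are renormalised (sequencing sees proportions) and
sampled to counts by a multinomial at the sequencing depth (default
20,000 reads). The ¹²C arm forces every taxon to natural abundance. Not
modelled: sedimentation-equilibrium physics, per-fraction recovery
efficiency, PCR/primer bias, chimeras, overdispersion between gradient
arms (microcosm mode offers Dirichlet overdispersion; its default is 0
to keep the null calibration exact).

**Scenario used for recovery checks** (`gradient_sip_scenario`): 12
labelled ASVs — three each from the four sediment DNA-forager groups
(Izemoplasma, Lutibacter, Shewanella, Fusibacteraceae) — with GC
0.31–0.34 and atom fraction 0.98, over 200 unlabelled background taxa
(GC 0.30–0.72, log-normal abundances). Geometric base abundances
(0.11 → 0.008) give heavy-window treatment shares from ~1.4% up to
~17.5% against control shares ≤ ~3%, bracketing the regime the
procedure is meant for. Because the labelled taxa co-band, their
individual window shares cannot all be large simultaneously; the spread
is the realistic consequence of a shared band position.

**NanoSIMS generator.** Elliptical cells on a background; per pixel and
plane the C₂-family count is Poisson at the local carbon rate (default
50 counts/px/plane in cells), split into ¹²C₂⁻/¹³C¹²C⁻/¹³C₂⁻ by random
pairing, with ¹³C₂⁻ generated and then discarded exactly as the
instrument configuration would; CN⁻ and ³¹P⁻ channels are independent
Poisson. Plane k is translated by k·drift (default 1 px/plane in the
scenarios) and the non-paralyzable dead-time distortion
m = n/(1 + n·τ/T) (rounded to integers) is applied to emulate raw
detector output. Not modelled: quasi-simultaneous-arrival effects,
electron-multiplier yield variation, topography, probe-size blur,
subpixel drift. Scenario cells all carry exactly the configured true
fraction (7.5 or 1.08 at%); the biological cell-to-cell spread of a real
labelled population is deliberately absent because the recovery checks
target the estimator mean at 1% relative tolerance.

Passing tests therefore demonstrate correctness of the *procedures*
(filters, test, windows, corrections, ratio, error model, calls) under
Poisson/multinomial counting noise and known truth — not robustness to
the instrumental and biological artefacts listed above.

## 4. Numerical and design choices

- Rank tests, t/z quantiles and BH correction come from scipy;
  brute-force rank enumeration and Monte-Carlo σ checks exist only in
  the test suite as independent oracles.
- Window membership is inclusive on both density bounds; trimming to
  `max_fractions` keeps fractions closest to the window midpoint with
  ties broken toward higher density (heavy-biased, deterministic).
- Time points missing a treatment arm, or with too few fractions in
  every window, are skipped with a warning and excluded from the tested
  denominator rather than counted as non-significant.
- The labelled-set is monotone by construction: raising α or lowering
  `min_timepoints` can only grow it.
- Per-pixel at% maps flag zero-denominator pixels invalid rather than
  reporting 0; ROI quantification errors on fully invalid ROIs.
- Reproducibility: all generators are deterministic given their seed;
  every CLI run writes a JSON manifest with parameters, seed, version
  and input digests.

## 5. Problem sizes

The shipped scenarios are sized so the full suite runs in about a
minute on one CPU: gradient recovery uses 212 taxa × 160 fraction
samples × 10 seeds; null calibration 20 seeds × 200 taxa; single-cell
recovery 512×512 px × 10 planes (51 and 25 cells); the multi-seed
unbiasedness check scales to 256×256 px × 4 planes × 20 seeds, which
leaves the per-cell counting error small against the 1% tolerance. All
sizes are plain function arguments and scale up freely.

## 6. Known limitations

- The serial-comparison procedure is categorical; it does not estimate
  atom fraction excess or density shifts (quantitative SIP is out of
  scope).
- With triplicate microcosms, inference rests on the
  no-continuity normal approximation (see §1); treat single-time-point
  microcosm calls as suggestive only — the ≥2-time-point rule is the
  guard.
- σ_Pois inherits the independent-Poisson assumption noted above.
- The enrichment call compares single cells to the CI of the control
  *mean*; with very tight controls this bound is close to the mean, and
  specificity rests on the 3σ criterion.
- Amplicon bioinformatics (ASV inference, classification), qPCR
  integration, metagenomics and instrument-vendor file formats are out
  of scope; TIFF/TSV/JSON are the interchange formats.
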