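# Methods

## Hazard model

Risk is quantified per site and exposure route as a Pollen Hazard Quotient
(PHQ): each detected compound's beebread residue (ng/g pollen, ppb) divided
by its honey bee LD50 (µg/bee), summed over compounds. The model assumes

1. **additivity** — no synergism or antagonism between compounds (known to
   be optimistic for ergosterol-biosynthesis-inhibiting fungicides combined
   with pyrethroids or neonicotinoids; interaction toxicology is out of
   scope);
2. a **100 mg adult bee** contacting a body-weight equivalent of pollen
   (100 mg) as the acute contact exposure, modeled as a single dose rather
   than a per-day rate;
3. **chronic oral** ingestion of 9.4 mg pollen/day over a 10-day bloom
   period (94 mg total), matching a 10-day chronic LC50 framing.

The quotient stays in the raw ppb/(µg/bee) convention everywhere; unit
conversion is confined to `pct_of_ld50`, where ppb × grams-of-pollen gives
ng of pesticide and ÷1000 gives µg, so percent of LD50 = PHQ × 10⁻²
(contact) and PHQ × 9.4 × 10⁻³ (oral) at the defaults. Inverting this,
the level-of-concern flags flip at total contact PHQ 4000 (EPA acute
risk quotient 0.4), 2000 (EFSA acute ETR 0.2) and total oral PHQ
0.03/9.4×10⁻⁵ ≈ 319.149 (EFSA chronic ETR 0.03). Flags use strict
exceedance: boundary equality is reported as non-exceedance. No
NOAEC-based chronic metric is implemented (NOAEC data exist for too few
compounds to be useful here).

A compound with a missing LD50 for a route contributes nothing to that
route's total and is recorded in `skipped_routes` — in the bundled panel
this affects the oral route of abamectin, atrazine and fenbuconazole.
Missing toxicity is represented as absent, never as 0 or infinity.

### Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `contact_mass_mg` | 100 | mg | pollen contacted in the acute window |
| `oral_rate_mg_per_day` | 9.4 | mg/day | chronic pollen ingestion rate |
| `duration_days` | 10 | days | bloom/pollination period |
| `epa_acute_contact_rq` | 0.4 | fraction | EPA Tier 1 acute contact trigger |
| `efsa_acute_contact_etr` | 0.2 | fraction | EFSA acute contact trigger |
| `efsa_chronic_oral_etr` | 0.03 | fraction | EFSA chronic oral trigger |

All are exposed through the YAML config (`exposure.*`, `thresholds.*`).

## Spray attribution and use index

A compound counts as "sprayed" at a site iff a during-bloom spray event for
it exists there; the non-spray risk share is the unsprayed fraction of the
route's total PHQ (defined as 0 when the total is 0, and reaching 1.0 at
sites with residues but no during-bloom sprays). `during_bloom` is an
explicit input column, never inferred from dates, because bloom windows
differ between sites.

The Pesticide Use Index sums (1/contact LD50) × (%ai/100) × application
rate over during-bloom events; %ai is on a 0–100 scale and rates are in kg
product/ha. Multiple applications accumulate. Events whose compound lacks
a contact LD50 are skipped with a warning rather than failing the site.

## Reported tables

Per-compound summaries average residues over positive detections only
(never-detected compounds report 0), and the quotient of that mean is the
reported mean PHQ. Reported tables round half-up to one decimal; internal
computation is full precision. Two printed reference cells are not
arithmetically consistent with this convention (a mean-residue/LD50 pair
that rounds the other way); they are excluded from exact checks, as are
four reference rows that follow a sum-of-residues rather than
mean-of-detections convention.

Residue inputs below a compound's limit of detection are coerced to 0
(non-detect) with a logged warning; the coercion is idempotent. How a
quantified-but-below-LOD value *should* be treated is genuinely open — the
coercion-to-zero rule is this package's decision and is the conservative
choice for detection counting.

## Pollen composition

Morphotypes at ≥ 3% relative abundance on at least one slide are retained;
all other grains pool into "other". The ≥ comparison at the boundary is a
documented choice (the verbal rule leaves exact equality ambiguous).
Richness counts retained morphotypes with positive count per site — the
"other" pool never counts. One pooled slide per site (colonies pooled) is
the data model; per-colony compositions are deliberately unsupported.

## Landscape

Buffer membership uses the cell-center-in-circle rule (no area weighting),
appropriate for 30 m categorical rasters; all group percents share the
denominator of in-buffer non-NODATA cells. Whether apple cells also count
as agricultural is a flag (default true, since orchard crops belong to the
agricultural class list while percent apple is also reported against all
land uses). Buffer-scale selection fits one simple regression of the
site-level response on each landscape predictor per radius and scores each
radius by its best AIC; ties break toward the largest radius. The
per-predictor (rather than joint) model form is the most literal reading of
scale selection for single-predictor analyses.

## Regression layer

`stats.ols` implements simple OLS from the normal equations with the
F(1, n−2) test and Gaussian AIC = n·ln(RSS/n) + 2k, k = 3, omitting the
additive constant consistently — only AIC differences are used. p-values
are reported exactly; no multiple-testing correction is applied. Degrees of
freedom are always recomputed from the rows actually present (sites with
missing values drop out per regression). Degenerate cases: constant x is
an error; constant y reports R² 0, F 0, p 1; numerically exact fits report
R² 1, p 0 with the RSS floored at 1e-300 inside the AIC logarithm.

## Synthetic-study generator

The generator emulates a 30-site orchard network (4 pooled colonies per
site, 300 grains counted per slide) with the couplings the analysis is
meant to detect, and returns the latent parameters for recovery tests.

* **Landscape**: sites on a lattice with non-overlapping 3000 m buffers on
  a 30 m grid; each site's buffer is filled with apple cells at a density
  drawn uniformly from 0.005–0.35 (the focal-crop gradient), the remainder
  a site-specific natural/agricultural mix.
* **Pollen**: latent apple-pollen fraction = 0.06 + 0.6 × apple density +
  Gaussian noise; slide counts are multinomial over the focal type plus
  4–14 non-focal morphotypes from a 19-type, buckthorn-dominated pool, each
  given a floor share so none is sporadic by construction.
* **Residues**: site totals per class are Gaussian linear responses —
  fungicides to the latent pollen fraction (800 + 8000·p ppb), insecticides
  to true richness (120 + 5.2·r ppb) — allocated across compounds with
  Dirichlet weights reflecting the bundled survey's detection frequencies;
  shares below a compound's LOD merge into the largest share so class
  totals stay exact. These anchors make fungicides carry ~92% of residue
  mass while insecticides dominate the hazard quotients, and site risks
  straddle all three level-of-concern lines.
* **Spray records**: every detected compound is sprayed during bloom except
  a per-site set of "novel" compounds sized by Bernoulli(28/30) × a
  zero-truncated Poisson whose rate is solved so the overall mean is 2.8
  compounds/site (a plain Poisson cannot match the mean and the
  affected-site fraction simultaneously); the count is capped at the number
  of detections, so a site can have *all* of its residues unsprayed.

### Calibration

Noise scales are solved analytically, never tuned. For a response with
target sample R², the population value is first deflated by the
finite-sample bias E[R²] ≈ ρ² + (1−ρ²)/(n−1), then
var(noise) = var(signal)·(1−ρ²)/ρ². Two measurement effects are budgeted
explicitly: multinomial counting error on the slide fraction
(≈ p(1−p)/300) is subtracted from the pollen noise budget, and for the
fungicide coupling — which regresses on the *measured* pollen fraction —
the attenuation λ = var(p)/(var(p)+var(count error)) enters the solution
var(noise) = b²·var(p)·(λ/ρ² − 1). Latent fractions are clipped to
[0.002, 0.9] and residue totals floored at small positive values; with the
default intercepts these clips are rare (< 1% of sites) and their effect on
the calibration is well inside the ±0.05 test tolerance. Defaults: 0.67
(apple area → apple pollen), 0.46 (apple pollen → total fungicide), 0.12
(richness → total insecticide). A target of exactly 0 for the richness
coupling generates a true null (zero slope, realistic noise).

One pseudo-random stream per component (landscape, pollen, residues,
sprays) is split from the master seed. Problem sizes in the validation
suite — 200 replicates of 30 sites for the calibration checks, 100 random
≤5×5 studies for the brute-force oracle comparison — were chosen to bound
Monte-Carlo error on a mean R² well below the 0.05 tolerance while keeping
the default test run fast.

### What the generator does and does not emulate

It reproduces the study's *statistical* structure: gradients, couplings
with specified strengths, detection patterns, non-spray contamination
rates. It does not model bee foraging behaviour, spatial autocorrelation
between neighbouring sites, residue covariance between compounds within a
site (independence is assumed), within-season residue decay, or real
land-cover spatial texture (cover types are i.i.d. cells). Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims on data with known structure — not that real orchard data satisfy
that structure. The default mean apple-pollen fraction (~17%) is higher
than typically observed in the field (~9%); the intercept was chosen to
keep the additive-Gaussian coupling away from the zero boundary, where
clipping would distort the analytic calibration.

## Known limitations

* Additivity understates risk where fungicide–insecticide synergy occurs.
* The landscape module handles projected-meter ESRI ASCII grids only; no
  CRS transforms, GeoTIFF, or raster download.
* The aggregate "share of risk not sprayed during bloom" is computed as
  Σ unsprayed PHQ / Σ total PHQ across sites; site-level averages of the
  per-site fractions would weight sites equally and differ.
* Simple OLS only; no GLM families beyond Gaussian-identity, no mixed
  models, no spatial error structure.
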