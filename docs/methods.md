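# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## 1. Data model and normalization

Expression data live in a `ConcentrationResponseDataset`: a genes ×
samples matrix (log2 scale) whose columns carry (nominal concentration
µM, replicate) labels; 0 µM marks the vehicle control. Invariants: ≥ 4
distinct non-control concentrations, ascending column order, no negative
concentrations. Concentrations stay in µM everywhere; unit conversions
(µM → µg/L via molecular weight, µg → ng) happen only at the module
boundaries where they are documented.

Raw counts are normalized with the median-of-ratios size-factor method
(size factor of sample *j* = median over all-positive-count genes of
count/geometric-mean), then log2(x+1). This is the size-factor core of
standard RNA-seq normalization; dispersion modelling is deliberately not
reproduced — data preparation is not this package's contribution, and
pre-normalized matrices are accepted directly. Note the size factors are
defined only relative to the geometric-mean reference: rescaling one
sample rescales the whole normalized matrix by a common constant.

Exposure-duration selection counts genes with one-way ANOVA p < 0.05
across concentration groups and keeps the duration with the most
(ties → earliest). This is a proxy: the differential-expression criteria
behind the original duration choice are not published, so the F-test
stands in without claiming to reproduce them.

## 2. Benchmark-concentration engine

Four monotone families are fitted per gene on log2 expression:

    hill   f(x) = a + b·xⁿ/(kⁿ + xⁿ)
    power  f(x) = a + b·xᵖ
    exp3   f(x) = a·exp(s·(b·x)ᵈ),  s = ±1 by trend direction
    exp5   f(x) = a·(c − (c−1)·exp(−(b·x)ᵈ))

Constraints: k ∈ [min_conc/10, 10·max_conc]; shape parameters (n, p, d)
∈ [1, 18] — the lower bound follows the restricted-model convention
(no infinite slope at the origin); with sublinear shapes admitted, noisy
fits drift to shallow slopes and bias the BMC low. Direction comes from
the Spearman correlation of group means with concentration. Optimization
is multi-start bounded Levenberg–Marquardt with analytic Jacobians,
batched across starts and bootstrap replicates (`txqivive._lm`); the
power family is seeded by variable projection (exact linear solve for
(a, b) on an exponent grid), which avoids its long (b, p) valley. Fits on
noise-free data recover generating parameters to machine precision.

**BMR and BMC.** The benchmark response is one residual SD. The
likelihood/AIC uses the MLE variance (SSE/N); the BMR uses the
df-corrected SD √(SSE/(N−p)), which is the better estimate of the
within-group noise the "1 SD" convention refers to. The BMC solves
|f(BMC) − f(0)| = BMR in closed form per family (a bracketed root-finder
is kept as an independent cross-check; they agree to 1e-6).

**Model averaging and interval.** Akaike weights
w_i ∝ exp(−ΔAIC_i/2) are computed over the converged effect models *plus
a constant (no-response) model*. The point estimate is the weighted
geometric mean of the effect models' BMCs (BMCs are ratio-scale; the
bootstrap works on log BMC). The interval is a parametric bootstrap:
each replicate draws a model by weight (including the constant model),
simulates y* = fit + N(0, σ̂), refits that family from the original
solution, and recomputes the BMC. Replicates from the constant model, and
replicates whose simulated response never reaches the BMR, enter as +∞ —
dropping them would condition the interval on detectability and shrink it
spuriously. BMDL/BMDU are outward-rounded order statistics of the
replicate distribution at the two-sided 90% level (exact in the presence
of +∞, slightly conservative otherwise), clamped to bracket the point
estimate. Choice-vs-noise streams are split so a larger n_boot reproduces
a smaller run's replicates exactly (common random numbers).

The constant-model competitor is the decisive guard against false
positives: a null gene whose top-dose group deviates by chance is fitted
by a steep family with an apparent effect just above σ̂, and a bootstrap
that simulates only from that fit reproduces the artifact; the flat
model's Akaike mass turns into +∞ replicates, BMDU blows up, and the
precision filter removes the gene. Measured on 400 null genes this takes
the false-positive rate from 7% to 0.8% while interval coverage for true
Hill genes is ~94% at the nominal 90%.

**Filters and ranking.** Responsive ⇔ lack-of-fit p > 0.001 (model vs
saturated group means, F-test) AND BMDU/BMDL ≤ 40 AND BMC ≤ highest
tested concentration. All genes, responsive or not, are ranked by
ascending BMDL for enrichment (undefined BMDLs get a +∞ sentinel and rank
last; ties break lexicographically).

## 3. Pre-ranked enrichment and the PoD gene

Duplicate probes are collapsed to symbols by averaging BMDLs. The ranking
score is s = −log₁₀(BMDL) (the weighted statistic needs a magnitude;
the log keeps ratio-scale meaning); sentinels map just below the smallest
finite score. The enrichment score is the standard weighted-KS running
statistic (weight p = 1 by default; p = 0 reduces to the classic KS
statistic, verified against a brute-force oracle). The null permutes set
membership over the ranked universe preserving set sizes — the only
admissible null for a pre-ranked list. NES = ES / mean(|null ES| of the
same sign); q-values follow the normalized tail-area FDR per sign class
with monotonicity enforced. Defaults: 1000 permutations, set sizes
15–500, permutation seed 149, q < 0.1 for significance.

Each significant pathway contributes its lowest-BMDL member gene; the PoD
is the lowest of these. Two eligibility guards apply: candidates must
have passed the three filters (a BMDL the workflow itself rejected is not
a defensible PoD), and their BMC must not fall below the lowest tested
concentration (no extrapolated PoDs). Pathways without eligible members
fall back to all present members.

## 4. In vitro mass balance

Equilibrium partitioning over six compartments; mass fraction of
compartment i is D_i·V_i / Σ_j D_j·V_j with water the reference (D = 1)
and plastic entering as an area term (K_plastic-w in L/m² × exposed m²).
Ionization is Henderson–Hasselbalch: f_N = 1/(1+10^(pH−pKa)).
Sub-models (all constants in `MassBalanceConfig`, recalibratable):

- D_OW = f_N·K_OW,N + (1−f_N)·K_OW,N·10^(−3.5) (ionic octanol penalty);
  medium and cell lipid use D_OW;
- albumin: log K_prot = 0.71·log K_OW,N + 0.42 for the neutral form, the
  anion offset by −1.15 log units — much smaller than the octanol
  penalty, because perfluoroalkyl anions bind serum albumin specifically;
- plastic: log K_plastic-w = 0.97·log K_OW,N − 6.94;
- air: D_AW = f_N·K_AW,N (ions non-volatile);
- cells: volume-weighted lipid + protein composition;
- nominal concentrations above the melting-point-corrected (subcooled
  liquid, exp(6.79·(1−Tm/T))) solubility are capped with a warning.

Defaults: PFOA (MW 414.07 g/mol, mp 54.3 °C, pKa 2.8, log K_OW,N 6.30,
log K_AW,N −2.10, solubility 9500 mg/L) in a 96-well HepG2 screening
setup (200 µL medium, 10% FBS with lipid 0.0021 / protein 0.059 volume
fractions of serum, 4×10⁴ cells of 2.43 pL, 1.1 cm² plastic, pH 7.4,
310 K). This default set yields f_free = 2.89%, dominated by serum
protein binding (~95% of mass), with cells ~1.6% and plastic ~0.2%.
Free concentrations are reported at 2 decimals in tables; full precision
propagates to reverse dosimetry. Equilibrium only — kinetic fate,
metabolic loss and transporter activity are out of scope, as is
spheroid-specific geometry (the cell parameters describe a monolayer
screening assay).

## 5. PBK model and reverse dosimetry

Flow-limited compartments (plasma, liver, kidney, gut, rest-of-body) with
oral uptake from drinking water (rate [PFOA]_DW × DW_total/24 into the gut
lumen, absorption ka to liver), renal filtration of the free plasma
fraction (GFR·C_free into a filtrate compartment), saturable tubular
resorption Tm·C_fil/(Kt + C_fil) back to plasma — the mechanism behind
the multi-year human half-life of PFOA — and first-order urinary outflow
Q_u·C_fil. Units: µg, L, h. The ODE system conserves mass to solver
tolerance (audited: absorbed = in-body + urine within 1e-12 relative).

At steady state the system reduces exactly: C_fil = R/Q_u,
C_free = (R + Tm·C_fil/(Kt+C_fil))/GFR, liver-efferent free
C_eff = C_free + R/Q_liver, with R the absorbed rate. The closed form is
used directly (cross-validated against a 50-year ODE run to 3.5e-7) and
is strictly increasing in dose, so reverse dosimetry is a bracketed
scalar root (Brent; an ABC accept/reject sampler over a log-uniform dose
prior is available and agrees with the root within its tolerance).
The free in vitro medium concentration is equated to the liver-efferent
free concentration by default (the medium bathes the cells as efferent
blood leaves the organ); mixed-venous free is a config switch.

Central parameters (70 kg adult): cardiac output 348 L/h with liver/
kidney/gut/rest flows 25/19/15/41%; plasma 3 L, liver 1.82 L, kidney
0.31 L, gut 1.2 L, rest 55 L; free plasma fraction 0.02 (strong albumin
binding); free-basis tissue:plasma partition coefficients 60/50/25/10
(≈1.2/1/0.5/0.2 on a total-plasma basis); GFR 6.7 L/h; Tm 1000 µg/h,
Kt 50 µg/L; urine flow 0.05 L/h (1.2 L/day); ka 1 h⁻¹; drinking water
2 L/day. Together these give a plasma-referenced distribution volume of
~0.24 L/kg and an elimination half-life of ~3.8 years, in the range
reported for PFOA in humans. Volumes scale ∝ BW, flows and capacities
∝ BW^0.75. The virtual population draws BW (lognormal, CV 20%) and
multiplies each scaled parameter by an independent median-1 lognormal
(CV 20% anatomical, 30% chemical-specific), truncated at ±3 log-SDs;
sampled flows never exceed cardiac output. Population reverse dosimetry
uses vectorized bisection on the closed-form steady state (identical to
per-individual root finding within 2⁻⁸⁰ relative) and is bit-reproducible
under a fixed seed. Intake = [PFOA]_DW × DW_total/BW × 1000 ng/µg.

## 6. Benchmark dose and TDI

The PoD gene's per-concentration response summaries (mean, SD, n of log2
expression; control at dose 0) are paired with the population-mean
intakes. Responses are treated as lognormal: summaries convert to
log-scale moments, and exponential (3/5-parameter) and Hill
(3/5-parameter) families are fitted to ln f(dose) by n-weighted least
squares with a pooled variance (profile likelihood → AIC). Models within
ΔAIC ≤ 2 of the best enter the average with renormalized Akaike weights.
BMD05 solves f(BMD) = f(0)·(1 ± CES), CES = 0.05 relative on the original
scale, direction auto-detected. BMDL05/BMDU05 are 5th/95th percentiles of
200 parametric-bootstrap replicates of the whole averaging procedure
(draw family by weight, simulate group means, refit all families,
re-average). TDI = BMDL05/3.16; the half-log UF covers human
toxicodynamic variability only, since toxicokinetic variability is
already in the population PBK step. The inverse-exponential and
log-normal families of the full PROAST-style suite are omitted; the
exponential + Hill core covers the monotone responses this pipeline
produces.

## 7. Synthetic data: what it emulates and what it does not

The generator mirrors the study design: 8 concentrations 0.02–50 µM plus
vehicle control (a 100 µM group is excluded on input when present),
3 replicates, 14% responsive genes, i.i.d. Gaussian log2 noise
(SD 0.15 — a typical replicate CV for curated transcriptomic panels),
log2 effect sizes 0.75–1.25, Hill slopes 1–3, true BMCs log-uniform
strictly inside the tested range. True BMCs are defined at BMR = 1 noise
SD, matching the engine's BMR convention. An exp5-shaped truth flag
exercises model competition under mis-specification with the true BMC
still exact. Gene sets: enriched sets draw ≥ 70% (default 80%) of members
from the most sensitive responsive genes; null sets draw uniformly.
Population truths forward-simulate a known dose through the same priors
the QIVIVE stage samples from.

Not emulated: count-level mean–variance structure beyond a simple
library-size model, correlated genes, probe-to-symbol ambiguity beyond
synthetic duplication, non-monotone responses, cytotoxicity, and any
spheroid biology. Passing the closed loop therefore demonstrates that the
pipeline's inference chain is self-consistent under its own assumptions —
not that those assumptions hold for a particular real dataset.

Problem sizes in the default experiments — 300 genes for end-to-end runs,
~200 genes for coverage studies, 3,000 virtual individuals, 200 bootstrap
replicates at both bootstrap stages, 1000 permutations — are the
package's chosen defaults balancing Monte-Carlo error against desk-scale
turnaround (a full run takes well under a minute on one core).

## 8. Known limitations

- The model-averaging scheme (Akaike weights + parametric bootstrap) is a
  documented, transparent procedure; it is not a re-implementation of any
  external tool's unpublished internals, and its intervals are
  approximate (coverage ~94% at nominal 90% in the regime tested).
- The lack-of-fit "best fit p-value" requires replication; without it the
  test is undefined and reported as 1 with the gene's adequacy untested.
- The PBK parameterization is a defensible central set with standard
  allometry, not a calibration to human biomonitoring data; absolute dose
  conversions inherit its uncertainty. Enterohepatic recirculation and
  non-oral routes are not modelled.
- The TDI step pairs the PoD gene's expression summary with mean
  population intakes; other pairings (e.g. per-individual dose–response)
  are possible and would change the interval, not the point logic.
- Mass-balance constants are literature-style regressions with a single
  calibrated anion-albumin offset; chemicals far from the perfluoroalkyl
  acid class need the config block revisited.
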