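# Methods

## The extrapolation chain

`hepscale` predicts individual hepatic clearance from microsomal data in
four steps.

**1. Microsomal scaling factor.** POR (cytochrome P450 oxidoreductase) is
essentially entirely microsomal, so the ratio of a liver's homogenate POR
activity (per g tissue) to its microsomal POR activity (per mg microsomal
protein) measures the microsomal protein yield per gram of liver:

    MPPGL [mg/g] = rate_homogenate [nmol/min/g] / rate_microsome [nmol/min/mg]

POR rates come from 550 nm cytochrome-c reduction kinetics: an OLS slope of
absorbance vs time, converted by Beer–Lambert with Δε = 21.1 mM⁻¹cm⁻¹
(the standard value for reduced-minus-oxidized cytochrome c at 550 nm;
overridable), scaled by the reaction volume (default 220 µL) and normalized
by the protein or tissue mass in the well. Homogenates at the standard
dilution of 10 mL buffer per g liver are supported through a volume→mass
helper. A non-positive fitted slope flags assay failure rather than
returning a silent zero. An optional automatic linear window trims trailing
time points until R² ≥ 0.98, since plate readers report a fixed 0–5 min
window but substrate depletion can bend the tail.

**2. Enzyme kinetics.** Tolbutamide 4-hydroxylation (CYP2C9) is measured at
seven concentrations (31.25–2000 µM, two-fold dilutions) and fit to the
single-enzyme Michaelis–Menten model by Levenberg–Marquardt least squares
with Lineweaver–Burk initial values (tolerance 1e-10 on relative
parameter/cost change, max 2000 evaluations). The in vitro intrinsic
clearance is CL_int = Vmax/Km, which is exactly µL/min/mg when Vmax is in
pmol/min/mg and Km in µM.

*Residual weighting.* The default minimizes relative residuals (σᵢ ∝ vᵢ),
because metabolite quantification error is roughly proportional to the rate
(approximately constant CV). Unweighted fitting lets the plateau points
dominate and measurably degrades Km: at 5% CV noise on this grid the median
relative Km error is ≈7% unweighted versus ≈4.7% weighted, the latter close
to the Cramér–Rao floor (≈4.6%) for this design. `weighting="none"` restores
raw least squares. Identifiability is monitored through the parameter
correlation of the fitted covariance: when all concentrations sit far below
Km the model collapses onto the line v = (Vmax/Km)·C, only the ratio is
identifiable, and the fit is flagged `ill_conditioned` (|corr| > 0.999)
while still reporting a reliable CL_int.

**3. Per-liver activity.** V_L [nmol/min/g] = V_M [pmol/min/mg] ×
MPPGL [mg/g] / 1000. Variability is summarized by max/min fold-change and
the 95% percentile-interval (2.5th–97.5th) fold-change, percentiles by
linear interpolation between closest order statistics (the common "type 7"
convention of mainstream numerical stacks). The rank-change analysis ranks
donors ascending by V_M and by V_L per isoform and reports the absolute
rank difference as a fraction of cohort size, binned as tiny [0, 10%),
moderate [10, 20%), obvious [20, 50%) and dramatic [50%, 100%]. Ties get
stable first-occurrence ranks for display (logged when they occur); the
statistical screens use conventional average ranks internally via the
standard tests. Group comparisons are Mann-Whitney U (two groups; exact
null distribution when tie-free and n ≤ 25 per group) or Kruskal-Wallis H
(three or more); correlations are Spearman with strength bands strong
(|r| ≥ 0.6), moderate (0.3 ≤ |r| < 0.6), weak. P values are unadjusted; no
multiple-testing correction is applied.

**4. Clearance prediction and scoring.** Liver volume follows the
anthropometric relation LV [mL] = 12.5·BW + 536.4 (derived for Chinese
adults), liver weight LW = 1.001·LV, hepatic blood flow Q_H = 24.5% of
cardiac output. Whole-liver intrinsic clearance is

    CL_int,liver [mL/min/kg] = CL_int,in vitro · MPPGL · LW / BW / 1000

and the well-stirred model gives

    CL_H = Q_H·fub·CL_int,liver / (Q_H + fub·CL_int,liver)

with everything per kg body weight and fub = 0.0982 for tolbutamide (single
literature scalar, not per-donor). Tolbutamide is low-extraction here
(fub·CL_int ≈ 0.11 vs Q_H ≈ 20 mL/min/kg), so CL_H ≈ fub·CL_int,liver and
the map is nearly linear — which is why all seven methods share the cohort
mean while differing enormously in spread. Accuracy is the average
fold-error AFE = 10^(mean log10 predicted/observed) over the N = 6 packaged
literature reports (base-10 logs, as the 10^ form dictates), with the
two-fold window 0.5 ≤ AFE ≤ 2 inclusive at both ends.

### The A–G method masks

Methods substitute individual vs cohort-arithmetic-mean values for the five
parameters {MPPGL, CL_int, LW, Q_H, BW}: A individualizes all five, B–F
exactly one each (in that order), G none. Two deliberate conventions:

* Q_H per kg divides the masked Q_H by the *masked* BW, keeping the
  well-stirred formula dimensionally consistent under every mask.
* Under method F (individual BW) the liver weight stays at the cohort mean
  even though LW is a function of BW — the one-parameter-at-a-time design
  would otherwise smuggle LW variation into the BW method. A
  `recompute_lw` flag provides the alternative reading.

## The synthetic cohort generator

The generator emulates a surgical liver bank: per-donor demographics
(gender 31%/69% male/female, three age bands between 20 and 75, ~10%
smokers and drinkers, six diagnosis categories at the published
proportions), body weight, cardiac output, a latent MPPGL, latent
tolbutamide (Vmax, Km), matched POR pairs, kinetic series and per-isoform
microsomal activities.

* **Distribution family.** Measured traits are strictly positive and
  right-skewed with no published distributional form, so each continuous
  trait is a truncated log-normal: (µ, σ) moment-matched to the target
  arithmetic mean/SD via σ² = ln(1 + (sd/mean)²), µ = ln(mean) − σ²/2, then
  restricted to the published min–max by rejection sampling (resampling, not
  clipping, to avoid boundary atoms). This is an explicit modelling
  assumption of the generator, not an inference about the real cohort.
* **Calibration defaults** are the published population summaries: MPPGL
  39.46 ± 21.57 mg/g on (6.71, 127.95); Vmax 255.82 ± 79.48 pmol/min/mg on
  (83.76, 454.80); Km 235.73 ± 99.78 µM on (101.20, 531.90). Per-isoform
  V_M uses a log-normal reconstructed from the published median
  (µ = ln median) and 95% PI (σ = ln(PI_hi/PI_lo)/(2·1.96)), since medians
  and PIs, not means/SDs, are what is published for those.
* **Unpublished defaults, chosen once:** body weight 60 ± 9 kg on (40, 85)
  — consistent with the reported ≈2-fold BW range in a predominantly female
  Chinese surgical cohort; cardiac output 5.0 ± 0.8 L/min on (3.5, 7.0) —
  textbook resting values, since the original age/gender lookup source is
  not published; microsomal POR rate 100 nmol/min/mg with 15% CV — typical
  human liver microsomal cytochrome-c reductase activity. All overridable
  in `CohortSpec` / `PipelineConfig`.
* **POR pairing.** The microsomal rate is drawn log-normally around its
  mean; the homogenate rate is defined as microsome_rate × latent MPPGL.
  Assay noise therefore cancels in the ratio and the MPPGL estimator
  round-trips exactly — by construction, so these tests verify plumbing,
  not robustness to unpaired noise.
* **Kinetic noise** is multiplicative Gaussian, vᵢ = MM(Cᵢ)·(1+εᵢ),
  εᵢ ~ N(0, CV), clipped at zero; default CV 5%.
* **Seeding.** One master seed; every trait and stage draws from its own
  `SeedSequence` substream, so outputs are byte-reproducible and adding a
  trait never perturbs another's draws.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: covariance between demographics and enzyme traits
(set to zero; the real cohort showed essentially none, with isolated
exceptions), disease-state effects, truly unpaired homogenate/microsome
assay error, genotype structure in CYP2C9, and any deviation of real trait
distributions from the truncated log-normal form. Note that truncation at
the published extremes pulls sample SDs a few percent below the nominal
calibration values (visible for Km, −14%); the moment-matching property is
exact only as bounds widen.

## Numerical choices and degenerate inputs

* Percentiles: linear interpolation ("type 7"); sample SD with ddof = 1;
  single-value samples report SD 0 and fold-change 1.
* Fold-changes require strictly positive values and error otherwise.
* Outlier flags use Tukey box-plot fences: beyond 1.5×IQR = outlier,
  beyond 3×IQR = extreme.
* A spec with sd = 0 degenerates to a constant trait; n = 0 yields an empty
  cohort.
* Michaelis–Menten fits with fewer than 3 distinct concentrations, all-zero
  rates, optimizer failure or a non-positive optimum raise typed errors
  carrying the donor id and initial values — nothing is silently imputed.
* CSV interchange writes shortest round-trip float representations and
  re-parses with correctly rounded conversion, so write→read is
  bit-identical; schema violations report file line numbers.

## Problem sizes

Default cohorts are 78 donors (matching the kinetically characterized
subset the prediction methods are defined over) or 128 (the MPPGL panel);
calibration-convergence tests use 5,000–20,000 donors and the estimator
precision studies 200 kinetic series — sizes at which every statistical
check stabilizes while the full suite runs in seconds.

## Known limitations

* Well-stirred liver only; no parallel-tube or dispersion models, no
  transporter uptake or blood:plasma partitioning corrections.
* Single-enzyme Michaelis–Menten only; no substrate inhibition or two-site
  kinetics.
* fub is a cohort-wide scalar; plasma-protein binding variability is not
  propagated.
* MPPGL recovery corrections other than the POR ratio (CYP content,
  glucose-6-phosphatase, ELISA) are out of scope.
* The AFE pools all observed reports into one geometric mean per donor; no
  per-study error decomposition.
* The median Km recovery error at the default noise level sits near its
  information-theoretic floor (≈4.6%); individual 200-series replicates
  scatter around it by ±0.6% (SD of the sample median).
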