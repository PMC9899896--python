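# Methods

This note documents the models, parameters, and numerical choices behind
`gentox`, and what the synthetic-data validation does and does not
demonstrate about real assay data.

## Concentration-series design

Series are geometric with ratio 0.70711 (≈ 1/√2, "70.71 % spacing"), top
concentration first: `c_i = top · 0.70711^i`.  A 6-point series spans a
5.66-fold range, a 10-point series 22.6-fold.  Top concentrations come from
a viability pre-screen: the highest *tested* candidate retaining ≥ 40 %
viability (transcriptomic and micronucleus assays) or ≥ 20 % (DNA-damage
biomarker assay), capped at 10 mM.  Viability between tested candidates is
never interpolated — real studies pick from tested ranges, not fitted
curves.  Concentrations are carried at full precision and rounded to 4
significant figures only for display.

## Transcriptomic DDI classification

Counts are normalized to log2(CPM + 1), probes collapsed to genes by mean,
replicates averaged, and fold-change computed as treated minus control mean
per gene.  Conditions below 40 % viability are dropped, as are samples
below an optional library-size floor (no default is claimed for that floor;
it is a config parameter).

**Nearest shrunken centroids.**  With class centroids x̄_kj, overall
centroid x̄_j, pooled within-class SD s_j, fudge s₀ = median(s_j), and
m_k = √(1/n_k + 1/n), the standardized deviation d_kj = (x̄_kj − x̄_j) /
(m_k (s_j + s₀)) is soft-thresholded by Δ and the shrunken centroid
reconstructed.  Classification uses the discriminant
δ_k(x) = Σ_j (x_j − x̄′_kj)²/(s_j + s₀)² − 2 log π_k with equal priors
π_k = 0.5 (the reference set's class balance is by design, not prevalence);
posteriors ∝ exp(−δ_k/2).  A concentration is called only when the winning
posterior exceeds 0.90, otherwise unclassifiable.  Δ is chosen by
leave-one-chemical-out cross-validation on the training set over a 15-point
grid from 0 to the largest |d_kj|, keeping the smallest Δ on ties.  With
the well-separated synthetic training set the chosen Δ is typically 0 —
shrinkage buys nothing when every gene is informative.

**PCA.**  Principal components are fitted on the training chemicals after
centering by training gene means (no variance scaling by default; scaling
is a config flag since the convention is not universal).  The PC1 sign is
fixed by convention so the DDI training mean is negative, making "negative
PC1 ⇒ DDI" well defined; a score of exactly 0 falls on the non-DDI side
(strict inequality for the positive call).

**Hierarchical clustering.**  Training chemicals and sample conditions are
clustered jointly (Euclidean, average linkage) and the tree cut into its
two top clusters.  A cluster's identity is the strict majority label of its
training chemicals; samples inherit it, and are unclassifiable when their
cluster has no training chemicals, a cluster's labels tie, or the two
clusters share a majority label.

The overall call is DDI iff any prong returns DDI at any concentration —
deliberately sensitive, mirroring a conservative screening posture.

## Micronucleus calling

Endpoints: %MN = 100·MN/nucleated events; relative survival
RS = 100·(treated nuclei/mL)/(mean control); fold-EMA = treated
%apoptotic-necrotic over the control mean, implemented as a plain ratio (a
fold quantity needs no percent scaling).  Gating is evaluated on the
replicate-averaged endpoint per concentration: RS < 40 % (the boundary
value 40.0 is retained) or fold-EMA > 4.

Significance per concentration comes from the likelihood-ratio test of the
treatment indicator in a Poisson log-linear model of MN events with offset
log(nucleated events).  With one indicator the group-rate MLEs are closed
form, so the deviance is computed directly; the test statistic and p-value
are identical to an iteratively fitted GLM (the test suite checks this
against statsmodels).  The per-concentration p-values of a compound are
Holm-Šidák adjusted (step-down: adj_i = max_{j≤i} 1 − (1 − p_j)^(m−j+1)).
A compound is positive iff some non-gated concentration shows both
fold-MN ≥ 2.50 (replicate-averaged) and adjusted p < 0.05; if every
concentration is gated the result is "undetermined", distinct from
negative.

The asymptotic LRT p-value tracks the exact conditional (binomial)
two-sample test closely in the count regime of this assay (tens of MN
events per well); at counts below ~20 both the exact test's discreteness
and the asymptotics degrade, which is documented rather than hidden.

## Mode-of-action calling

Fluorescence endpoints are fold-shifts of treated median channel
fluorescence over the control mean; %polyploidy = 100·8n/(2n4n + 8n);
%p-H3 = 100·positives/(2n4n + 8n); RNC = 100·treated density/control mean;
cytotoxicity = 100 − RNC at 24 h, gating concentrations above 80 %.

Global Evaluation Factors (fold thresholds, "met or exceeded" so equality
counts): clastogen set 4H γH2AX 1.51, 24H γH2AX 2.11, 4H p53 1.40,
24H p53 1.45; aneugen set 4H p-H3 1.71, 24H p-H3 1.52, 24H polyploidy 5.86,
24H p53 1.45.  24H p53 deliberately belongs to both sets, so a compound can
reach pan-genotoxicity through 24H p53 plus one set-specific biomarker per
side.

"Two successive concentrations" is read strictly — the *same* ≥ 2 set
biomarkers over threshold at two consecutive concentrations of the ordered,
gate-filtered series — because that is the tightest unambiguous reading;
the looser any-two-anywhere reading is available behind
`strict_consecutive=False`.  Consecutiveness is assessed after removing
gated concentrations, which carry no interpretable signal.  Two set
biomarkers at a single concentration give a "weak" call.  One positive set
⇒ clastogen or aneugen; both ⇒ pan-genotoxic; otherwise non-genotoxic.

## Benchmark-concentration modeling

**Gene-level (SD-based) BMCs.**  Genes are prefiltered by a permutation
Williams-type trend test (isotonic estimate of the highest-dose mean minus
the control mean, standardized by the pooled within-group variance; both
orientations, larger |t|; p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), default
500 permutations, α = 0.05) and a linear fold-change floor (max over
concentrations of 2^|Δlog2| ≥ 1.5).  Both one- and two-sided conventions
exist for the Williams test; the two-orientation maximum is used and
flagged here.

Surviving genes are fitted with Exp2 a·e^(bx), Exp3 a·e^(±(bx)^d),
Exp4 a[c−(c−1)e^(−bx)], Exp5 a[c−(c−1)e^(−(bx)^d)], Linear, quadratic
Polynomial, and restricted Power a + bx^g (g ≥ 1); shape exponents are
bounded in [1, 18] and the Exp3 exponent sign is pinned to the adverse
direction.  Linear and Poly2 solve in closed form; the nonlinear members
use trust-region least squares with analytic Jacobians and data-driven
starts.  The likelihood is Gaussian with constant variance;
AIC = 2(k+1) − 2 ln L counts the variance parameter.  The best (lowest-AIC)
model defines the BMC as the smallest concentration where
|f(x) − f(0)| = bmr_sd · σ, located on a 512-point log grid and refined by
Brent's method; σ defaults to the best model's residual SD, but the assay's
characteristic SD can be supplied to keep the benchmark response fixed
across endpoints (and to keep the BMC defined on near-noiseless data).
Fit adequacy is a pure-error F lack-of-fit test against the group-means
model (undefined without replicate degrees of freedom).  BMCL/BMCU are
2.5/97.5 bootstrap percentiles over refits of the best model to replicates
resampled within concentration (default 250; warm-started at the fitted
parameters).

Gene BMCs are removed when fit p < 0.1, BMC/BMCL ≥ 20, BMCU/BMC ≥ 20, or
BMCU/BMCL ≥ 40; BMCs above the top tested concentration are retained but
flagged (the ToxPi substitution rule handles them).  The gene-set BMC is the
median of surviving gene BMCs with a CI from 2.5/97.5 percentiles of
medians over resamples of the surviving set (default 2000; the count is a
package choice, not a published value).  Confidence limits use the
nonparametric bootstrap throughout rather than profile likelihood — one
uniform mechanism across model families, documented as a methodological
difference from the reference tools.

**Flow-endpoint (CES) BMCs.**  The single 5-parameter exponential
y = a[c − (c−1)e^(−(x/b)^d)] (a, b > 0, c ≥ 1, d ≥ 1) is fitted to fold or
%-induction data; the BMC solves f(BMC)/f(0) − 1 = CES with CES = 1.0 for
MN induction and 0.5 for the DNA-damage biomarkers, in closed form from
the fitted parameters: BMC = b·(−ln((c−1−CES)/(c−1)))^(1/d).  A fitted
plateau below the CES target leaves the BMC undefined (flagged), and the
lowest defined biomarker BMC is the overall endpoint BMC.  The printed form
of this model in the surrounding literature is typographically ambiguous;
the canonical parameterization above is what the cited dose-response
software fits.

## ToxPi integration

Absent, infinite, or above-top BMC confidence limits are substituted with
10,000 µM.  Each of BMCL and BMCU maps to −log10(µM); the two are summed
(transform-each-then-sum: −log10 of a *sum* of concentrations has no
potency interpretation, though that alternative reading is available behind
a flag), shifted so the substitution-only baseline (−8) maps to 0 — an
inactive slice therefore does not protrude from the origin — and divided by
the slice maximum across compounds.  Overall score = Σ weight · slice with
default weights 1/3 (TGx-DDI), 1/3 (MN), 1/12 each for 4H/24H p53 and
γH2AX; custom slice sets are re-normalized to sum to 1.  Confidence bands
come from deterministic rescoring with all-BMCL (upper) and all-BMCU
(lower) inputs.  Ranks descend by overall score with ties sharing a rank;
profiles are clustered on slice-score vectors (Euclidean, average linkage,
k = 2 by default).  Scores are relative to the compound set scored —
comparing scores across separately scored sets is not meaningful.

## Synthetic-data generator

The generator emulates the study shape: a 28-chemical training set
(14 DDI / 14 non-DDI, half the 64 genes up- and half down-regulated in the
DDI class — the two-block heatmap structure, which exercises centroid sign
handling), 6-point duplicate expression series, 10-point flow plates with
6 solvent-control wells per plate, a 5,000-event analysis stop gate, and a
0.7 % background MN frequency.

Mean curves are the monotone 5-parameter exponential
fold(x) = c − (c−1)e^(−(x/b)^d); every active endpoint therefore has an
analytically known true BMC.  Noise families are generator choices, not
measured assay properties: additive Gaussian on log2 expression
(σ = 0.25 per replicate), Poisson MN counts, binomial ploidy/p-H3 events,
log-normal fluorescence (σ_log = 0.05) — multiplicative so fold-changes are
scale-free and intensities positive.  Defaults: effect size 1.0 log2 units
at the plateau (4 noise SDs — clear but not caricatured), MoA biomarker
plateaus set 1.5–2× above their GEFs, MN plateau 4-fold.  Gene-level BMC
data are emitted on the log2 *expression* scale with per-gene baselines
uniform on [6, 10] (mid-abundance transcripts): the multiplicative
exponential family needs a non-zero baseline, and fold-change-scale input
(baseline 0) silently degrades it to near-linear fits.

Randomness is split one child stream per (sub-generator, compound) via seed
sequences, so adding a compound never perturbs the data of existing ones.

What passing the synthetic suite shows: the statistics are implemented
correctly (they recover known truth, match closed forms and independent
oracles, and are calibrated under their own assumptions).  What it does not
show: robustness to real-data pathologies — batch effects, probe
cross-hybridization, non-Poisson MN overdispersion, fluorescence carryover,
solubility limits — none of which the generator emulates.

## Validation study sizes (package choices)

- Ensemble class recovery: 100 studies × 4 compounds, effect 4× noise SD.
- MN null calibration: 500 inactive compounds; family-wise significance
  tracks α and the full call rule (fold ≥ 2.5 AND adjusted p < 0.05) yields
  essentially no false positives at 35-event backgrounds.
- BMC recovery: noiseless curves to 1 %; 50 noisy endpoints at the stated
  log-normal fluorescence noise (median relative error ≈ 4–5 %).
- Gene-set BMC coverage: 100 studies of 16 genes in triplicate sharing a
  true BMC placed mid-range of a 10-point series that brackets the curve's
  foot and saturating shoulder (potency scale 600 µM under a 1000 µM top).
  This
  bracketing matters: when the true BMC sits at or below the lowest tested
  concentration, the AIC model-selection step biases per-gene BMCs (simpler
  family members cross the benchmark early or late where the curvature is
  unsampled) and no resampling CI can stay calibrated around a biased
  median.  The same applies to real studies — it is what viability-based
  top-concentration selection is meant to achieve.

## Known limitations

- The published 64-gene biomarker panel and 28-chemical reference data are
  not bundled; the classifier is generic over any labeled panel in the
  documented CSV format.
- Constant-variance Gaussian likelihoods throughout the BMC family; no
  variance modeling on the log scale as some reference tools offer.
- Bootstrap (not profile-likelihood) confidence limits.
- The MN caller models counts as Poisson; real MN data can be
  overdispersed, which would make the p-values anticonservative.
- S9 metabolic-activation conditions are collapsed by "positive in either
  condition"; the generator does not simulate distinct S9 arms.
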