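# Methods

This note documents the statistical procedures, the conventions and
defaults behind them, and what the synthetic-data tests do and do not
establish.

## Community-weighted means and screening

A subplot's CWM for a trait is the abundance-weighted mean over the species
recorded there. Subplots with zero total abundance for a life form are
excluded from that life form's table rather than imputed as zero — a zero
would be a fabricated trait value, not an observation. CWMs are invariant
to rescaling all abundances by a positive constant, so relative abundance,
cover or counts may be used interchangeably as the weight.

Normality screening uses Shapiro–Wilk at α = 0.05; variables that fail are
Box-Cox transformed with the maximum-likelihood λ. Non-positive values are
an error, never silently shifted: the size of a shift changes the
transform, so it must be an explicit analyst decision. Plot comparisons use
one-way ANOVA with a Tukey-HSD compact letter display (letters descend from
"a" at the highest group mean; an insert-and-absorb algorithm merges
non-significant groups).

## Minimum data set

Sampling adequacy is checked with the overall KMO statistic
(Σr² / (Σr² + Σp²) with p the anti-image partial correlations) and
Bartlett's sphericity statistic −(n−1−(2p+5)/6)·ln|R|. Defaults for
proceeding: KMO ≥ 0.5 and Bartlett p < 0.05.

The factor model eigen-decomposes the CWM correlation matrix and retains
components with eigenvalue ≥ 1. Retained loadings are varimax-rotated by
default (`rotate=False` gives the raw components); after rotation the
per-component "eigenvalue" reported is the column sum of squared loadings,
which is what the Norm value and FTEI weights consume. Signs are fixed by
making each component's dominant loading positive, so results are
deterministic. Data in which many eigenvalues sit near 1 (e.g. essentially
uncorrelated traits) make the retained-component count unstable; the fit
warns rather than failing.

The Norm value of trait i is √(Σₖ U²ᵢₖ·λₖ) over retained components — the
length of the trait's loading vector weighted by component variance. The
selection rules:

1. every trait joins the group of the component where its |loading| ≥ 0.5;
   traits clearing the cut nowhere form a residual group; a trait clearing
   it on two components joins the group whose members it correlates with
   least (mean |r|);
2. within each group, candidates are traits with Norm within 10 % of the
   group maximum ("top 10 %" is read multiplicatively — within 90 % of the
   best — not as a percentile, which would be ill-defined in groups of two
   or three);
3. a single candidate is retained; among several, each candidate is
   compared with the top-Norm trait — |r| ≥ 0.5 keeps only the higher-Norm
   trait (coefficient of variation of the raw CWM column breaks exact Norm
   ties), |r| < 0.5 keeps both.

On the published worked-example tables these rules reproduce the seven
woody groups (six component groups plus the residual group
{LC, LN, LP, H, LL}), the six herbaceous groups, and the published
seven-trait woody and six-trait herbaceous MDS exactly.

## FTEI scoring and cross-validation

Linear scores are x/x_max for "positive" traits and x_min/x for "negative"
ones; non-linear scores are 1/(1+(x/x̄)^b) with b = −2.5 (positive) or
+2.5 (negative). Which traits a survey should treat as negative is a
biological judgement; the default is all-positive and is overridable per
trait. Extremes (x_min, x_max) and means are pooled over all subplots of a
life form across plots.

FTEI_A is the plain mean of scores; FTEI_W weights each trait by the
variance of its defining component divided by the total over the traits in
the set. Traits from the residual group have no defining component and use
the component where their |loading| is largest — a convention, chosen so a
residual trait is weighted by the structure it is closest to rather than
arbitrarily. Cross-validation regresses the total-set FTEI on the MDS FTEI
for all four {weighted, average} × {linear, non-linear} combinations and
reports R², slope and p.

## Ecosystem-function indices

EF per function (C, N, P) is the equal-weight mean of its indicator
variables after min–max normalisation to [0, 1]. Normalisation is global
across the table by default (`groupby_plot=True` switches to per-plot);
global is the default because the plots form one transect and per-plot
normalisation would erase between-plot gradients. Negative indicator values
are folded by absolute value with a warning — concentrations should not be
negative, so this is a data-quality flag, not a silent fix.

## Trend models

Rows are split 70/30 within each plot (floor(0.7 n) training rows,
seed-deterministic), so every plot is represented in training and testing.
Models: PLS with the component count chosen as the smallest within one
standard error of the minimum 5-fold train-CV RMSE; random forest with 100
trees; and a feed-forward network with four hidden layers of five logistic
units, linear output, ≤ 500 iterations, standardized inputs, trained with
L-BFGS (stable at a few hundred rows where stochastic gradient descent is
noisy). RMSE and MAE are reported on the held-out rows only; whole-sample
metrics would mix memorisation with generalisation, and the two model
families memorise very differently.

## Variography and kriging

The empirical semivariogram is the method-of-moments estimator on 10 (by
default) equal-width distance bins up to half the maximum pairwise
distance. An optional `groups` argument restricts pairs to within-group
(used when plots share relative coordinates but are physically far apart).

Model fitting is weighted least squares over four forms — linear,
spherical, exponential, Gaussian — with the best form chosen by R²
(computed on the binned points with the same weights), RSS breaking ties.
The default weights are N(h)/h², which emphasise the short lags that
determine the nugget; recovery experiments on simulated exponential fields
showed plain N(h) weights systematically inflate the fitted nugget and
misclassify the nugget–sill ratio, while N(h)/h² (also the gstat default)
does not. `weights="counts"` restores plain N(h) weighting.

**Range convention.** Exponential and Gaussian models are parameterised by
their *effective* range — the distance at which the curve reaches ~95 % of
the sill: γ = C₀ + C·(1−e^(−3h/a)) and γ = C₀ + C·(1−e^(−3h²/a²)). Fitted
ranges under the "distance parameter" convention differ by 3× (exponential)
or √3× (Gaussian); comparisons across software must account for this.

The nugget–sill ratio 100·C₀/(C₀+C) classifies spatial autocorrelation:
< 25 % strong, 25–75 % moderate, > 75 % weak.

Ordinary kriging solves the standard system with an unbiasedness
constraint; the model semivariance at exactly zero distance is taken as 0
(not C₀), so the predictor honours the data at sample locations. Weights
sum to 1 by construction. Regression kriging adds ordinary-kriged
training-set residuals (observed − trend, per plot, in plot-relative
coordinates) to the trend-model surface; with a constant trend it is
numerically identical to ordinary kriging of the raw values. When all
residuals are zero the trend is returned with a warning rather than fitting
a degenerate variogram.

## Synthetic data

The generator emulates the survey design: three 100 m × 100 m plots, each
a 10 × 10 grid of subplots with coordinates at subplot centres
((5+10·col, 5+10·row) m, plot-relative). Trait CWMs come from a latent
factor model — six factors by default, with blocks mirroring field
structure (leaf-mass traits together; SLA/SLW; LDMC/LWC; leaf shape; stem
size and leaf thickness alone; C/N/P concentrations, height and leaf
length loading weakly) — rescaled to positive trait-typical ranges, since
the scoring formulas assume positive values. Chemistry indicators are a
linear trend in designated standardized traits plus a zero-mean Gaussian
random field per plot. The field is sampled exactly by Cholesky
factorisation of the covariance implied by the variogram (cov = sill − γ;
nugget as unstructured variance), which is the right tool at ≤ a few
hundred points. Default field truth: exponential, C₀ = 0.1, C = 0.9,
effective range 30 m — strong spatial autocorrelation with a nugget share
like the published surveys report. No raw data were ever deposited for the
original survey, so these magnitudes are field-plausible conventions, not
estimates.

`generate_observations` disaggregates each CWM into pseudo-species records
whose abundance-weighted mean reproduces the CWM exactly, letting the
aggregation stage run end-to-end on synthetic input.

What passing synthetic tests show: the estimators recover planted structure
(factor blocks, trend coefficients, variogram parameters) under the model's
own assumptions. What they do not show: robustness to the features of real
surveys the generator omits — non-Gaussian trait distributions, abundance
structure across species, anisotropy, non-stationary trends, measurement
error correlated within plots.

## Known limitations and numerical notes

* Method-of-moments + WLS variogram estimation at ~300 points has large
  sampling variance in the nugget: on simulated exponential fields with a
  true nugget share of 10 %, roughly one seed in five misclassifies the
  autocorrelation class across every sampling layout and weighting scheme
  tried (uniform, gridded, close-pair cluster designs; N, N/h², Cressie
  weights). Per-seed nugget estimates should not be over-read; the sill is
  much better behaved (mean fitted sill well within ±20 % of truth).
* The recovery suites run at 20 seeds × 300 points, sizes at which the
  whole test suite completes in well under a minute on one core.
* Kriging uses dense solves (n ≤ a few hundred samples per plot); no
  neighbourhood search is implemented.
* Duplicate sample coordinates make the kriging system singular and are
  rejected; jitter your data explicitly if duplicates are genuine repeat
  measurements.
* The variance-contribution rates reported by `FactorModel` are
  100·λₖ/p from its own decomposition; published tables sometimes print
  rates from conventions that cannot be reconstructed from the printed
  loadings alone, so only the cumulative-sum arithmetic is checked against
  print.
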