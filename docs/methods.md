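# Methods

## The model

The quantity modelled is recombinase activity of a missense variant,
expressed as a percentage of wild-type activity in a cell-based
inverted-GFP recombination assay (bounded below by 0; values above 100 %
occur for activating variants, and the working range is taken as
[0, 150] %).  Activity is regressed on a panel of per-variant numeric
scores of two kinds:

* **sequence-based** (tag `seq`): 22 dbNSFP-style pathogenicity
  predictors, 4 VARITY models and 5 esm1v models — 31 columns;
* **structure-based** (tag `struct`): 16 FoldX empirical energy terms and
  21 frustration-derived scores — 37 columns;

68 columns in total.  Scores enter as given; the pipeline never rescales
features except inside PLSR (standardization) and never imputes missing
cells — rows missing a required feature are excluded from fits and
flagged unpredictable at prediction time.

### Forward selection with iterative outlier removal

Selection is greedy: starting from the intercept-only model, each round
adds the candidate score giving the largest R², provided the candidate's
coefficient passes a two-sided t test at p < 10⁻³.  The loop stops when
the best gain falls below ΔR²_min = 0.005 (the plateau rule), when no
candidate reaches significance, or at a feature-count cap.  The scan is
vectorized: with Q an orthonormal basis of the current design, each
candidate's gain is its squared partial correlation with the current
residual, and the t test on that partial correlation is algebraically the
t test of the added coefficient in the augmented OLS fit (asserted
against statsmodels in the test suite).  Exact ties between candidates
resolve to the lexicographically smallest name, which makes selection
invariant to column order.

The selected-variable OLS fit is then screened for outliers with two
standard diagnostics: Cook's distance D_i > 4/n, and |externally
studentized residual| > 3 — the latter being the numeric surrogate for a
Q-Q plot inspection.  A variant flagged by *either* rule (union; an
intersection mode is available) is removed, and selection restarts on the
reduced data, up to 10 iterations or until an iteration flags nothing
new.  Removed variants are never reinstated, and every removal is logged
with its iteration index.

A property of the 4/n rule worth knowing: because the threshold adapts to
the shrinking sample and ordinary noise keeps producing moderate
influence values, repeated trimming rarely reaches a fixed point on noisy
data and will continue to remove observations until the iteration cap.
The cap (default 10) is therefore a real model parameter, not a safety
valve; training R² after trimming exceeds the generating R² for exactly
this reason.  The loop aborts with a diagnostic if removals would leave
fewer than p + 3 observations.

### Regression engines

MLR is ordinary least squares (statsmodels) with classical homoskedastic
p-values; influence diagnostics (leverage, Cook's D, studentized
residuals) come from the same fit.  PLSR is univariate NIPALS, written
here so that per-component predictions are available in one pass:
NIPALS scores are nested, so a single max-k fit yields the prediction of
every smaller model, which makes leave-one-out PRESS over all component
counts O(n) fits instead of O(n·k).  Predictors are standardized to zero
mean and unit variance inside PLSR (the 68 scores have heterogeneous
scales); zero-variance columns are dropped with a recorded warning.  The
component count is the PRESS argmin, ties toward fewer components.
sklearn's PLSRegression serves as an independent oracle in the tests,
never as the engine.

### Validation and test-set R²

Validation uses repeated random subsampling — 20 independent splits, each
withholding 10 variants — not a k-fold partition.  Test-set R² is
reported primarily as the squared Pearson correlation between predicted
and observed (the convention matching predicted-vs-observed scatter
reporting); the variance-explained form 1 − SSres/SStot is recorded
alongside, since the two differ off the 45° line and the choice is a
genuine convention ambiguity.  RMSE is in activity percentage points.

### Classification

Activity is binarized at a cutoff c: label 1 (impaired) iff activity < c;
a value exactly at the cutoff is labelled 0.  AUC is the Mann-Whitney
statistic with half-credit for score ties — exact and reproducible, and
identical to trapezoidal ROC area.  The cutoff grid runs 70–150 % in 1 %
steps by default (range and step configurable); grid points that leave a
class empty are skipped and recorded.  Confusion matrices default to the
Youden-J operating threshold on the score, ties toward the lower
threshold; a fixed threshold can be supplied instead.

### GNM flexibility

The Gaussian Network Model uses a Cα contact Kirchhoff matrix with
cutoff 7.3 Å and uniform spring constant γ = 1 (standard coarse-grained
practice; both configurable).  Mean-square fluctuations are the diagonal
of the pseudo-inverse, computed from the eigendecomposition with zero
modes identified by λ < 10⁻⁸ · λ_max.  Exactly one zero mode is required;
a disconnected contact graph is an error that names the components rather
than a silent near-singular inversion.  Multi-chain selections
(monomer/dimer/tetramer) are caller-specified residue subsets.

### Prediction and annotation

Final predictions are reported raw and clipped to [0, 150] %; activity
groups AG1 [0, 20), AG2 [20, 50), AG3 [50, 80), AG4 [80, ∞) are assigned
on the clipped value, since the groups live on the bounded activity
scale.  Structural-location annotation uses Cα-distance proxies with
documented defaults — near_DNA if any of the variant residue's copies
lies within 8 Å of a DNA-chain site, else interface within 8 Å of the
partner protein, else buried if ≥ 16 protein neighbours lie within 10 Å,
else surface — with precedence near_DNA > interface.  A supplied
annotation column overrides computation.

## The synthetic-data generator

The generator emulates the *shape* and the *planted structure* of a
variant-effect study table, not the marginal distributions of real
scores.  Score marginals are i.i.d. uniform on [0, 1] (real marginals are
unspecified by any source the generator could copy); activity is exactly
linear in the informative scores plus Gaussian noise, truncated to the
activity range.  Noise is solved analytically from a target generating
R²: with uniform scores, signal variance is Σβ²/12.

Scores with a requested Pearson correlation to activity are produced by a
Gaussian copula against the standardized pre-truncation activity; the
latent correlation is inflated by √(π/3) ≈ 1.023 because mapping a normal
margin to uniform attenuates Pearson's r by exactly that factor.  The
achieved correlation was verified by Monte-Carlo (20 seeds, n = 500:
within ±0.06 of the target, slight positive bias from the
lighter-than-normal tails of the activity variable).

Outliers are planted by shifting activity ±`outlier_shift` — a mechanism
the feature model cannot represent, mimicking variants whose structural
scores misdescribe their real conformational effect — never by corrupting
features.  Truncated rows keep their outlier flag.  Ground truth (true
coefficients, intercept, noise SD, outlier flags) always accompanies the
data.

**Study-conditions benchmark** (the default of `study_config` and of
`scripts/acceptance.py`): 150 variants × the full 68-score layout; five
informative scores — VEST4_S (−60), foldx_total_energy (−45),
delta_energy_configurational (−40), REVEL_S (−35),
delta_frustration_mutational (+30) % activity per score unit, signs
chosen so pathogenicity/destabilization-like scores lower activity;
intercept 150 (with uniform score means of 0.5 this centres mean
activity at 75 %); generating R² 0.9
(noise SD ≈ 9.3 %); five planted outliers shifted ±60 %.  Twenty
generator seeds give stable aggregates (mean held-out test R² ≈ 0.93,
planted-outlier recall ≈ 0.99, informative recovery 20/20) at about a
minute of total runtime; these sizes were chosen to make the benchmark
cheap to rerun while keeping split-level noise small.

What passing these tests shows: the pipeline recovers a known sparse
linear signal among 63 irrelevant scores, flags gross activity-shift
outliers, and estimates held-out accuracy consistent with the generating
noise.  What it does not show: performance under correlated real score
panels (dbNSFP predictors are strongly inter-correlated), non-linear
score-activity relationships, heteroskedastic assay noise, or the
feature composition of the deposited measured tables — reproducing the
published per-protein values requires those tables (see README).

## Numerical choices

* Zero-mode tolerance λ < 10⁻⁸ λ_max; eigendecomposition via LAPACK
  `eigh` on the dense symmetric Γ.
* Forward-selection candidate ties: lexicographic; cutoff-scan AUC ties:
  lowest cutoff; Youden ties: lowest threshold; PRESS ties: fewest
  components.
* Perfect-fit guard: when a fit's RMSE is below 10⁻¹⁰ of the fitted-value
  scale, residuals are rounding noise and no outlier is flagged (Cook's
  distance of numerical noise is otherwise unstable).
* External studentization requires n > p + 2; the selection loop enforces
  it before and after removals.
* Degenerate inputs are errors, not warnings: constant response, rank
  deficiency (the collinear set is named via pivoted QR), single-class
  labels, disconnected contact graphs, insertion-coded PDB residues.
* Seeds: one master seed; per-stage seeds derived as the first four bytes
  of SHA-256(f"{seed}:{stage}") mod 2³¹, so stages are decoupled and any
  stage can be rerun in isolation.

## Known limitations

* The exact composition of the 21 frustration-derived scores in the
  deposited tables is not documented; the `default21` schema (per-method
  wild-type/mutant/delta energy and frustration sums plus
  highly-frustrated count changes) is this package's versioned choice,
  and deposited column headers should override it when available.
* The iterative 4/n outlier rule over-trims on noisy data (see above);
  interpret the post-trimming training R² accordingly and prefer the
  held-out metrics.
* Location annotation is a Cα-proxy heuristic with round-number cutoffs,
  not a solvent-accessibility calculation.
* The package consumes FoldX/frustration/dbNSFP outputs as tables; it
  never executes those tools, and no attempt is made to emulate their
  real output distributions.
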