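# Methods

## Scope and data model

The package implements a prognostic-modelling chain for aneurysmal
subarachnoid hemorrhage (aSAH) oriented at the structure of the Tirilazad
trial database: n = 3551 patients, 30 clinical predictors, and the 5-level
Glasgow outcome score (GOS) at 3 months.  The real database is not publicly
available, so all empirical claims made by the test suite and the acceptance
script are *parameter-recovery* claims on synthetic cohorts, never
reproductions of the original data analysis.

Outcome coding: the latent outcome is oriented higher = worse so that harmful
predictors carry positive coefficients, matching the sign convention of the
published regression tables.  The stored `gos` column is the reversed GOS
(1 = good recovery … 5 = death); the conventional scale is `6 - gos`.

## Synthetic cohort generator

Each of the 30 predictors is sampled independently: binary predictors as
Bernoulli with documented prevalences (0.05–0.80, e.g. myocardial infarction
0.05, normal motor response 0.80), continuous predictors as Normal with
clinically plausible moments (age ~ N(52, 12²) years, mean arterial pressure
~ N(105, 15²) mmHg, admission temperature ~ N(37.2, 0.7²) °C, …).  These
marginals are fixture data chosen once to be realistic for an aSAH trial
population; they are not estimates from any dataset.

The latent outcome is linear, y = α + Xβ + ε with ε ~ N(0, σ²), σ = 1 by
default.  Two generating coefficient sets are available — the published
frequentist multivariable fit ("table1") and the published Bayesian posterior
means ("table2").  The two sources disagree for some predictors (cerebral
infarction: 0.790 vs 0.9499) and the discrepancy is unexplained; the
generator therefore supports either set as truth but never both at once.
Predictors absent from the chosen set get a null effect.

Ordinal coding places four thresholds at latent-scale quantiles producing a
realistic 3-month outcome mix (40% good recovery, 25% moderate disability,
15% severe disability, 5% vegetative, 15% dead).  Thresholds are recomputed
analytically from the spec's moments (`CohortSpec.reset_thresholds`), so
edits to coefficients or noise keep the mix stable.

Optional heteroscedasticity scales the noise SD linearly in standardized age
(slope 0.5, floored at 0.1): the published analysis reports heteroscedasticity
without attributing it, and age is the dominant continuous predictor.  Note
that even homoscedastic latent noise yields a Breusch–Pagan rejection when the
*ordinal* outcome is modelled linearly — discretization induces genuine
level-dependent residual variance.  This is a feature of the emulation, not a
bug: it reproduces the qualitative finding that the untransformed outcome is
heteroscedastic.

What the generator does **not** emulate: predictor correlations (the real
data show strong collinearity between e.g. neurological grade and motor
response; synthetic VIFs are all ≈ 1), missing data, treatment arms, or any
nonlinear/latent structure.  Consequently, passing recovery tests shows the
estimators are correct and well calibrated under the assumed generative
model — it says nothing about their performance on the real database (in
particular the published AUC = 0.85 is not a reproduction target).

## Linear stage

OLS with intercept via statsmodels; two-sided t-tests and 95% CIs.  The
5-level GOS is treated as continuous for this fit (the published coefficient
magnitudes only make sense that way); the clean latent outcome is also
exposed for recovery tests.  Collinearity: VIF_j = 1/(1 − R²_j) from
regressing column j on the rest; tolerance = 1/VIF.  Heteroscedasticity: the
Breusch–Pagan LM test (the published analysis names no specific test).  Odds
ratios: logistic regression on poor outcome, default cut {reversed GOS > 2},
i.e. good recovery/moderate disability vs worse — a standard aSAH split;
quasi-separation (|log OR| > 15) is flagged rather than reported.  No
multiple-testing correction is applied, matching the raw-p-value convention
of the source tables.

## Hierarchical meta-analysis

Normal–normal hierarchy on study log odds ratios with the per-study effects
marginalized analytically, leaving a 2-D posterior over (μ, τ) sampled with
emcee (affine-invariant ensemble; 4 independent ensembles of 32 walkers,
≥ 200 burn-in steps each; split-R-hat on pooled per-ensemble chains, flagged
above 1.1).  Priors: μ ~ N(0, 10²) on the log-OR scale, τ ~ Half-Normal(1) —
weakly informative choices standard for this model class; the original
analysis states none.  Whether the original used binomial likelihoods on 2×2
tables or normal approximations on log ORs is unstated; the normal
approximation is implemented here.  Study-level effects θ_i are reconstructed
conditionally for shrinkage diagnostics.  The published consensus-OR table
cannot be reproduced because the contributing studies' data are not printed;
model-form fidelity and recovery of a known consensus OR from simulated
studies are what the tests establish.

## Bayesian regression

Same linear model as OLS with Normal coefficient priors.  Uninformed:
N(0, 100²) (the WinBUGS-era convention); informed: mean/SD of the
meta-analysis posterior of the log OR, with an SD floor of 1e-3.  Noise
scale: Half-Cauchy(0, 5·sd(y)).  Sampling is Gibbs: the full coefficient
block has a conjugate multivariate-normal conditional (one joint draw per
iteration), and log σ is updated by Neal's stepping-out slice sampler.  This
mixes nearly iid at n in the thousands, so defaults of 4 chains × (1000
warm-up + 2000 kept) give MC errors two orders below posterior SDs.  The
published "Start 5000 / Sample 95001" is read as burn-in/kept-draws and not
replicated exactly.  MC error uses batch means (20 batches).  Whether the
original model was linear on GOS or logistic is unstated; linear on the
reversed GOS is implemented (the published magnitudes support this reading).

## Perceptron

Architecture fixed at 30 → 11 tanh → 5 linear.  The output layer is linear
with squared-error loss on one-hot targets (fidelity to the defining
equations rather than to SPSS internals); predicted class is the argmax, and
the scalar severity score renormalizes the clipped outputs as approximate
class probabilities (least-squares-on-indicators estimates conditional class
probabilities; a softmax link was rejected as badly calibrated for this
loss).  Inputs are standardized inside training (means/scales stored with
the parameters).  Initialization N(0, 1/√fan_in), seeded.  The 60/40 split
uses round-half-up, giving exactly 2131/1420 at n = 3551.  Importance is the
Garson connection-weight method — per-hidden-unit input shares weighted by
absolute outgoing strength, renormalized over inputs — chosen to match the
"weighted average of connection strengths" description; permutation
importance is available as an alternative.  AUC is the Mann–Whitney
statistic with midranks.

## Bayesian-regularized network

Objective F(θ) = β·E_D + α·E_W with E_D = ½Σ‖residual‖², E_W = ½‖θ‖² (the
evidence-framework convention, so a Gaussian likelihood with precision β and
an isotropic Gaussian prior with precision α).  MAP by L-BFGS with analytic
backprop gradients.  The weight posterior is a Laplace approximation with
Gauss–Newton curvature H = β·JᵀJ + α·I; stationarity of the supplied MAP is
checked with the Newton decrement gᵀH⁻¹g (scale-invariant, threshold
0.1·√P), and a non-PD Hessian falls back to jittered Cholesky with a warning
flag.  α and β are fixed by configuration; evidence-maximization updates are
out of scope at default settings.  Posterior predictives draw weights from
the full Gauss–Newton Gaussian; for the 5-output ordinal network the Gaussian
observation model restricted to one-hot targets yields p(y=k|f) =
softmax(β·f)_k, averaged over draws; single-output models produce a Gaussian
mixture on a grid.  Log evidence is the standard Laplace formula
N/2·ln β − N/2·ln 2π + P/2·ln α − F(θ_MAP) − ½·ln|H|.

The machinery is written against a minimal model interface; a plain linear
map shares it so that conjugate closed forms (ridge MAP, posterior SD,
marginal likelihood, predictive quadrature) serve as exact oracles in the
tests.  The published 11-entry hidden-to-output weight vector is descriptive
output of the original run on unavailable data, not a reproduction target.

## Fuzzy inference

Cluster memberships are fractional presence, |present ∩ cluster|/|cluster| —
the minimal function satisfying "all members present ⇒ membership 1".  Rule
activations follow the min-conjunction ladder (w_low = m_d,
w_raised = min(m_d, m_s), w_high = min(m_d, m_s, m_n)).  Because the three
consequents form an ordinal severity scale, defuzzification first applies
ordinal-dominance weighting — w_high keeps its activation, w_raised keeps
only its excess over w_high, w_low its excess over w_raised — then the usual
Mamdani clip/max-aggregate/centroid.  Without this, a patient fulfilling all
three clusters would accumulate low-suspicion mass and the centroid could
never exceed the 2.5 cut-off, contradicting the rule system's own intent.

Output sets on the [0, 3] universe: low = triangle(0, 0, 1.5),
raised = triangle(0.75, 1.5, 2.25), high = trapezoid(1.9, 2.75, 3, 3) —
configuration data (YAML-exposed) chosen so a fully active high set has
centroid ≈ 2.62 > 2.5.  The source describes no membership shapes.  The
"greater than 2.5 clusters" cut-off is implemented as a centroid threshold
(it is paired with the centroid technique in the source); a raw
fulfilled-cluster count is recoverable from the memberships if preferred.

`classify_case` evaluates rule antecedents on presence-saturating
memberships by default (a cluster engages once *some* member is present,
which is how the rules are phrased); the graded fractional antecedent is an
option.  Monotonicity (adding a risk factor never lowers the crisp score)
holds for the presence antecedent; under graded antecedents extra demographic
factors strengthen the low-suspicion rule and can legitimately lower the
centroid, so no such guarantee is made there.  Centroid integration is
trapezoidal on a 2001-point grid (agrees with a 200001-point oracle to
< 1e-4); defuzzifying a discrete predictive mass uses the exact weighted mean
instead, since trapezoid endpoint half-weights would bias a 5-point grid.
Max/min, left-of-mean and right-of-mean defuzzifiers are read as
plateau-midpoint, smallest-maximizer and largest-maximizer respectively.

Pipeline ordering: fuzzy inference runs strictly after the Bayesian network
stage (learning must finish before crisp rules are applied); the
orchestrator raises a stage-order error otherwise.

## Numerical choices and problem sizes

Tests run the MCMC stages at reduced sizes (2–4 chains, hundreds of warm-up
draws) and the recovery experiments at the full n = 3551 once each; the whole
suite completes in about a minute on one CPU, and the acceptance script in
well under one.  Degenerate inputs are refused loudly: cohorts below n = 50,
rank-deficient designs (with the collinear columns named), single-class
outcomes for AUC/odds ratios, all-zero weights for importance, empty
predictive distributions, fewer than 200 samples for batch-means MC error.
Seeds flow through `numpy.random.default_rng` everywhere; identical seeds
give bitwise-identical cohorts and reports (timestamps and durations aside).

## Known limitations

Independent predictors make the collinearity diagnostics nearly trivial on
synthetic data; the VIF machinery is exercised by dedicated fixtures instead.
The Laplace weight posterior is unimodal by construction and cannot represent
multimodality of the network posterior; the Monte-Carlo predictive inherits
this.  The meta-analysis assumes normal within-study likelihoods, which is
questionable for very small studies.  The fuzzy output sets are conventions,
and conclusions that depend on their exact shape (anything but the ordering
and the 2.5 threshold semantics) should not be over-read.
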