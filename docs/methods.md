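# Methods

## Task and data model

The package models a binary economic choice task: on each trial a
participant chooses between a fixed *baseline* (the lowest effort level for
1 credit, subjective value defined as exactly 1) and an *offer* combining
one of five higher effort levels (2–6) with one of five rewards (2, 4, 6,
8, 10 credits), within one effort domain (cognitive or physical). A run
holds 150 trials, 75 per domain, randomly interleaved. Offer effort levels
map onto the dimensionless code E = (level − 1)/5, giving the five codes
0.2–1.0; with five levels onto five codes this monotone map is the only
consistent assignment. Choice data are long-format tables (one row per
trial); trials with no response are recorded as `missing` and excluded from
every likelihood and summary.

## Subjective value and choice rule

Four discounting families give the offer's subjective value from reward R,
effort code E and a subject-specific steepness k ≥ 0:

- linear: SV = R(1 − kE)
- hyperbolic: SV = R/(1 + kE)
- parabolic: SV = R − kE²
- exponential: SV = R·e^(−kE)

Negative SVs are legal outputs of the linear and parabolic forms (they are
subtractive by construction) and are never clipped. The baseline never
passes through a discount function; its value is the constant 1.

The probability of accepting the offer is a two-option softmax referenced
to that unit baseline, Pr(offer) = e^(βSV)/(e^β + e^(βSV)). It is computed
as a logistic of β(SV − 1), which is algebraically identical and immune to
overflow for large β·SV (β·SV can reach ~10³ at the search bounds). β ≥ 0
is enforced: β indexes choice consistency, and a negative value would
invert preferences, which is outside the model space.

## Candidate model space

A candidate model is a family per domain plus a parameter-sharing class:

1. shared k, shared β — identical valuation and consistency across domains;
   4 models (one per family);
2. separate k per domain, shared β — 16 models (4 × 4 family pairs);
3. separate k and separate β — 16 models.

Enumeration order is deterministic (class 1, 2, 3; cognitive family
outermost), which fixes tie-breaking and report layout.

## Fitting

Each model is fitted to one subject's full run (both domains in a single
likelihood — the sharing classes couple domains, so per-domain fitting
would leave shared-parameter models ill-defined). The negative
log-likelihood sums −log p(observed choice) over non-missing trials;
non-finite intermediates and out-of-box parameters return +inf so the
optimiser treats them as infeasible.

Optimisation is multi-start Nelder–Mead (derivative-free simplex): 20
restarts by default with starting values k ~ U(0.01, 3) and
β ~ U(0.5, 20), covering the effect sizes the task can express (SV range
0–10) and plausible consistency levels. The search box is k ∈ [0, 10],
β ∈ [0, 100]; the β ceiling is deliberately loose, so near-deterministic
subjects can run β to the boundary — a property of pure maximum likelihood
on separable data, discussed under limitations. Simplex tolerances default
to xatol 1e−5 / fatol 1e−7; the batch recovery experiments relax them to
1e−4 / 1e−6, which changes estimates far below their sampling error while
roughly halving run time.

For the separate-k/separate-β class the likelihood factorises across
domains (each domain's (k, β) touches only that domain's trials), so those
4-parameter models are solved exactly as two independent 2-parameter
problems, and `fit_all_models` caches the 8 per-domain solutions (4
families × 2 domains) across the 16 models of the class. Per-domain
optimisations are seeded by (seed, domain, family), so a cached solution is
bit-identical to a direct `fit_model` call.

AIC = 2p + 2·NLL and BIC = p·ln(n) + 2·NLL use the subject's count of
non-missing trials as n (the likelihood is a product over exactly those
trials). Group comparison sums the criterion across subjects
(fixed-effects comparison; per-subject winner counts are also reported so
either convention can be inspected). Ties break toward fewer parameters,
then enumeration order.

## Synthetic data

The generator reproduces the task's design: per domain, the 5 × 5
effort-by-reward factorial repeated n/25 times (3 repetitions at the
default 75), the two domains interleaved by a seeded permutation. Offer
onsets accumulate the task's timing (3 s offer, 2–4 s uniform jitter,
2.4 s choice window, 2–4 s inter-trial jitter) so exported regressor tables
have realistic time stamps. Choices are Bernoulli draws from the softmax of
the generating subjective value; a configurable missing rate (default 0)
exercises exclusion logic. Training blocks simulate 10 trials per effort
level 1–6 per domain with per-level success probabilities (default 0.85,
matching reinforcement above 80%).

Simulated reaction times are drawn with a mild dependence on decision
difficulty purely so the schema is complete; nothing downstream models RT.
What the generator does *not* emulate: sequential effects, fatigue or
learning drift, lapses correlated with difficulty, and any within-subject
deviation from the assumed discounting family. Passing recovery tests
therefore show the estimator is correct for data that follow the model, not
that real choices do.

## Behavioural statistics

Acceptance summaries compute per-subject cell proportions first, then the
group mean ± between-subject SEM; empty cells are reported absent, never as
zero. The choice regression fits, per subject and domain, a binomial GLM of
choice (offer = 1) on effort code, reward and the training reinforcement
rate at the offer's effort level, all entered simultaneously on their
natural scales (normalising coefficients to t = β/SE makes the group test
scale-invariant, so covariate scaling is innocuous). Group inference is a
two-sided Wilcoxon signed-rank of the normalised statistics against zero,
exact below n = 25 and normal-approximate above. Degenerate fits —
zero-variance covariates, or |t| > 10³ indicating complete separation — are
flagged and excluded from the group test with a reported count, never
silently dropped.

d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate), with extreme rates 0 and 1
continuity-corrected to 1/(2N) and 1 − 1/(2N) using that rate's own trial
count. The difficulty index is −|p − 0.5| from the fitted softmax: 0 at
indifference, −0.5 at certainty.

## Recovery experiments

**Parameter recovery** (defaults: 30 subjects × 150 trials, generating
model separate-k/separate-β with hyperbolic cognitive and parabolic
physical, β = 8 per domain, k ~ U(0.2, 2)) refits only the generating model
and reports bias, RMSE and Spearman correlation between true and estimated
parameters. When a generating β is 0, choices are coin flips and k is
unidentifiable; the report flags this instead of printing a spurious
correlation.

**Model recovery** (defaults: 20 replicates × 20 subjects, full 36-model
refit at 4 restarts — the restart count is the cost driver and the
likelihood surfaces here are well-behaved) simulates from the
separate-k/separate-β hyperbolic/parabolic specification and asks whether
summed AIC and BIC select it. The default generating regime is deliberately
*strongly identified*: k_cog ~ U(0.5, 3), k_phys ~ U(1, 6), and clearly
distinct stochasticity per domain, β_cog ~ U(10, 16) versus
β_phys ~ U(0.7, 1.8). The sharing classes are only distinguishable when the
two domains' βs genuinely differ at a magnitude where β has likelihood
curvature: when the generating βs are similar (or both large enough that
choices saturate), the shared-β model fits within a fraction of a nat per
subject and the fourth parameter cannot pay its AIC (2) or BIC (ln 150 ≈ 5)
penalty — selection then correctly collapses to the more parsimonious
class, and the experiment says nothing about the machinery under test.
The complementary case (generating from the shared class and checking that
separate-parameter models do *not* win under BIC) is covered in the test
suite.

**Null calibration** checks the size of the group signed-rank test:
1,000 cohorts whose choices are independent of every covariate
(generating β = 0), 12 subjects each — small because the property under
study is the test's size, not its power, and the exact signed-rank
distribution applies below n = 25.

All experiment seeds derive from a single user seed via independent
substreams, so every report is reproducible bit-for-bit from (config,
seed), and subjects, replicates and experiment stages are statistically
independent.

## Numerical choices and degenerate inputs

- Log-likelihoods use `log_expit` (log-domain logistic) throughout; no
  naive exponentials of β·SV appear anywhere.
- Offer rewards outside {2, 4, 6, 8, 10}, effort levels outside 2–6,
  unknown domains, unknown choice labels and unknown family names are
  rejected with diagnostics at the I/O boundary and in the core types.
- All-offer (or all-baseline) subjects are legal: the optimiser returns a
  boundary-consistent estimate (no discounting signal), and the likelihood
  remains finite.
- A subject-domain regression with a single outcome value is flagged, not
  fitted.

## Known limitations

- β is weakly identified once choices are nearly deterministic: the
  likelihood is almost flat in β above ~20 for consistent subjects, so β
  estimates can drift to the search ceiling while fitting the data
  essentially perfectly. Discount parameters k remain interval-identified
  in that regime; for subjects who accept every offer the interval spans
  all small k, which is the main noise source in parameter-recovery rank
  correlations (they sit close to, and sometimes only just above, 0.9
  under the default recovery conditions).
- Group model comparison is fixed-effects (summed criteria); no
  random-effects or exceedance-probability selection is provided.
- No hierarchical shrinkage: each subject is fitted independently, so
  scarce data (e.g. 50-trial runs) produce visibly noisier estimates.
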