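# Methods

## Discount-rate estimation

Each choice item offers a smaller-sooner reward (SSR) now against a
larger-later reward (LLR, always 10 currency units) after a verbal delay.
Value is hyperbolic, V = A/(1 + kD). Delays are converted to weeks with
1 day = 1/7 week, 1 calendar month = 365.25/12 days ≈ 4.3482 weeks and
1 year = 365.25/7 weeks. This convention is not arbitrary: the second
study battery's smallest and largest item indifference rates then have
natural logs of −5.49 and −1.79, which are exactly the fitted log-k extremes
a cohort of self-consistent responders can receive, and no day- or
month-based unit reproduces both. Amount currency cancels in the
indifference rate (LLR/SSR − 1)/D, so pound and euro batteries are treated
as numerically identical.

Fitting is enumeration-and-match: the candidate set is exactly the battery's
item indifference rates (84 for the first battery, 64 for the second),
de-duplicated at an absolute tolerance of 1e−12. For each candidate the
predicted choice is SSR iff SSR strictly exceeds the discounted LLR; exact
indifference predicts LLR (the "otherwise" branch of the rule). The retained
k is the candidate with the highest match proportion against the observed
vector; when several candidates tie, their geometric mean is taken, which
always lies inside the tied range. No out-of-range sentinels or interval
midpoints are added: an all-LLR responder receives the smallest candidate,
an all-SSR responder the largest, so fitted log k is bounded by the battery
geometry. log k (natural log) is the analysis variable because k is roughly
exponentially distributed across people.

Degenerate inputs: empty observation sets and duplicate
(participant, item) pairs are rejected; a single-participant cohort's pooled
match proportion is that participant's.

## FTR coding

The classifier is a closed-vocabulary keyword matcher, deliberately not a
parser: the elicitation design fixes the target verb per item, so
present-tense detection checks the item's declared present-form inflections,
and future detection checks a short list of future auxiliaries. Multiword
markers ("going to", "staat op het punt") match as contiguous token
sequences, so "is/are/am going to" all match via the "going to" subsequence.
Normalization lowercases, removes parenthetical material (participants were
told to omit it, so echoed certainty cues must not be scored), expands
contractions ("'ll" → will, "won't" → will not, "gonna" → going to), and
tokenizes on word characters. "will" inside "will not" still marks future:
the schema keys on auxiliaries, not polarity.

Modal dominance is the load-bearing rule: any modal marker — low-certainty
(*might*, *possibly*, *misschien*) or high-certainty (*definitely*,
*zeker*) — suppresses both classes, because the modal then carries the
certainty semantics rather than the tense. Consequently future + present +
modal-dominated proportions need not sum to 1 and future and present are
mutually exclusive by construction.

The shipped English and Dutch lexicons are editable plain-text files; the
published class schema names the anchor words but gives modal vocabulary
only by example, so the lists here are an explicit, overridable
reconstruction. Temporal adverbials alone do **not** mark future by default;
an `adverbials_count_as_future` toggle (with an `[adverbial]` lexicon
section) exists for the alternative reading.

Per-participant scores are means over non-excluded items only; a participant
with no scorable responses is reported missing, never as zero.

## Mediation model

Predictor X is the language indicator (Dutch = 0, English = 1), mediator M
is the participant's future-tense proportion standardized over the pooled
sample (z-scaling the binary indicator would halve α, contradicting the
fitted scale, so language stays 0/1 and log k stays raw). The outcome
equation adds the fut × language product formed **after** standardizing the
mediator.

With flat priors the posterior of each normal linear equation is available
in closed form — σ² has a scaled inverse-χ² marginal with n − p degrees of
freedom and coefficients are conditionally multivariate normal around the
least-squares solution — so draws are sampled exactly and reproducibly
(4,000 by default, seeded; the two equations share no parameters and use
independent child streams). This is distributionally identical to what an
HMC sampler with uniform priors converges to, without Monte-Carlo
convergence diagnostics. Tests cross-check posterior means against
closed-form least squares and verify 95% interval coverage by simulation.

Summaries use central (equal-tail) quantile intervals — the posteriors here
are symmetric — and *pp*, the fraction of draws whose sign matches the
directional hypothesis (default: indirect effects hypothesized negative, so
*pp* = P(draw < 0)). Indirect-effect point estimates are posterior means of
the per-draw product; the product of posterior means is exposed separately
(`point_indirect`) since that is what a coefficient table implies. Bayesian
R² is computed per draw as var(Xβ)/(var(Xβ) + σ²); the outcome vector does
not enter this residual-σ² form, so the function takes only coefficient
draws, σ draws and the design.

The sample-size rule of thumb (50 + 8m per group of independently estimated
slopes) is provided as `power_rule`; m = 8 predictors and two language
groups give N > 228.

## Synthetic cohorts

The generator realizes the mediation equations directly at the studies'
fitted coefficients and sample sizes (study 1: 113 English / 122 Dutch;
study 2: 301 / 305), so parameter recovery is well-posed by construction.
Residual scales are not published; they are solved once, in closed form
(`scripts/calibrate_generator.py`), from two constraints: the pooled latent
variance of the standardized mediator must be 1 (giving σ1 = 0.734 / 0.656),
and the within-language log-k variances must match the descriptive SDs
(giving σ2 = 1.985 / 1.341, averaged across languages on the variance
scale). The proportion back-transform (grand mean, grand sd) is solved from
the language-wise proportion means against λ1 and λ1 + α; clipping to [0, 1]
is logged, and affects <1% of participants at study-1 defaults. At study-2
defaults ~7% of (mostly Dutch) participants clip at 0 — unavoidable, and
arguably faithful: the real study-2 Dutch distribution piles up at the floor
(minimum 0.00, lower quartile 0.04), so a Gaussian matching its mean and SD
must put several percent of mass below zero. A Gaussian latent with affine
back-transform was chosen over a Beta law to keep linear-equation recovery
exact.

Choices follow the hyperbolic rule at the participant's latent k with an
independent symmetric flip at rate ε = 0.06; because refitting can only meet
or exceed the generating k's agreement, the refit match proportion lands at
~94%, matching the studies' reported predictive accuracy. Elicitation text
comes from a small per-language template grammar (subject–auxiliary–verb
orders appropriate to each language), with a modal adverb spliced in at rate
0.10 per response — emulating the substantial share of real responses that
are modal-dominated (observed future + present proportions sum well below
1). Ground-truth labels are emitted alongside, and the classifier reproduces
them on 100% of templated responses.

What the generator does **not** emulate: real linguistic variation (it is a
fixture grammar, not a language model), item-factor effects (distance,
modality condition, and prediction/intention mode are carried as metadata
but do not modulate response probabilities), demographic covariates, and
asymmetric choice lapses. Passing recovery tests therefore demonstrate the
estimators are correct under the stated model, not that the model captures
every feature of human data. One consequence worth knowing: measuring the
mediator from a finite number of coded utterances (26/24 items, modal
injection) attenuates the fitted mediator→outcome slopes relative to the
generating values, so full-chain indirect estimates are biased toward zero
even though their sign is stable across seeds; the parameter-recovery
harness accordingly evaluates `fit_mediation` on the generator's latent
standardized scale, where the generating coefficients are well-defined.

## Pipeline and reporting

The orchestration (`run_pipeline`) is a pure function of (inputs, config,
seed): identical runs produce byte-identical result files, so provenance
records the seed, a config hash, and the package version rather than a
wall-clock timestamp. Participants missing either task are dropped listwise
with a logged count; duplicated participant ids are schema errors.
Descriptive tables report mean, sample SD (n − 1), median, MAD with the
1.4826 normal-consistency constant (a config switch, since conventions
vary), min/max, and linear-interpolation quartiles. Correlations are
Pearson product-moment with two-sided p-values and conventional
significance stars.

Known limitations: only English and Dutch lexicons ship (the schema is
extensible by lexicon file); the discounting module fits a single hyperbolic
k per participant (no exponential or quasi-hyperbolic alternatives, no
softmax choice likelihood); the mediation is single-level with exactly two
groups and flat priors. The first study's published log-k extremes are not
reproducible as candidate points under any delay convention tried — the
week convention is validated against the second study's battery, whose
extremes it reproduces exactly.
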