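# Methods

This note documents the models, defaults, and numerical choices behind
`tactsim`, and what the synthetic cohort does and does not emulate.

## Staircase protocols

Each protocol tracks one stimulus variable under a transformed up/down
rule. Trial indices are 1-based; trials 1–`rule_switch_trial` (default
10) follow one-up–one-down (step easier after an error, harder after a
correct response), and from the next trial onward a two-correct rule
applies: a step harder requires two consecutive correct responses (the
streak counter then resets), while any error immediately steps easier
and resets the counter. The streak counter is zero throughout the
one-up–one-down phase, so the first trial of the second phase always
starts a fresh pair. The order-judgement protocol is one-up–one-down
throughout, with multiplicative steps: ×0.9 after a correct response,
×1.1 after an error, so the tracked asynchrony can never reach zero.

Defaults per protocol (all configurable through `make_protocol`
overrides):

| protocol | tracked variable | start | step | trials | limits |
|---|---|---|---|---|---|
| detection | stimulus amplitude (μm) | 20 | ±2 μm | 24 | [1, 350] |
| amplitude discrimination | difference from 100 μm standard (μm) | 100 | ±10 μm | 20 | [10, 250] |
| frequency discrimination | difference from 30 Hz standard (Hz) | 10 | ±1 Hz | 20 | [1, 20] |
| temporal order judgement | onset asynchrony (ms) | 150 | ×0.9 / ×1.1 | 20 | [1, 500] |

The detection and frequency step sizes and all floors/ceilings are
package defaults chosen so that plausible child thresholds are reachable
within the trial budget: the detection staircase must reach ~6–12 μm
from 20 μm in 24 trials, and a stimulus must always exist, hence the
1 μm floor. Discrimination limits are expressed on the difference scale
so the comparison stimulus stays within the 0–350 μm / 0–50 Hz device
range and above the standard. Values are clamped to the limits after
every step.

Each run begins with a practice gate: blocks of three trials at the
starting value, repeated until one block is answered fully correctly,
with at most 10 blocks before the run is abandoned
(`PracticeGateError`). Abandoned runs contribute no outcome row —
exactly as a non-compliant child contributes no data — which means
simulated participants with latent thresholds near or above the
starting value are occasionally missing from a protocol. Target sites
are independent fair coin flips per trial; no run-length constraint is
imposed on the pseudorandomization.

A *reversal* is defined as a sign change in the sequence of non-zero
trial-to-trial steps of the tracked variable; trials on which the value
did not move (two-correct holds, clamping) are transparent to the
count. The threshold estimate is the arithmetic mean of the tracked
variable over the final five non-practice trials — only values actually
presented count, never the post-update value after the last response.

## Observer model

The probability of a correct 2AFC response at tracked level `x` is
`p(x) = 1/2 + (1/2 − λ)·Φ((x − θ)/σ)`. The cumulative Gaussian was
chosen over a Weibull because the tracked variables are on linear
stimulus scales and no shape information is available to prefer an
asymmetric form; the function is configurable at the observer level.
`σ = 0` is handled as the step-function limit. Reaction times are
log-normal (`median × exp(spread·Z)`) and independent of correctness —
median RT is only a descriptive outcome, so no diffusion-style
accuracy–RT coupling is modelled. For order judgement the same
functional form applies with `x` the onset asynchrony in ms.

Under this model the one-up–one-down phase targets the 50% point of the
*tracking* probability and the two-correct phase the ~71% point, so the
final-five-trials estimate sits slightly above θ by a roughly constant
offset (~0.5σ); group contrasts are unaffected by the shared offset.

## Synthetic cohort

Group sizes (197/34/104/99), per-group age means/SDs (10.20±1.20,
10.34±1.25, 9.94±1.20, 10.48±1.35 years), order-judgement completion
(64%, sampled uniformly across groups) and the effect-size and
correlation targets are the study-structure configuration. Latent
thresholds are drawn per protocol from a truncated-normal (at zero)
control baseline — detection 8±4 μm, amplitude difference 40±25 μm,
frequency difference 4±2.5 Hz, order judgement 80±50 ms — shifted per
group by `d·σ_baseline·inflation` and tilted by a small age slope
(−0.5 μm, −3 μm, −0.25 Hz, −6 ms per year, centered at age 10). The
baseline levels and age slopes are plausibility defaults; only
standardized quantities (d, r) are calibration targets, so absolute
levels are configuration, not claims. Ages are not truncated to the
8–12-year recruitment window; the tails are rare and harmless to the
standardized targets. Observer nuisance parameters: σ fixed per
protocol (3 μm, 15 μm, 1.5 Hz, 30 ms), lapse uniform on [0, 0.05],
median RT log-normal around 800 ms.

### Effect-size calibration

Targets are defined on the *measured* (staircase-estimated) scale,
because measurement noise attenuates latent separations (verified as a
property test: injecting a latent d recovers a smaller measured d).
Empirically the measured d responds linearly — very nearly
proportionally — to the latent inflation factor `f`, so calibration
estimates the slope `s` of `d(f) = s·f` by pooling every `(f, d)`
measurement across iterations (3 iterations × 75 replicate two-group
cohorts, sized so the calibrated factor's Monte-Carlo error contributes
about 0.01 SD to the recovered d) and sets `f = target/s`. Pooling was
chosen over a pure
`f ← f·target/measured` update after the latter was observed to chase a
single unlucky replicate batch (±0.02 Monte-Carlo error per batch) and
overshoot. Calibration is per (protocol, group) pair and stores its
factors on the cohort spec.

### Questionnaire injection

Scores are injected conditional on measured thresholds (not latent θ),
so recovery targets are direct: within a target's analysis mask, the
subscale z-score is `Σ b_i·z_i + shared + √(residual)·ε`, with `z_i` the
standardized measured metrics named by the targets, `b = Σ⁻¹r` solved
against the empirical metric correlation matrix, and residual variance
set so the total is unit. The three SEQ composites (hyper-, hypo-
responsivity, seeking) additionally load 0.85 on a shared latent
responsivity factor, giving pairwise correlations of
`0.85² + r_i·r_j ≈ 0.81`; SEQ social/non-social facet scores load 0.9
on their composite. Participants outside a mask, or inside it but
missing the metric (order-judgement non-completers), receive
uncorrelated noise; instruments a group does not receive (ADOS/ADI-R
outside the ASD-containing groups) are absent entirely. Scores are
emitted on a T-score-like scale (mean 50, SD 10). Jointly infeasible
target sets (non-positive residual variance) raise rather than silently
renormalize. Item-level questionnaire structure, IQ, and diagnostic
scoring logic are not simulated.

## Statistics

Group comparisons fit `outcome ~ group + age + group×age` by OLS
(statsmodels) and report the group main effect from type-II sums of
squares with the interaction retained, plus partial
η² = SS_group/(SS_group+SS_resid). The interaction is surfaced as a
flag (p < 0.05) but contrasts are always computed — simple-slope
follow-ups are out of scope. Pairwise contrasts come from the additive
model's adjusted means; Tukey adjustment evaluates the studentized
range at `|t|·√2` with the family size equal to the number of groups,
and Cohen's d is the adjusted mean difference over the pooled residual
SD (`√MSE`). With no covariate the model reduces to a classical one-way
ANOVA, which the oracle tests exploit. A lightweight two-group least-
squares path (`age_adjusted_cohens_d`) serves the calibration loop and
is tested to agree with the full model contrast.

Correlation screens are pairwise-complete Pearson correlations with
Bonferroni multipliers equal to the number of subscales screened per
instrument: SPM 7 (the total-sensory-systems composite is not
screened), SEQ 9, ADOS 4, ADI-R 3, Conners 2, DuPaul 2 — all
configurable. Raw measured thresholds (not age-adjusted residuals)
enter the screens. The ADHD-scale screen includes only the ADHD-only
group; the ASD instruments only the ASD and ASD+ADHD groups. Result
tables carry an empty Bayes-factor column for schema compatibility;
Bayes factors are not computed.

## Problem sizes and validation scope

The validation suite uses: exhaustive staircase-vs-replay equivalence
over all 2¹⁰ response patterns; 200 replicate two-group cohorts at
study sizes for each effect-size recovery (Monte-Carlo SE ≈ 0.01 on d);
50 replicate full cohorts for correlation recovery (SE on mean r well
inside each target's 95% sampling band); a 500-replicate null-generator
simulation at 15 participants per group for the type-I error of the
group test; and 10,000 draws for the observer's accuracy at threshold.
These sizes were chosen so Monte-Carlo error is small against each
tolerance while the whole suite runs in a couple of minutes on one CPU.

## Known limitations

Passing tests show the pipeline is internally consistent and recovers
what was injected; they cannot show that real children behave like the
generative observer. In particular the simulator omits attention
lapses that vary within a run, learning across protocols,
non-stationary motivation, any accuracy–RT coupling, and group
differences in σ, lapse, or RT; order-judgement missingness is
uniform across groups by construction; and the questionnaire model
reproduces target correlations, not item-level psychometrics. The
one-up–one-down order-judgement staircase has no stable equilibrium
below the 50% point, so its measured scale is compressed relative to
the latent scale — handled by calibration, but a reminder that
absolute simulated thresholds should not be over-interpreted.
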