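# Methods

This note documents the models, parameter choices and numerical decisions
behind `stereoscreen`, and what the synthetic-data results do and do not
show about real screening data.

## Stimulus geometry and rendering

Visual angles convert to pixels through the exact tangent relation
`extent = D · tan(θ)` with the viewing distance `D`, rounded half away from
zero. The shipped device presets describe a 10.1-inch 1920×1200 tablet
(pixel pitch ≈ 0.1133 mm) at 25 cm, on which the 420″ dot is 4 px and the
840″ disparity is 9 px. `DeviceProfile` is fully configurable because
arcsecond fidelity is meaningless without explicit pixel geometry.

Dots live on a grid of square cells one dot-size wide; `density_fraction`
is the probability that a cell holds a bright dot on the dark background.
Inside the Snellen-E target the green-channel dots are shifted rightward by
the disparity (crossed disparity, target in front); cells vacated by the
shift are refilled at the field density so the target carries no monocular
density signature. Uncorrelated noise adds an independent `noise_fraction`
of cells per channel (and per frame when dynamic): "added", not replacing,
and sampled independently per eye, which is what degrades binocular
correlation. Monocular controls render a solid, luminance-defined E over a
background at field density, identical in both channels.

Choices the source material leaves open, decided here once:

* dot shape: square cells, no anti-aliasing;
* dynamic stimulus duration: 90 frames (3 s at 30 Hz), configurable;
* channel-to-eye assignment is a rendering convention (pure red and pure
  green on black, configurable at export);
* per-stimulus seeds derive from the session seed as `seed + index`, so any
  stimulus is independently re-renderable;
* the E glyph is the canonical 5×5 limbs-right pattern scaled to the
  nearest whole multiple of the ~2° target size.

Rendering is deterministic: a `(seed, frame_index)` pair fully determines a
frame.

## Observer model

Responses follow a high-threshold 4AFC model: the target is truly perceived
with probability `d`, otherwise the observer guesses among four
alternatives, and a lapse rate (default 0.02) makes even perceived targets
occasionally wrong — the standard psychophysical account of a forced-choice
Snellen-E task. So P(correct) = (1 − lapse)(d + (1 − d)/4). Monocular
controls have `d = 1` for every group: they measure compliance, not
stereopsis.

Cohorts draw each subject's per-condition `d` from group-specific Beta
distributions: amblyopia Beta(1, 6), amblyogenic Beta(2.5, 2.5),
nonamblyogenic Beta(6, 1.5), control Beta(12, 1), scaled by per-condition
difficulty multipliers 1.0 / 0.95 / 0.90 / 0.85 (SRDS 8 / DRDS 1 /
DRDS 0.7 / DRDS 1 + noise) so harder stimuli carry partially independent
information — the property that makes score fusion worthwhile. Refractive
correction adds +0.15 to `d` for the refractive groups (amblyogenic,
nonamblyogenic) and nothing for amblyopia or emmetropic controls. These are
fixture parameters producing the qualitative group ordering
(control > nonamblyogenic > amblyogenic > amblyopia) and realistic
single-test AUCs (~0.8); they are not estimates of any clinical population.

The default cohort is 23/23/39/45 subjects by group. Glasses prescriptions
default to 23/23/6/0 per group — every amblyopic and amblyogenic child has
a prescription, emmetropic controls have none by definition — so 52
subjects are retested with correction and the merged dataset holds
130 + 52 = 182 four-dimensional score vectors. Per-condition draws are
independent by default; a `shared_ability_weight` mixes in a common
per-subject ability factor for studying violations of conditional
independence.

What the generator does **not** emulate: age effects, test–retest learning,
response bias among the four alternatives, attention lapses correlated
within a session, or any coupling between diagnosis subtypes and specific
conditions. Passing tests on this cohort therefore demonstrate correctness
of the machinery and qualitative behaviour, not clinical performance.

## Pass criteria

`false_pass_probability` is the upper binomial tail of the guessing
distribution; `min_correct_for_alpha` inverts it. With four alternatives,
P(≥ 3 of 5) = 0.1035, so the behavioural 3-of-5 rule does **not** meet a
strict α = 0.05 criterion (the α-derived threshold is 4 of 5); both rules
are provided and neither is silently substituted for the other. The
combined 0–20 score floor is `min_correct_for_alpha(20, ¼, 0.05) = 9`.
Sessions failing any monocular control are flagged invalid rather than
failed — the controls gate interpretability, not stereopsis.

## Perceptron trainers

**Simulated annealing** perturbs the weight vector with Gaussian proposals
(sd 0.2), cools geometrically (T₀ = 1, factor 0.995, 5000 iterations), and
accepts regressions with probability exp((F_old − F_new)/T). The objective
is (1 − sens)² + (1 − spec)² at the Youden-optimal cut of the current
weighted score, recomputed per candidate (a fixed-threshold mode exists).
Best-so-far weights are returned; ties at the decision threshold classify
pathologic, the fail-safe direction for screening.

**Damped least squares** minimises the squared error of the logsig output
against 0/1 targets by damped Gauss–Newton: the damping multiplies the
Jacobian's diagonal scaling plus an identity floor, is divided by 10 on an
accepted step and multiplied by 10 otherwise, and each update's norm is
capped at 2 — without the floor and cap, one early step can throw the unit
into irrecoverable sigmoid saturation when scores (0–5) make |w·x| large.
Inputs are jittered each epoch with uniform noise of half-width
0.03 × 5 = 0.15 score units; weights and bias initialise uniformly in
[0, 1]; splits are 75/25 with half-up rounding (182 → 137/45); convergence
at SSE change < 1e-8 or 200 epochs.

The `W` and `AW` fused scores are the same trainer with different positive
classes (amblyopia only vs amblyopia ∪ amblyogenic); weighted scores are
rescaled onto [0, 20] by their maximum attainable value.

## Evaluation statistics

AUC is the tie-corrected Mann–Whitney statistic computed from midranks;
its variance and the paired-comparison covariance come from the DeLong
structural components (verified to 10 decimals against pROC's independent
implementation). AUC confidence intervals are Wald on the DeLong SE,
clipped to [0, 1]. Operating points maximise Youden's J with ties broken
toward sensitivity, then specificity. Proportion intervals are
Clopper–Pearson (exact tail inversion). The two-sided Fisher test uses the
probability-mass convention with a 1e-7 relative tolerance for float ties;
exact McNemar is `min(1, 2·P(X ≤ min(b,c)))` with X ~ Binomial(b+c, ½)
(plain exact, not mid-p) and p = 1 for no discordant pairs. Degenerate
Fisher margins yield p = 1 with a warning rather than an error. Report
tables round proportions to 2 and AUCs to 3 decimals.

## Analysis scale and known limitations

The default analyses run at the study-sized cohort (182 merged vectors),
100 training runs per configuration, and 400 stimuli for the
single-channel-concealment measurement; these sizes keep the whole suite
and the reproduction script fast while leaving Monte-Carlo error well below
the asserted tolerances.

One behaviour deserves explicit note: across 100 random-split retrainings
the mean training AUC exceeds the mean validation AUC by ~0.01–0.03, and a
two-sample t-test over 100 runs has the power to call that difference
significant for many seeds. Diagnostics show this is not model overfitting —
the per-run train and validation AUCs are strongly *anti*-correlated
(splits that concentrate hard subjects in the validation side do the
opposite to the training side), and every trained model scores ~0.90 on the
full dataset. It is the intrinsic optimism of in-sample evaluation plus
split-composition noise in a fixed 182-vector pool, and it varies with the
seed; the package reports it honestly rather than averaging it away.

Other known limitations: no model of eye optics or development; no
multilayer networks; no sample-size machinery; observer parameters are not
fitted to any real cohort.
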