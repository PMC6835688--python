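# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `ocusearch`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Ocularity algebra and luminance mappings

An item's dichoptic input is summarized by its per-eye contrasts
`(C_L, C_R)` with `0 ≤ C_E ≤ 1`, eye weights `s_L = C_L / (C_L + C_R)`,
`s_R = 1 − s_L`, and ocularity `O = s_L − s_R`.  A zero-sum pair is
rejected as an invisible item.  The inverse mapping for a given binocular
contrast sum is `C_L = C_sum (1 + O) / 2`, `C_R = C_sum (1 − O) / 2`; the
round trip is exact to 1e−12 and conserves `C_sum`, which is the quantity
held fixed when an item's ocularity changes over time.

Three display mappings are implemented (all luminances are screen-side
cd/m²; attenuation along the optical path is metadata only):

- **bright** (bar search on black): an eye with weight `s` receives
  `s · C_sum · L_sum` with `L_sum = 48` cd/m² by default, so an ocularly
  balanced full-contrast bar shows 24 cd/m² per eye and a 9:1 dominance
  split (`|O| = 0.8`) shows 43.2 / 4.8 cd/m².
- **decrement** (dark items on a 110 cd/m² white field): item luminance
  `110 · (1 − s)` per eye — darker for the more dominant eye.
- **increment** (light letters on a 43 cd/m² grey field): non-target
  strokes show `L_o + L_1 (0.5 + x)` to both eyes with
  `x ~ U(−0.3, 0.3)`; the target shows `L_o + L_1 · s (1 + x)` with
  `x ~ U(−0.2, 0.2)`, so its two-eye increments always sum to
  `L_1 (1 + x)` regardless of the ocularity split.  `L_1 = 67` cd/m².
  Jitter intervals are open; rejection sampling discards boundary draws.

**Temporal profiles.**  An item's ocularity can be `static`, `abrupt`
(removed at `ΔT`), or `smooth` (held to `ΔT`, then ramped to zero over a
fixed 0.1 s window).  The smooth ramp is a raised cosine
`O(t) = O₀ (1 + cos(π (t − ΔT)/0.1)) / 2`, C¹ at both ends — a smooth
decay exists precisely to avoid perceptible transients, so a ramp with
discontinuous slope would defeat its purpose.  A linear ramp is available
behind the `ramp="linear"` flag.  At all times the item's `C_sum` is
unchanged; only the split between eyes evolves.

## Stimulus generation

Coordinates are degrees of visual angle, origin at the array centre, x
rightward, y upward; grid cells are (row, col), 1-based from the top-left.
Stated array extents are ambiguous between the span of the item centres
and of the outer edges; the *centre-span* reading is used ((n − 1) gaps)
and recorded in each scene's metadata.  Disparity sign:
`d = x_right_eye − x_left_eye`; `d < 0` is crossed (nearer than fixation).
Each monocular image shifts an item by `∓ d/2`, so the mean of the two
monocular positions is exactly the perceived position.  First- and
last-column items are pinned to `d = 0`.

Per-experiment geometry (grid, extent, item size and tilt, jitter bound,
disparity range, target-placement constraints, session grid) is tabulated
in `stimuli._EXPERIMENTS`.  Target placement enumerates the full feasible
cell set and samples uniformly, with ties in "closest to the radius-R
circle" resolved by keeping every cell within 1e−9 of the minimal gap.
The large-array design uses an eccentricity band of 13.5–16.5° (reading
"about 15°" as ±10%) with a 12° minimum horizontal offset, measured to
the bar centre.

The DI singleton is placed by mirroring the target's grid cell across the
vertical midline — guaranteeing the opposite perceived half and exactly
matched grid eccentricity — with uniform sampling from the opposite half
available behind a policy flag (the original placement rule, "far from
the target", is under-specified; the mirror is an assumption).

Dichoptic schemes: `sign_flip` (all items share `|O|`, the odd item takes
the unique sign), `zero_among_full` (binocular singleton among monocular
items), `full_among_zero` (monocular singleton among binocular items,
either *double-strength*, `C_sum` matched, or *single-strength*,
`max(C_L, C_R)` matched, i.e. the singleton's `C_sum` is halved), and
`target_only` (all non-targets balanced; only the target may carry `O ≠ 0`).
In the heterogeneous-contrast design the whole-trial jitter draw —
including the target's — is resampled (cap 10⁴) until the target's
binocular sum is strictly between the array's min and max; both target
and non-target sums have expectation `L_1` above the background, so the
acceptance condition does not bias the target's expected contrast.

Vergence anchors: one binocular zero-disparity dot at the centroid of
every 2×2 neighbourhood of jittered positions ((rows−1)(cols−1) dots),
plus four corner disks placed 1° outside the array corners (large-array
design) or an enclosing frame 1.1× the array extent.  Letters are drawn
upright from axis-aligned strokes of 0.085° thickness (a stroke-glyph
approximation of the original sans-serif letterforms).  The pre-onset
fixation screen is emitted as timeline metadata rather than rendered
frames unless raster output is requested.

Generation is a pure function of (config, cell, seed); session schedules
spawn per-trial seeds from the session seed, so two runs with equal seeds
are bit-identical.

## The synthetic observer

The observer is phenomenological — there is no neural circuit here.  Its
purpose is to give the analysis pipeline data with the qualitative effect
structure of dichoptic search behaviour, so that the pipeline, and effect
and parameter recovery, can be tested end to end.  Item priorities are

```
priority_i = w_ori · [tilt_i ≠ array mode]
           + w_oc · tanh(max(0, ΔO_i − oc_threshold) / oc_scale)
           + w_lum · (C_sum,i − mean C_sum) / mean C_sum
           + w_near · nearness_rank_i
           − aversion · [unbalanced among balanced ∧ persistent]
```

with `ΔO_i = |O_i − median O of the other items|` at onset.  Design
choices that matter:

- **Saturating ocularity term.**  A linear gain in `ΔO` cannot both keep
  first-saccade capture of the singleton well below 50 % at `ΔO = 1.2`
  (compact arrays) and produce a recoverable DI−DC effect at `ΔO = 1`
  (monocular-among-binocular sessions).  The `tanh` saturation (scale
  0.4) resolves this; an eye-of-origin singleton (`ΔO = 2`) is close to
  the saturation ceiling.
- **Softmax capture** at temperature 0.3 rather than hard argmax, so the
  first saccade is only sometimes captured and error rates stay below
  50 % in the compact-array designs.
- **Aversion as a subtractive penalty**, applied only to an item that is
  ocularly unbalanced among balanced neighbours (`|O_i|` exceeding the
  leave-one-out median of `|O|` by more than 0.5) *and* whose ocularity
  persists beyond `tau_percept = 0.2` s.  A 0.15 s transient therefore
  evades the penalty, while a 0.5 s transient does not — the lustre
  percept needs time to form, gaze aversion follows the percept.
- **Event timing.**  First saccade at `t_saccade` (lognormal-perturbed);
  a corrective saccade to the target costs `t_move`; the button press
  follows the final fixation by `t_decide`, with multiplicative lognormal
  noise of scale `rt_noise_sd = 0.12`.  With probability
  `distracted_press_prob = 0.05` a captured observer presses at the
  distractor before correcting (short, usually incorrect RT, gaze never
  reaches the target); a `lapse = 0.02` flips the button at random; an
  optional heavy-tail mixture (`heavy_tail_prob`) injects RT outliers for
  exercising the exclusion rule.

Presets: `paper_like_E1 … E4`, `null` (`w_oc = 0`), and
`aversion_static`/`aversion_transient` (aliases of the large-array preset,
named for the session designs they pair with).  The large-array preset
uses a weaker orientation weight (`w_ori = 2`; a 20° orientation contrast
in a 34°×46° array is far less salient than 90° in an 18° array), longer
movement and decision costs (`t_move = 0.6`, `t_decide = 0.7`, giving
baseline RTs near 1 s), a stronger ocularity weight (`w_oc = 3.2`), and
`aversion = 2.9 = w_oc · tanh(1.5)` — exactly the saturated ocularity
term of a persistent monocular singleton among balanced items, i.e. the
lustre percept *fully* masks that singleton's saliency advantage, which
is the observed phenomenon the preset encodes.

## Analysis pipeline

Per observer × condition: incorrect button presses are excluded first;
then, with mean `m` and sample SD `s` (ddof = 1; single-trial pools use
`s = 0`) computed over the correct trials *before any removal*, trials
with RT < 0.2 s or RT > `m + 3s` (strict) are excluded in one pass.  The
gaze-RT pool is the same kept pool minus trials whose gaze never reached
the target.  Error rates are counted over *all* trials of the condition.

Normalization divides each observer's condition mean by that observer's
baseline mean for the matching (|O|, transient) family, falling back to
the observer's unique global baseline when the family has none (the
heterogeneous-contrast design has a single zero-ocularity baseline).  It
is applied on request or automatically when the between-observer
coefficient of variation of baseline RT exceeds 0.25.

Scoring conventions: a first saccade is erroneous iff its horizontal
displacement sign opposes the target's side; displacements below 0.1° are
unclassified (micro-displacements should not count as directional
choices).  Gaze "reaches" the target within a 1.5° radius (half the
inter-item spacing of the densest array would be ~0.4° — too strict given
fixation scatter).  Median-split ties go to {near, weak}; arrays with no
disparity variation are unlabelled.  The paired t-test is two-sided at
p < 0.05 with no multiple-testing correction; zero-variance non-zero
differences report p = 0 with a degenerate-variance flag, identical
vectors report t = 0, p = 1.

## Validation design and problem sizes

The replicate-cohort checks in `tests/test_acceptance.py` use the full
session sizes (450-trial, 6-observer cohorts; 150-trial, 4-observer
cohorts for the masking designs): 20 replicates for effect recovery, 400
for the null observer's rejection rate (expected band 5 % ± 3 %), and 10
per preset for the masking contrast, requiring the expected pattern in at
least 8 of 10 — a single-cohort check would fail ~5 % of the time by
chance, since the static masking preset realizes an exact null.  The
"absence of an effect" at the weakest contrast is operationalized as *no
significantly positive* difference, symmetric with the presence check.

## Known limitations

- The observer makes at most one corrective saccade and always knows the
  target's location after the first capture; multi-fixation serial search
  and the resulting RT set-size effects are not modelled.
- Oculomotor dynamics (velocity profiles, main sequence), fixational eye
  movements and saccade detection are out of scope; fixation events are
  emitted directly.
- With the large-array preset, a strongly salient distractor slows DI
  trials reliably; the original large-array human data show a DC benefit
  without a resolvable DI cost (attributed to RT variability at ~1–2 s
  baselines).  The synthetic cohorts are less variable than those humans,
  so this particular null is not reproduced.
- Perceived-contrast nonlinearities, gamma correction and photometric
  calibration are not modelled; luminances are nominal screen values.
- Letter glyphs are stroke approximations; no rotation is applied.
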