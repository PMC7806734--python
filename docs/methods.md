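# Methods

## The maze and its sequence statistics

The ViS4M is an x-shaped, four-arm enclosure in which a mouse explores
freely for 5 minutes while each arm presents a controlled visual stimulus —
a colored LED field (red/green/blue/white) or a grayscale object
(black/grey/clear/white).  The raw datum is the ordered sequence of arm
entries with entry/exit times; everything downstream derives from it.

**Spontaneous alternation.**  A window of four consecutive entries succeeds
when its four arms are all distinct.  The reported percentage is
`100 * successes / (N - 2)` for a sequence of `N` entries.  Note that only
`N - 3` overlapping windows exist, so the score is capped at
`100 (N-3)/(N-2)` rather than 100% — a perfect 30-entry session scores
96.4%, not 100%.  We keep this `N - 2` denominator as the package default
because it is the field convention for this maze and matches the observed
ceiling in real cohorts; the `N - 3` variant (`denominator="windows"`),
under which a perfect explorer scores 100%, is exposed for users who prefer
an interpretable ceiling.  Sequences with fewer than 4 entries raise an
error rather than scoring 0%, so that unusable sessions flag themselves
instead of biasing group means downward.

**Re-entries.**  A mouse that exits to the center and re-enters the same
arm produces a consecutive repeat.  The 12 transition types exclude
self-pairs and the chance model assumes three choices per step, so repeats
are collapsed before scoring; the raw entry count is retained separately
for total-entry (locomotion) reporting, and the number collapsed is
reported per session.

**Transitions.**  With four arms there are exactly 12 ordered
(unidirectional) and 6 unordered (bidirectional) distinct-arm pairs.
Unidirectional percentages are counts over `N - 1` total transitions;
bidirectional percentages are the sum of the two opposing unidirectional
percentages.  Chord-diagram exports restrict to the most (Q4) or least
(Q1) frequent quartile — the top or bottom 3 of the 12 — with ties broken
by the canonical alphabetical (origin, destination) ordering so the
selection is deterministic; no tie-break convention is standard, so we fix
one.

**Time in arms.**  Percent time uses total in-arm dwell as the denominator
(center-zone time excluded); it is the only base under which the four arm
percentages sum to 100.

## Chance level

The null explorer moves at every step to one of the three arms other than
its current arm, uniformly and with no memory.  Exhaustive enumeration of
the 27 equally likely 3-step continuations from any starting arm gives a
window success probability of 6/27 = 2/9 ≈ 22% — the chance level for
four-arm alternation.  (Allowing self-transitions would give 4!/4⁴ ≈ 9.4%,
which is not the regime the transition statistics live in.)  For a
finite sequence the expected score under the `N - 2` denominator is
`100 (N-3)(2/9)/(N-2)` by linearity of expectation — 21.43% at N = 30 —
approaching 22.22% asymptotically.  The Monte-Carlo test compares an
observed percentage against simulated null sessions at the observed `N`
with the add-one empirical p estimator (two-sided, capped at 1), which
cannot return p = 0 at finite simulation size.

## Photometry

Conversions are anchored in the light meter's EV formulas (`lux = 2.5·2^EV`,
`cd/m² = 2^(EV−3)`, hence lux = 20 × cd/m² for this setup) and in the
candela definition (683 lm/W at 555 nm, where the CIE photopic curve
V(λ) = 1).  The CIE 1924 curve is embedded at its canonical 5-nm
resolution and interpolated linearly onto the 1-nm working grid
(300–800 nm); integrals are trapezoidal at 1 nm, and test oracles re-derive
them at 0.1 nm.

LED bands are Gaussians parameterized by the printed peak/FWHM
(σ = FWHM/2.355): red 628/17, green 517/31, blue 452/22 nm.  The phosphor
white LED is a two-component mixture (441/19 blue pump + 533/104 phosphor
band).  The pump/phosphor power split is not a published quantity; the
default is 0.3/0.7 and is configurable.  A component with FWHM 0 is treated
as a monochromatic line and all conversions reduce to closed forms; the
Gaussian path converges to these as FWHM → 0 (verified to 0.2% at 1 nm
FWHM).

Pigment spectral sensitivities use the Govardovskii A1 nomogram (α and β
bands, parameterized solely by λmax and peak-normalized): S-opsin 360 nm,
M-opsin 508 nm, rod 498 nm, melanopsin 480 nm.  Opsin-effective photon
flux weights the spectral photon flux by the pigment template and, by
default, a lens-transmission curve.  The murine lens table used by the
original toolbox chain is not recoverable, so the package ships a
**synthetic logistic stand-in** (midpoint 340 nm, scale 12 nm: near-full
transmission through the visible band, substantial near-UV transmission,
roll-off below ~340 nm); it is toggleable (`lens_correction=False`).
Consequences: per-opsin *absolute* effective fluxes are model outputs, not
reproductions of any published table, and are validated **ordinally** —
at matched irradiance, S-opsin is driven blue ≈ white ≫ green ≈ red and
M-opsin green ≈ white > blue > red, which is the gradient the stimulus set
was designed to produce.

Luminance regimes: scotopic < 0.001 ≤ mesopic ≤ 3 < transition ≤ 10 <
photopic (cd/m²).  The 3–10 cd/m² band is labeled `transition` since it
falls between the named mesopic and photopic ranges; the mesopic interval
is closed at 3 so an equal-luminance condition targeting ~3 cd/m²
classifies as mesopic.

## Cohort statistics

Two-way (e.g. genotype × age) fixed-effects ANOVA uses Type-III sums of
squares with sum-to-zero coding (statsmodels under the hood), chosen
because the cohorts are unbalanced; on balanced designs it reproduces the
classical decomposition exactly, which the tests verify against a
hand-computed 2×2 fixture.  Fisher's LSD is the unprotected pairwise
t-test on the pooled ANOVA error term — no multiplicity correction, by
definition — and equals a pooled-variance two-sample t-test when the
design collapses to two groups.  Simulation shows the genotype F-test
holds its nominal 5% type-I error under an unbalanced null.

Alternation-vs-transition regressions are simple OLS with alternation on
the x-axis and the transition predictor on y (the maze literature's axis
convention); R² is symmetric in the two variables, so the convention does
not affect it.  Composite predictors are signed sums of bidirectional
percentages (positive set minus negative set, disjoint by construction);
the exact composition rule for published "combined" predictors is not
printed anywhere we could follow, so the pair sets are caller-supplied
configuration rather than hard-coded.  Percentages enter these models
untransformed (no arcsine/logit), matching common practice for this assay.

## The exploration simulator

No raw tracking data accompanies the assay, so the package includes a
generative stand-in whose purpose is pipeline testing and qualitative
phenotype emulation — not biological inference.  It is a semi-Markov model
with three interpretable mechanisms:

- **preference** — positive per-arm weights (elevated red weight emulates
  the innate preference for the dark arm);
- **working memory** — each of the last *k* entries (default k = 3, one
  less than the window size that defines alternation) is recalled with
  probability *m*; remembered arms' weights are multiplied by the
  avoidance factor ε ∈ [0, 1];
- **pairwise discriminability** — a recalled visit to arm *b* is
  misattributed to arm *c* with probability 1 − d(b,c) (normalized only if
  the total confusion mass exceeds 1).  Low d(B,W) makes the animal avoid
  the wrong member of the blue/white pair, selectively collapsing B↔W
  transitions while leaving entry counts untouched — a color-discrimination
  deficit, mechanistically distinct from a memory deficit (m, ε).

Candidates at each step are the three non-current arms.  If ε = 0 leaves
all three candidates remembered, the choice falls back to bare preference
weights (the degenerate all-avoided case).  Timing: inter-entry intervals
are exponential with mean 60/entry_rate s and dwells are exponential
(mean `dwell_mean`) truncated to the interval and session end — memoryless
by assumption, since no dwell distribution is published.  Defaults
(WT 6 entries/min, dwell 6 s; AD 8 entries/min, dwell 5 s) give ~30 and
~40 entries per 300-s session, typical of this assay, with the higher AD
rate encoding the strain's documented hyperactivity.

Limit behavior ties the simulator to the analytic null: m = 0 with uniform
preferences *is* the null model (transition types uniform at 1/12,
verified by chi-squared over 10⁵ steps), and m = 1, ε = 0, d ≡ 1 forces a
novel arm every step, saturating alternation at its `N - 2` cap.

**Presets.**  The WT preset (m = 0.80, ε = 0.25, red weight 1.4, all
d = 1) yields a group mean alternation of ≈46% — inside the 38–49% band
wild-type cohorts show in this assay.  The AD preset (m = 0.60, ε = 0.40,
red weight 1.9, d(B,W) = 0.3, d(G,W) = 0.5, higher entry rate) yields
≈19%, near the 21.4% finite-N chance level, with selectively depressed
B↔W transitions.  These values were fixed once against those published
group-level bands and are not fitted quantities.

**What the simulator does not emulate:** spatial trajectories and
kinematics (distance/speed are pass-through metadata), center-zone
dynamics, within-session fatigue or habituation, sex effects, and any
dependence of dwell time on the stimulus.  Tests that pass on simulated
cohorts therefore validate the *analysis pipeline*, not claims about real
mice.

**Parameter recovery.**  The per-step choice distribution is computable
exactly by enumerating recall × confusion outcomes (≤ 5^k terms; k = 3 by
default), giving an exact step-wise log-likelihood.  Identical
(current arm, memory tuple, choice) states are pooled before evaluation,
so likelihood cost scales with the number of distinct states (a few
hundred) rather than total steps.  Fitting is bounded L-BFGS-B; confidence
intervals are profile-likelihood intervals at the χ²(1) cutoff located by
bisection.  Under-determined configurations (many free parameters, little
data) warn and report wide intervals rather than failing.  With 200
simulated sessions, d(B,W) is recovered within ±0.1 and the true-estimate
correlation across replicates exceeds 0.8.

## Numerical and I/O choices

- Times are seconds (decimals) on a 0-based session clock; event logs are
  UTF-8 CSV with a fixed header, validated with line-number diagnostics.
- Circos tableviewer exports carry integer counts (the tableviewer
  consumes counts); percentages live in the tidy summary table.
- Sessions with N < 4 after collapsing are flagged in summaries
  (`too_few_entries`, missing alternation) rather than dropped.
- Zero spectral overlap in effective flux returns a −inf sentinel with a
  warning (a log-scale quantity with no mass), while a spectrum with zero
  photopic overlap raises, since lux is then undefined.
- Random streams are per-call `numpy.random.Generator`s; no global seeding.
- Test problem sizes (10⁵ null windows/steps, 1000-replicate ANOVA
  calibration, 20 recovery replicates × 200 sessions) were chosen so the
  statistical assertions sit at ≥3 standard errors while the whole suite
  runs in about a minute.

## Known limitations

- Absolute per-opsin effective fluxes depend on the synthetic lens curve
  and the unpublished white-LED component split; only their ordering is
  validated.
- The Type-III/sum-coding ANOVA choice cannot be confirmed against the
  original analyses for unbalanced cells; alternative SS types are not
  implemented.
- The confusion mechanism is one of several that could produce
  pair-selective transition deficits; perceptual preference blending is
  deliberately out of scope.
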