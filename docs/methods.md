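# Methods

## Scope and data model

`scedan` analyzes a single behavioral measurement observed over
consecutive sessions in a two-phase AB layout: `n_pre` baseline
sessions followed by `n_post` intervention sessions, session times
implicitly `1..n_pre+n_post`. Multi-phase (ABAB) and multiple-baseline
containers are out of scope. Missing data are rejected outright — no
imputation — because every procedure below assumes a complete,
equally spaced series. The improvement direction (`aim`) is fixed per
series and flips the inequality in every directional statistic.

All standard deviations use the sample (n−1) convention by default; a
`ddof` switch exposes the population convention. The sample convention
makes the 2-SD band slightly wider, i.e. more conservative about
declaring change.

## NAP

`nap` enumerates all `n_pre · n_post` ordered pairs. A pair improves
when the intervention value is strictly better in the aim direction;
exact equality is a tie weighted 0.5. An optional absolute tie
tolerance (default 0) accommodates instrument-rounded data; the
default treats ties as exact equality. NAP equals the rank-based
probability of superiority `U/(n_pre·n_post)` with midrank ties; the
test suite asserts exact agreement with the rank-sum statistic from
`scipy.stats.mannwhitneyu` on a thousand random series — the SciPy
route is an independent oracle, never the implementation.

Interpretive bands: values in [0, 0.65] are labelled *small* — the
only boundary with wide currency for AB data — and the defaults
continue with *medium* (0.65, 0.92] and *large* (0.92, 1.0], following
the index's original calibration. Bands are configurable and each band
is closed at its upper end. No p-values or confidence intervals are
attached: with serial dependence their basis is doubtful, and the
package's stance is descriptive throughout.

## SLC

Baseline trend is the mean of baseline first differences, which
telescopes to `(last − first)/(n_pre − 1)`; it is therefore driven
entirely by the endpoints. Detrending subtracts `(t−1)·trend` from the
score at session `t` — the first session of the series is unmoved.
Slope change is the mean of first differences of the detrended
intervention phase; its positional removal within the intervention
phase (`(j−1)·slope_change`, first intervention session unmoved)
yields the doubly corrected values, and the net level change is the
difference of the corrected phase means. Both phases must have at
least two points; a baseline shorter than five sessions triggers a
report warning rather than an error. Outputs stay in raw score units —
no standardization — so a level change of −6 on a T-score scale means
six T-score points.

The positional origins (global first session for detrending, first
intervention session for slope-change removal) are a design choice:
they make each correction leave its reference point unmoved, and they
make the generator's decomposition exactly invertible (see below).

## Visual aids

* **Range lines**: per-phase min/max and whether the two intervals
  intersect.
* **2-SD band**: baseline mean ± k·SD (k defaults to 2), projected
  over the intervention phase; a median-centered variant is available
  for skewed baselines. Points exactly on a limit count as *inside* —
  strict inequality defines "outside" throughout, favoring the
  no-change reading.
* **OLS trend lines**: per-phase least squares in (session, score),
  used for plotting and narrative description only.
* **Split-middle trend**: the phase is halved; for odd length the
  middle observation belongs to both halves by default (the
  alternative, dropping it, sits behind `odd_middle="drop"`). Each
  half contributes its (median session, median score) point and the
  line passes through the two points, making it resistant to a single
  wild value. Identical half median sessions raise `degenerate-split`.
* **Stability envelope**: split-middle on the baseline, half-width =
  `fraction × median(baseline)` with `fraction = 0.25`, projected over
  the intervention phase. Containment is computed twice: for the
  baseline itself (is the baseline trend-stable?) and for the
  projected intervention points (do they behave as the baseline trend
  predicts?). The published 80% criterion does not say which fraction
  it governs; the `stable` verdict applies it to the intervention
  containment, with the baseline containment reported alongside and a
  low value raising an `unstable-baseline` warning. Projection is
  unbounded in time, but when `scale_min`/`scale_max` are configured
  the report warns when the projected envelope exits the plausible
  measurement range.
* **Immediacy**: mean of the first `window` intervention sessions
  minus the mean of the last `window` baseline sessions (default 3,
  clipped to the shorter phase), labelled improvement/deterioration
  against the aim.

## Synthetic generator

`simulate_ab` adds AR(1) noise to a deterministic part built from the
SLC decomposition itself:

```
y_t         = level + trend·(t−1)                                  t ≤ n_pre
y_{n_pre+j} = level + trend·(n_pre+j−1) + level_change + slope_change·(j−1)
```

so with `noise_sd = 0` the SLC estimators return the generating triple
to machine precision — the property the test grid asserts. The noise
is `e_t = phi·e_{t−1} + ε_t`, `ε_t ~ N(0, noise_sd²)`, with a 100-step
burn-in; `noise_sd` parameterizes the **innovation**, so the marginal
noise SD is `noise_sd/√(1−phi²)`. AR(1)+normal is the standard
serial-dependence assumption for repeated measurements on one
individual. What the generator does **not** emulate: bounded or
integer-valued scales, floor/ceiling effects, cyclic patterns, or
measurement reactivity — passing tests on synthetic data therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every real-data pathology.

`null_nap_calibration` draws both phases i.i.d. normal (no effects, no
trend, no dependence) and returns the Monte Carlo mean of NAP with its
standard error; it converges to the 0.5 chance level.

## Numerical and reporting choices

* Floats are serialized with 4 decimals in the JSON report;
  percentages are rounded to 2 decimals. Key order is fixed by
  construction, so `analyze` output is byte-identical across runs.
* Validation failures carry stable string codes (`phase-empty`,
  `non-contiguous-phases`, `bad-time-index`, `baseline-too-short`,
  `window-too-large`, …); the CLI exits with status 2 on any of them.
* The report never aggregates the visual, quantitative and substantive
  components into one verdict; it flags sign disagreements (level
  change vs band exceedance direction, slope change vs envelope
  direction) and leaves adjudication to the analyst.
* Clinical cut-off rule: a score exactly at the cut-off is *not* on
  the functional side; the final-k check (default k = 3) asks whether
  the last k intervention sessions all qualify.

## Problem sizes used in the checks

The chance-level calibration uses 10,000 replicates at the 5/10 phase
lengths, giving a Monte Carlo SE of about 0.15 percentage points. The
2-SD band calibration check uses a 200-session baseline with 10
intervention points over 10,000 replicates: the band's "<5% outside"
expectation is a property of the normal distribution (the two-sigma
rule), and with a short baseline the sample mean and SD estimated from
a handful of points inflate the exceedance well above 5% (≈14% at
n_pre = 5). That inflation is a real small-sample limitation of the
aid and is the reason the band should be read as a visual aid rather
than a formal test; the long-baseline check isolates the
distributional claim from it.

## Known limitations

* Baseline trend from endpoint-sensitive first differences can be
  misleading under alternating baselines; the split-middle line is the
  resistant alternative offered.
* NAP saturates at 1.0 and cannot distinguish degrees of complete
  non-overlap; it is also insensitive to within-phase trend (use SLC).
* The stability envelope inherits the split-middle line's variance
  when the baseline is as short as four points; the report's
  `short-baseline` warning fires below five.
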