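# Methods

## Signal model and indices

The package treats the HRV tachogram y(n) as the output of an autoregressive
map on past respiration: given the embedding x̄ₙ⁻ = [x(n−1), …, x(n−L)], an
ε-SVR is trained on all usable samples of a 5-min epoch and evaluated
in-sample. Training and evaluation deliberately share the epoch — no
held-out split — so the RBF index Pxk can over-read coupling on short
epochs; the surrogate test below is the guard against interpreting that
overfit as nonlinearity.

Three indices are reported per epoch:

* **Px** — variance fraction of y retained by orthogonal least-squares
  projection onto the column space of the lagged-respiration matrix Q. The
  projection uses a rank-revealing least-squares factorization rather than
  the explicit (QᵀQ)⁻¹ inverse; rank-deficient embeddings (constant
  respiration) fall back to the minimum-norm solution and carry a
  `rank_deficient` flag.
* **Pxl** — same variance fraction from the linear-kernel SVR prediction.
* **Pxk** — from the RBF-kernel SVR prediction.

Both y and the predictions are centered by the epoch mean of y before the
ratios, making all three *variance* fractions and keeping them comparable.
Pxl and Pxk may exceed 1 for aggressive in-sample fits; values are not
clipped — a `ratio_gt_one` flag marks them, since clipping would hide
exactly the overfitting the analysis needs to see. The lag set is strictly
past (1..L) for the projection and both kernels, so the three indices see
the identical regressor set.

## Hyperparameters

| parameter | rule | rationale |
|---|---|---|
| c (box constraint) | IQR(y)/1.349 | robust estimate of the response SD; tolerant to outlier beats |
| ε (tube width) | c/10 | fixed fraction of the response scale |
| σ² (RBF bandwidth) | entropy rule (below) | data-adaptive, deterministic |
| L (model order) | ceil(2·fs/Fr) | regressor window spans two breathing periods |

σ² is selected on a fixed grid of 21 log-spaced candidates spanning
10⁻²–10² times the median squared pairwise distance between embedding rows.
For each candidate the Shannon entropy of a 30-bin histogram on [0, 1] of
the off-diagonal kernel entries is computed; the maximizer wins, with ties
going to the smallest candidate. Both extremes of the grid are degenerate
(entries pile at 0 or at 1), so the rule lands on an interior bandwidth that
spreads kernel values — the grid bounds and bin count are fixed once and are
not tuned per dataset.

The representative respiratory frequency Fr comes from the epoch's Welch
PSD: inside the band holding the central 90% of the spectral mass (5th–95th
percentile of cumulative mass), take the lowest-frequency strict local
maximum when three or more maxima exist, otherwise the band's global
maximum; plateaus are credited to their leftmost bin, and exactly three
maxima take the lowest-frequency branch. Fr is clamped to ≥ 0.1 Hz, which
bounds L at 40 samples for 2 Hz signals and keeps the design well-posed on
pathological spectra.

## Dual solver

The ε-SVR box-constrained dual is solved by libsvm (SMO) through
scikit-learn's `SVR`; the package owns the design construction, kernel
evaluation, bias handling and index computation, and *verifies* feasibility
of every accepted solution (|βₙ| ≤ c, |Σβₙ| ≤ 10⁻⁶·c·N) instead of trusting
the solver. SMO can cycle without converging near machine precision on
degenerate instances (nearly realizable targets with large c), so the
stopping tolerance is relaxed stepwise 10⁻⁸ → 10⁻⁶ → 10⁻⁴ before a fit is
declared failed; the test suite checks the dual objective against a generic
SLSQP solution of the same program on small instances.

## Band-pass details

The canonical analysis band is 0.03–1 Hz at fs = 2 Hz, where the upper edge
*is* Nyquist and a band-pass is ill-posed; since no energy exists above
1 Hz at that rate, the filter degrades to the 4th-order high-pass half alone
(logged when it happens). Filtering is zero-phase (forward-backward), with
the edge padding stretched to up to 600 samples: the 0.03 Hz corner puts
poles close to the unit circle, and scipy's default pad leaves edge
transients large enough to break both the DC rejection and the
time-reversal symmetry that zero-phase filtering should satisfy. The
0.03–1 Hz filter is applied after resampling to 2 Hz; the respiration
anti-alias stage for higher-rate input is an 8th-order low-pass at
0.8·(fs_out/2) followed by interpolation.

RR intervals are anchored at each interval's closing R-peak and
cubic-spline-interpolated to the 2 Hz tachogram — standard HRV practice,
giving a smooth series without step artifacts. Consecutive RR values
outside (0.2, 4.0) s flag the record as suspect but do not abort it.

## Surrogate test

The null hypothesis is a purely linear (Gaussian) coupling. A surrogate
pair adds one conjugate-symmetric random phase vector (DC and Nyquist
untouched) to the Fourier phases of *both* channels, then refines each
channel by joint IAAFT: alternately (i) rank-remap each channel onto its
original sorted values (exact amplitude multiset) and (ii) restore the
original Fourier amplitudes with phases of the form "original + one common
per-frequency rotation", the rotation chosen as the spectral-power-weighted
circular mean closest to both channels' current phases. Keeping the phase
*increment* common at every iteration preserves the cross-spectrum — hence
the cross-correlation — which per-channel-independent IAAFT slowly destroys
(empirically that drift roughly doubled the false-alarm rate on strongly
coupled linear pairs before the joint refinement was adopted). Iteration
stops at rank convergence of both channels or after 100 passes, always
ending on the amplitude step.

Pxk is recomputed on 24 surrogate pairs with the same L; σ², c and ε are
re-tuned per surrogate so each surrogate traverses the identical pipeline
as the original. The verdict is significant when the original Pxk exceeds
the empirical 95th quantile (linear interpolation between order statistics)
of the surrogate values. Failed surrogate fits are dropped; a verdict
requires at least ⌈5/6 · n⌉ successes. Under the null the nominal
exceedance rate is ~1/25; the test suite bounds the empirical false-alarm
rate on uncoupled pairs at 15% to absorb quantile-estimation noise at 24
surrogates.

## Simulation bench

The verification bench couples a stationary AR(2) driver x1 (poles at
radius √0.7, spectral peak near 0.25·fs/2 — conveniently where a breathing
peak would sit at 2 Hz) into a driven series x2 via a linear term −C1·x1(n−1)
and a quadratic term −C2·x1(n−1)². Innovations are independent standard
normal streams scaled by 0.1. Two sweeps of C1 over [0, 1.8] in 0.2 steps
with 20 realizations per value are provided: linear-only (C2 = 0) and mixed
(C2 = 2 − C1, trading one component against the other). Realizations are
1000 samples after a 500-sample burn-in from zero initial conditions —
long enough for stable SVR fits at L ≈ 16–18 while keeping a full sweep
around a minute of CPU. The recursion guards against non-finite values for
user-supplied coefficient variants, although the admissible (C1, C2) range
cannot destabilize it.

In the mixed sweep the RBF index significantly exceeds the linear index for
weak linear coupling and loses that dominance as C1 grows; the crossover
cell depends mildly on the realization length (which has no single canonical
value) and lands at C1 ≈ 0.8–1.0 for the defaults here. The linear-only
sweep is the specificity check: the surrogate test should rarely flag
nonlinearity there.

## Synthetic cardiorespiratory epochs

Real polysomnographic epochs are private, so the pipeline is exercised on
generated 5-min, 2 Hz epochs: narrowband respiration (sinusoid at a nominal
0.25 Hz with 5% slow frequency jitter and 5% measurement noise) or
broadband apnea-like respiration (0.1–0.6 Hz band-limited noise);
HRV = gain_linear · lag-1 respiration + gain_quadratic · (mean-removed
squared lag-1 respiration) + LF-band (0.04–0.15 Hz) noise standing in for
non-respiratory autonomic modulation + a small white floor. Respiration is
standardized to unit variance before the drives so gains are comparable
across modes; both channels pass the standard band-pass and are then
demeaned (finite noise epochs retain a small sample mean otherwise). With
LF-noise amplitude 0.3 the linear-gain grid {0, 0.5, 1, 2} spans Px from
≈ 0.05 to ≈ 0.95.

What these fixtures do *not* emulate: ectopic beats and artifacts, apnea
event dynamics beyond spectral broadening, nonstationarity within an epoch,
and the subject-level clustering of real datasets. Passing tests therefore
validate the estimators' behavior under controlled coupling, not clinical
performance.

## Group statistics

Paired triples (Px, Pxl, Pxk) are compared with the Friedman test (the
all-tied degenerate case is reported as statistic 0, p = 1, where the
standard tie correction is 0/0); independent groups with Kruskal-Wallis.
Pairwise follow-ups are Wilcoxon signed-rank (paired) or rank-sum
(independent), Bonferroni-corrected; stars at adjusted p < 0.05 / 0.01 /
0.001. Repeated subjects within groups are not modeled.

## Problem sizes in the test suite

End-to-end checks run the full sweeps at their nominal sizes (10 × 20
realizations of 1000 samples). Surrogate-heavy property checks (false-alarm
rate, specificity of the linear scenario) use 300–1000-sample series and
3–24 realizations per condition — sizes chosen so the whole suite stays in
the minutes range on one CPU while the binomial bounds being asserted
remain meaningful.

## Known limitations

* In-sample evaluation makes Pxk an optimistic coupling measure by
  construction; only the surrogate comparison licenses a nonlinearity claim.
* The entropy-based σ² rule and the percentile definition of the 90%-power
  band are deterministic stand-ins for procedures whose original recipes
  are underspecified; both are fixed once, documented, and tested for their
  stated properties rather than for agreement with any external
  implementation.
* The IQR-based c is a rule of thumb; regularization tuning for ε-SVR on
  short physiological epochs is an open problem, and strongly coupled
  epochs occasionally push SMO into its slow-convergence regime (handled by
  the tolerance cascade).
* Amplitude adjustment and common-phase preservation conflict slightly in
  IAAFT for non-Gaussian channels; residual cross-correlation error is
  bounded in tests at 0.1 but is not exactly zero.
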