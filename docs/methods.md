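# Methods

This note documents the models and procedures implemented in `hairwave`,
the assumptions behind them, the parameters that matter, and what the
synthetic study design does and does not establish.

## Problem setting

Mouse dorsal-skin transcriptomes sampled over the hair cycle mix several
cell populations whose relative sizes change dramatically: follicular
epithelial (matrix-derived, MX) cells proliferate massively during growth
(anagen), are removed by apoptosis during regression (catagen), and are
absent in quiescence (telogen), while mesenchymal dermal-papilla (DP) and
other background cells stay comparatively static.  Bulk expression of many
transcripts therefore oscillates with the ~31-day cycle even when their
intracellular expression is constant.  The analysis chain (i) detects
periodic transcripts on a non-uniform two-cycle time grid, (ii) treats them
as phase oscillators and quantifies their synchronization, (iii) asks
whether a minimal positively/negatively coupled mean-field oscillator model
can reproduce the observed two-cluster, out-of-phase locking, (iv) explains
the clusters mechanistically by deconvolving the matrix into an expanding
and a background population, and (v) screens for genes that could carry the
inhibitory feedback signal from the background to the expanding population.

Two experimental conditions — a naturally synchronized second cycle and a
depilation-induced cycle — are merged onto one postnatal axis by mapping
induced collection days {3, 5, 8, 12, 17} to morphologically equivalent
natural days {24, 25, 27, 29, 37}.  After merging, an induced sample is
treated as sharing the cycle phase of its matched natural day.

## Periodicity detection

Each log2 signal x(t_n) is fit with a truncated Fourier series
x̂(t) = a0 + Σ_l (a_l cos 2π f_l t + b_l sin 2π f_l t) over pre-selected
harmonics f_l = l/T of a fundamental period T.  On the default synthetic
grid T equals the 31-day span of the natural arm, harmonics are kept only
while the period stays above 3× the minimum sampling interval (higher
frequencies mask the rest of the spectrum in the g-statistic), and the
number of harmonics is capped so the design stays overdetermined on the
distinct time points (L = 6 on the default grid).

The fit is an M-estimator with Tukey's biweight (c = 4.685), iterated
reweighted least squares with the residual scale re-estimated each
iteration as 1.4826·MAD with a small-sample degrees-of-freedom correction.
Two safeguards matter at these sample sizes: the scale is floored at 0.3×
the initial least-squares scale (a redescending estimator with ~3 points
per coefficient can otherwise collapse onto an interpolating solution with
zero MAD), and an essentially exact initial fit short-circuits to ordinary
least squares with unit weights.  In the outlier-free quadratic regime the
solution coincides with OLS.

Periodicity is scored by Fisher's g — the share of the strongest frequency
in the spectrum S(f_l) = (N/4)(a_l² + b_l²); the N/4 constant is the
classical periodogram normalization and cancels from g.  Significance comes
from permutations: values are shuffled across time points, the entire
robust fit + g pipeline re-runs per shuffle, and p = (b+1)/(n+1) when at
least 10 null values reach the observed g.  Otherwise permutations escalate
(doubling, up to a cap) and, failing that, a generalized Pareto distribution
is fit by maximum likelihood to the null exceedances over the ~90th
percentile (at least 100 tail points) and supplies the tail probability.
Observed and null statistics are computed by one vectorized code path, so
the comparison is exactly exchangeable.  Benjamini–Hochberg q-values are
thresholded at 0.10, and calls whose dominant period equals the longest
grid period are flagged low-frequency oscillators (LFOs).

## Oscillator characterization

The Fourier fit is an analytic representation, so its Hilbert transform is
available in closed form (cos → sin, sin → −cos term by term).  The
instantaneous phase is ψ = atan2(x_H, x − a0) and the instantaneous
frequency is evaluated as (x ẋ_H − x_H ẋ)/(x² + x_H²) from closed-form
derivatives — the exact derivative of the unwrapped phase, with no 2π
discontinuities and no finite differencing.  Ensemble coherence is measured
by Z_m(t) = ⟨exp(i m ψ_j)⟩: |Z₁| detects one-cluster synchronization (and
saturates at |2p−1|·r for two antipodal clusters of unequal weight), |Z₂|
detects two-cluster structure.  The identity Z₁ = w₁ z_c1 + w₂ z_c2 with
cluster weights w_c holds exactly and is tested.

LFOs are split into two clusters at the two largest gaps of their circular
phase-shift distribution — deterministic and seed-free.  Cluster 1 is the
group whose mean expression maximum falls in the anagen window (default
postnatal days 24–40); a cut whose circular silhouette is below 0.2, or
that leaves one group under 5% of the probes, is flagged ambiguous.  The
control ensemble adds an independent Uniform[0, 2π) offset per probe, which
drops both order parameters to the O(1/√N) floor.

## Coupled mean-field model

Each oscillator obeys dθ_j/dt = ω_j + K_σ(j) R sin(Θ − θ_j) with mean field
R e^{iΘ} = ⟨e^{iθ}⟩, Lorentzian intrinsic frequencies (center ω0 = 2π/31
rad/day, half-width γ) and group couplings K₊ = K > 0 and K₋ = −ρK < 0.
For Lorentzian frequencies the Ott–Antonsen ansatz reduces the dynamics
exactly (N → ∞) to one complex ODE per group in the ω0-rotating frame:

    dz_s/dt = −γ z_s + (K_s/2)(W − W̄ z_s²),   W = p z₊ + (1−p) z₋.

At a quasi-steady out-of-phase state (z₊ = r₊, z₋ = −r₋ on the real axis)
the two fixed-point equations invert exactly:

    γ/K₊ = W(1 − r₊²)/(2 r₊),
    ρ = |K₋|/K₊ = r₋(1 − r₊²)/(r₊(1 − r₋²)),      W = p r₊ − (1−p) r₋.

Equal radii give ρ = 1.  The equations are homogeneous in the rates, so the
overall scale only sets the time units; the convention K₊ = 1 rad/day fixes
it.  Realizability requires γ > 0: assigning the smaller cluster to the
positive group flips the sign of W and yields γ < 0, which rejects that
configuration without any simulation.  The surviving configuration is then
checked dynamically (a perturbed fixed point must relax back, and small
random initial conditions must grow into the locked state).

A single coupling magnitude (ρ ≡ 1) was considered and rejected during
design: it leaves only the ray γ/K identifiable and — shown numerically by
attractor sweeps and by continuation of the rotating fixed point, which
exits the unit disk for γ > 0 — admits no traveling-wave attractor at all,
so the three-state bifurcation structure would be unreachable.  With ρ
determined by the radii, a scan over the positive fraction p (holding K, γ,
ρ fixed) produces, for ρ < 1, the sequence incoherent → traveling wave →
π-state.  Attractors are classified on the trailing quarter of a long
integration: incoherent if steady |Z₁| < 0.01; π-state if both groups are
synchronized (|z±| > 0.1), locked within 0.1 rad of π, and the mean field
drifts slower than 1e−3 rad/day; traveling wave if the drift Ω persists
(full-frame period 2π/(ω0 + |Ω|), shorter than the intrinsic 2π/ω0);
anything non-stationary is labeled unresolved rather than binned.  All
integrations use adaptive RK45 (rtol 1e−8, atol 1e−10); the finite-N model
(default N = 1000) is integrated with the same solver and agrees with the
reduced model within the across-seed 1-SD envelope at steady state.

## Two-population deconvolution

The mixing model is x_ij = f_i y1_j + (1 − f_i) y2_j on the linear scale
(the model is additive in concentrations; log2 input is refused).  Fitting
alternates two exact solves: per-gene OLS for (y1, y2) on the shared design
[f, 1−f], and per-sample scalar least squares for f_i, whose unconstrained
optimum projects onto [0, 1] (a 1-D convex quadratic, so the projection is
exact).  Each half-step solves its subproblem exactly, so the total squared
error is non-increasing; iteration stops at max|Δf| < 1e−6 or 500 sweeps.
f is initialized as a linear 0→1 ramp over samples in chronological order,
and label switching is resolved by orienting f so the expanding population
is depleted at the end of the cycle.

The trajectory is identifiable only up to an affine gauge: f → αf + β with
compensating y's reproduces the data exactly.  Recovery is therefore
assessed after min–max canonicalization of both trajectories to [0, 1], and
population expressions are compared after estimating the gauge map.  In the
canonical gauge the default synthetic conditions give RMSE(f) < 0.05.

Differential expression between the two estimated populations uses the
per-gene regression t = (y1 − y2)/se_diff with n−2 degrees of freedom,
standard errors from the unbiased residual variance and the design's
inverse Gram matrix; genes fit exactly (numerically zero residual variance)
are defined to have t = 0.  LFOs with BH q ≤ 0.10 are assigned to their
higher-expression population; this split coincides with the phase split for
essentially all assigned probes.  The negative control shuffles each
probe's values across time separately within each cycle arm and re-runs the
identical fit: no phase-aligned rise-and-collapse survives and LFOs show no
COD advantage.

## Feedback screen

Candidate carriers of the inhibitory signal are background-cluster LFOs
whose static-expression fit is poor (COD < 0.60) and whose observed/fitted
ratio exceeds 1 at every sample whose cycle phase falls 14–16 days after
initiation, just before the expanding population collapses.  The COD
ceiling is a genuinely open choice; 0.60 sits in the empty margin the
default synthetic conditions produce between step-up feedback probes
(COD ≤ ~0.55; the static model absorbs part of a sustained rise into an
inflated background level) and static background probes (COD ≥ ~0.66).
Both the window and the thresholds are configuration values.

## Enrichment and literature distance

Gene-set enrichment is the exact hypergeometric upper tail P(X ≥ k) with
target and signature restricted to a declared background.  Term relatedness
uses the Normalized Google Distance computed from supplied occurrence and
co-occurrence counts (no live queries): NGD = 0 for identical usage, 1 for
statistically independent terms (f(x,y) = f(x)f(y)/N — the closed form the
screen's default threshold of 1.0 comes from), infinity for terms that
never co-occur.  The formula is a ratio of log differences and hence
independent of the logarithm base.

## Synthetic study design

The generator is mechanistic: it draws static intracellular expressions for
an expanding and a background population (log-normal levels, 8× fold
separation for cluster probes, reciprocal between populations), mixes them
through a shared expanding-fraction trajectory, and multiplies by log-normal
measurement noise (sd 0.2 log2 units).  Defaults define the study
conditions:

* **Grids.** Natural days 23–54 (one full 31-day cycle: the fundamental
  period must fit inside the observation window to be spectrally
  identifiable; a grid ending at day 44 makes the second harmonic dominate
  by construction) plus induced days {3,…,17} mapped through the standard
  day map; 2 replicate arrays per collection day, which tightens the
  permutation null enough for the lower-amplitude background cluster to be
  detectable at desk scale.  These are synthetic defaults, not any
  experiment's grid.
* **Expansion.** Logistic rise from phase 0.5 d to a peak fraction of 0.8
  at 13 d, Gaussian-flank collapse pinned to 0 at 22 d, zero through
  quiescence.  The induced arm shares the merged-axis phase, which on its
  own day axis appears as the delayed anagen onset seen when comparing the
  two conditions.
* **Clusters.** 110 expanding-population probes and 190 background probes
  (positive fraction ≈ 0.63).  Expanding-cluster probes get per-probe
  Gaussian time shifts (sd 2.5 d) of the mixing curve — the differentiation
  program staggers their peaks — which broadens cluster 1's phase
  distribution relative to the purely population-driven cluster 2 and puts
  the fitted coupling-magnitude ratio below 1, the regime with a resolvable
  traveling-wave band.  The shared-fraction mixture remains exact for all
  other probes.
* **Feedback probes.** 12 probes, background-like but low-abundance (4×
  below other probes, as secreted signaling transcripts are), whose
  background expression steps up smoothly (logistic, center phase 14 d,
  width 1 d, plateau 3×) and stays up — an inhibitory signal switched on at
  catagen onset.  A transient pulse at the same position was rejected
  during design: any pulse large enough to break the static fit also
  destroys the probes' low-frequency classification on this grid.
* **Noise probes.** 300 constant-mean probes.

What passing tests show — and what they do not: the synthetic data share
the analysis chain's own structural assumptions (a single shared mixing
trajectory, static intracellular expression, log-normal noise, exactly two
populations).  Recovery under these conditions validates the implementation
and the identifiability of the procedure, not the biological adequacy of
the two-population or static-expression assumptions for real skin, which
also contains batch effects, probe-level artifacts and additional cell
types the generator does not emulate.

## Numerical choices and limitations

* Robust-fit constants: Tukey c = 4.685, MAD scale 1.4826 with √(n/(n−k))
  correction, coefficient tolerance 1e−8 (1e−6 inside the permutation
  loop), scale floor 0.3× the initial scale.
* Permutation estimator never returns 0 (b+1)/(n+1); GPD refinement needs
  ≥ 100 tail points and falls back to the empirical estimator when the MLE
  fails or the observed value sits below the tail threshold.
* Spectral ties resolve to the lowest frequency; phase shifts are reported
  in [0, period).
* ODE tolerances rtol 1e−8 / atol 1e−10; long-time horizon 600 model days
  for attractor classification; classification tolerances as listed above
  and configuration-exposed.
* Problem sizes in the default suite: 612 probes × 38 samples for the
  study-condition dataset; 1000 probes × 500 permutations × 3 replicate
  simulations for the false-discovery check; N = 1000 oscillators with a
  40-seed envelope for the finite-N comparison.
* The coupled model's rate scale (units of K) is conventional; only ratios
  are inferred from data.  Oscillator counts, coupling values and critical
  fractions printed by the analysis refer to the synthetic study design.
* The mixture model fits exactly two populations with static intracellular
  expression and no nonnegativity constraint on expressions; transient
  intracellular dynamics are only detected as misfit, not modeled.
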