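# hairwave

Analysis of periodic gene expression over the mouse hair cycle: periodicity
detection on non-uniformly sampled two-cycle time courses, phase-oscillator
characterization of the periodic transcripts, a two-group coupled
mean-field oscillator model of their out-of-phase synchronization, and
two-population deconvolution of the bulk expression matrix into an
expanding (follicular-epithelial-like) and a static background
(dermal-papilla-like) cell population, ending in a screen for genes that
could carry the negative-feedback signal between them.

It is written for computational biologists studying cyclic tissue renewal
who want each step of that chain as a tested, reusable library function,
exercised end-to-end on a mechanistic synthetic-data generator.

## The models at the core

**Detection.** Each log2 signal is fit by robust regression (Tukey-biweight
M-estimator) with a truncated Fourier series over harmonics f_l of a
fundamental period, scored by Fisher's g = max_l S(f_l) / Σ_l S(f_l) with
S(f_l) = (N/4)(a_l² + b_l²), and assigned a permutation p-value whose
extreme tail is refined by a generalized Pareto fit; Benjamini–Hochberg
q ≤ 0.10 calls a probe periodic.  Calls at the longest admissible period
(~31 d) are the low-frequency oscillators (LFOs).

**Oscillators.** The analytic signal of the Fourier fit gives each probe an
instantaneous phase ψ_j(t); coherence is measured by the order parameters
Z_m = ⟨e^{i m ψ_j}⟩.  The LFOs split into two phase clusters locked ~180°
apart, which the mean-field model

    dθ_j/dt = ω_j + K_σ(j) R sin(Θ − θ_j),   R e^{iΘ} = ⟨e^{iθ}⟩,

with Lorentzian ω_j and group couplings K₊ = K, K₋ = −ρK, reproduces via
its exact Ott–Antonsen reduction
dz_s/dt = −γ z_s + (K_s/2)(W − W̄ z_s²), W = p z₊ + (1−p) z₋.  The observed
cluster radii and sizes invert the steady state exactly for γ/K and ρ; only
the configuration with the smaller cluster negatively coupled is physical
(γ > 0) and dynamically stable, and scanning the positive fraction p yields
incoherent → traveling-wave → π-state attractors.

**Deconvolution.** On the linear scale, x_ij = f_i y1_j + (1 − f_i) y2_j is
fit by alternating exact least squares (per-gene regressions given the
fractions; per-sample box-constrained scalar solves given the expressions),
giving the expanding-population fraction per sample, per-gene population
expressions with regression t-statistics, and a coefficient of
determination whose shortfall flags transcripts with genuine intracellular
dynamics — the feedback-candidate screen.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic conditions and write their tables under `results/`:

```
python analysis/01_simulate_dataset.py
python analysis/02_detect_periodicity.py
python analysis/03_characterize_oscillators.py
python analysis/04_fit_coupled_model.py
python analysis/05_deconvolve_populations.py
python analysis/06_screen_feedback.py
```

Output of a full run (seed 0):

```
simulated 612 probes x 38 samples (seed 0)
probe classes: {'cluster1': 110, 'cluster2': 190, 'feedback': 12, 'noise': 300}
313 probes periodic at 10% FDR, 304 low-frequency oscillators
  cluster1 : periodic 0.99, LFO 0.99, median period 31.0 d
  cluster2 : periodic 0.95, LFO 0.95, median period 31.0 d
  feedback : periodic 1.00, LFO 1.00, median period 31.0 d
  noise    : periodic 0.04, LFO 0.01, median period 6.2 d
304 LFOs -> cluster sizes [111 193] (separation 15.4 d of a 31 d period)
mean |Z1| 0.289, |Z2| 0.689; cluster radii r_c1 0.856, r_c2 0.921; randomized |Z1| 0.048
  config1: K=1, gamma=+0.0226, |K-|/K+=0.530 -> stable
  config2: K=1, gamma=-0.0425, |K-|/K+=1.886 -> unrealizable (negative rate)
stable configuration: config1
bifurcation boundaries: {'incoherent->traveling_wave': 0.3875, 'traveling_wave->pi_state': 0.6375}
traveling-wave period 16.1-30.7 d vs pi-state period 31.0 d
LFO probes assigned: 97.7% (expanding 104, background 193)
median COD: LFO 0.84 vs other probes 0.01
negative control: LFO COD median 0.01 (no improvement over 0.01)
10 candidate signals (10/12 planted feedback probes recovered, 0 false positives)
```

Reading the numbers: nearly all planted periodic probes are recovered at
the 31-day period while noise probes stay at the nominal false-discovery
level; the phase split finds the two out-of-phase clusters 15.4 days apart
(half a period, i.e. ~180°); only the coupling configuration with the
smaller cluster pushed away from the mean field is physical and stable,
and the fitted system sits in the π-state with a traveling-wave band (much
shorter period) below it; the deconvolution assigns almost every LFO to the
population its phase predicts, the shuffled-time control shows none of this
structure, and the feedback screen recovers the planted catagen-onset
signals with no false positives.

`hairwave.pipeline.run_all(config, out_dir)` runs the same chain from one
configuration dictionary (or YAML file) and writes a JSON run report.

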