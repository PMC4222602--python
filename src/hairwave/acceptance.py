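"""Desk-scale headline computations of the analysis.

Three quantities summarize the chain's correctness at desk scale and are
recomputed from scratch by ``scripts/acceptance.py``:

* the Normalized Google Distance of two statistically independent terms
  (closed form: exactly 1),
* the steady circular separation of the two cluster order parameters in the
  fitted two-group coupled-oscillator model (180 degrees in the stable
  out-of-phase configuration), and
* the realized false-discovery proportion of the periodicity pipeline on
  labeled synthetic data at the nominal Benjamini-Hochberg level of 10%.
"""

from __future__ import annotations

import numpy as np

from hairwave.coupled import simulate_reduced, solve_steady_parameters
from hairwave.enrichment import independent_cooccurrence, ngd
from hairwave.periodicity import bh_fdr, build_frequency_grid, permutation_pvalue
from hairwave.simulate import SimulationConfig, simulate_dataset


def ngd_of_independent_terms(
    fx: float = 1000.0, fy: float = 2000.0, n_pages: float = 1e6
) -> float:
    """NGD of a term pair whose co-occurrence equals the independence value."""
    fxy = independent_cooccurrence(fx, fy, n_pages)
    return ngd(fx, fy, fxy, n_pages)


def steady_phase_separation_degrees(
    r: float = 0.9,
    p: float = 0.64,
    n_seeds: int = 10,
    seed: int = 0,
    t_end: float = 200.0,
) -> float:
    """Long-time cluster phase separation of the stable coupling configuration.

    Fits (K, gamma) from symmetric cluster radii ``r`` at positive fraction
    ``p`` via the steady-state equations, integrates the reduced model from
    small random-phase initial conditions (|z| = 0.01) for ``t_end`` days,
    and returns the circular separation |arg z_+ - arg z_-| in degrees,
    averaged over ``n_seeds`` independent starts.
    """
    fit = solve_steady_parameters(r, r, p)
    params = fit.params()
    seps = []
    for k in range(n_seeds):
        rng = np.random.default_rng((seed + 1) * 1000 + k)
        zp0 = 0.01 * np.exp(1j * rng.uniform(0.0, 2.0 * np.pi))
        zm0 = 0.01 * np.exp(1j * rng.uniform(0.0, 2.0 * np.pi))
        _, zp, zm = simulate_reduced(params, zp0, zm0, (0.0, t_end))
        dphi = np.angle(zp[-1]) - np.angle(zm[-1])
        seps.append(np.degrees(np.abs(np.angle(np.exp(1j * dphi)))))
    return float(np.mean(seps))


def default_merged_times() -> np.ndarray:
    """Merged sample times of the default synthetic study design."""
    cfg = SimulationConfig(
        n_probes_cluster1=1, n_probes_cluster2=1, n_noise_probes=0, n_feedback_probes=0
    )
    ds, _ = simulate_dataset(cfg)
    return ds.merged_day


def realized_fdp_percent(
    seed: int = 0,
    n_seeds: int = 3,
    n_periodic: int = 200,
    n_noise: int = 800,
    amplitude: float = 2.0,
    noise_sd: float = 1.0,
    period: float = 31.0,
    n_perm: int = 500,
    fdr: float = 0.10,
) -> float:
    """Mean realized false-discovery proportion of the periodicity pipeline.

    Simulates ``n_periodic`` sinusoidal probes (period ``period`` days,
    amplitude-to-noise ratio ``amplitude``/``noise_sd``) and ``n_noise``
    pure-noise probes on the merged synthetic time grid, runs the robust
    Fourier / Fisher-g / GPD-refined permutation / BH pipeline, calls probes
    at q <= ``fdr`` and returns 100 x the mean false-discovery proportion
    among the calls over ``n_seeds`` replicate simulations.
    """
    times = default_merged_times()
    basis = build_frequency_grid(times)
    fdps = []
    for rep in range(n_seeds):
        rng = np.random.default_rng((seed + 1) * 7919 + rep)
        n_total = n_periodic + n_noise
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_total)
        signals = np.empty((n_total, len(times)))
        for j in range(n_total):
            base = rng.normal(8.0, 1.0)
            clean = base + (
                amplitude * np.cos(2.0 * np.pi * times / period - phases[j])
                if j < n_periodic
                else 0.0
            )
            signals[j] = clean + rng.normal(0.0, noise_sd, size=len(times))
        p_values = np.empty(n_total)
        for j in range(n_total):
            p_values[j], _, _ = permutation_pvalue(
                signals[j], times, basis, n_perm=n_perm,
                seed=(seed + 1) * 100_000 + rep * 2000 + j,
            )
        q = bh_fdr(p_values)
        called = q <= fdr
        n_called = int(called.sum())
        false = int(called[n_periodic:].sum())
        fdps.append(false / n_called if n_called else 0.0)
    return float(100.0 * np.mean(fdps))
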