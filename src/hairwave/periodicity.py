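"""Periodicity detection on non-uniformly sampled expression signals.

Each signal is fit with a discrete Fourier series over a pre-selected
frequency grid by robust linear regression (M-estimator with Tukey's
biweight), summarized by the periodogram-style power spectrum and Fisher's
g-statistic (relative power of the strongest frequency), and assigned a
permutation p-value whose extreme tail is refined with a generalized Pareto
distribution fit.  Benjamini-Hochberg q-values control the false discovery
rate across probes, and the Principal Periodic Component (PPC) -- the
dominant-frequency term of the fit -- yields each probe's period, amplitude,
phase and time-to-next-maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TUKEY_C = 4.685  # classical 95%-efficiency biweight tuning constant
MAD_SCALE = 1.4826  # makes MAD consistent for the normal distribution


class GridError(ValueError):
    """No admissible frequency grid for the given sampling times."""


class RegressionError(ValueError):
    """The Fourier design is unusable (rank deficient or too small)."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. all-zero spectrum)."""


@dataclass(frozen=True)
class FourierBasis:
    """Strictly increasing positive frequencies (cycles/day)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or len(f) < 1:
            raise GridError("need at least one frequency")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise GridError("frequencies must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.frequencies

    def design_matrix(self, times: np.ndarray) -> np.ndarray:
        """Columns [1, cos(2 pi f_1 t), sin(2 pi f_1 t), ...]."""
        t = np.asarray(times, dtype=float)
        cols = [np.ones_like(t)]
        for f in self.frequencies:
            w = 2.0 * np.pi * f * t
            cols.append(np.cos(w))
            cols.append(np.sin(w))
        return np.column_stack(cols)


@dataclass
class FourierFit:
    a0: float
    a: np.ndarray  # cosine coefficients per frequency
    b: np.ndarray  # sine coefficients per frequency
    weights: np.ndarray  # robust weights per time point, in [0, 1]
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    mad: float
    converged: bool
    n_iter: int


def build_frequency_grid(
    times: np.ndarray,
    fundamental_factor: float = 1.0,
    min_spacing_factor: float = 3.0,
) -> FourierBasis:
    """Harmonic frequency grid for a non-uniform time grid.

    Frequencies are harmonics f_l = l / T of a fundamental period
    T = span(times) * ``fundamental_factor``; only periods of at least
    ``min_spacing_factor`` times the minimum sampling interval are kept, since
    frequencies near or above the sampling rate mask the rest of the spectrum
    in the g-statistic.  The number of harmonics is additionally capped so the
    Fourier design stays overdetermined on the distinct time points.
    """
    t = np.unique(np.asarray(times, dtype=float))
    if len(t) < 6:
        raise GridError("need at least 6 distinct times")
    span = t[-1] - t[0]
    min_dt = np.diff(t).min()
    fundamental = span * fundamental_factor
    min_period = min_spacing_factor * min_dt
    l_max = int(np.floor(fundamental / min_period))
    # keep 2L + 1 strictly below the number of distinct times
    l_max = min(l_max, (len(t) - 2) // 2)
    if l_max < 2:
        raise GridError("fewer than 2 admissible frequencies for this grid")
    freqs = np.arange(1, l_max + 1) / fundamental
    return FourierBasis(freqs)


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def fit_fourier_robust(
    signal: np.ndarray,
    times: np.ndarray,
    basis: FourierBasis,
    tuning: float = TUKEY_C,
    tol: float = 1e-8,
    max_iter: int = 100,
    design: np.ndarray | None = None,
) -> FourierFit:
    """IRLS Fourier-series fit with Tukey-biweight weights.

    The residual scale is re-estimated each iteration as 1.4826 * MAD of the
    current residuals with a small-sample degrees-of-freedom correction, and
    floored at a fraction of the initial least-squares scale: with few points
    per coefficient a redescending M-estimator can otherwise collapse onto an
    interpolating solution (zero MAD, all remaining points rejected).  When
    the initial fit is already essentially exact the least-squares solution
    is returned with unit weights; in the outlier-free quadratic regime the
    solution coincides with ordinary least squares.  ``design`` lets callers
    reuse a precomputed design matrix (the permutation loop re-fits thousands
    of shuffles of the same grid).
    """
    y = np.asarray(signal, dtype=float)
    X = basis.design_matrix(np.asarray(times, dtype=float)) if design is None else design
    n, k = X.shape
    if len(y) != n:
        raise RegressionError("signal and times lengths differ")
    if n <= k:
        raise RegressionError(f"under-determined design: {n} points for {k} coefficients")
    if np.linalg.matrix_rank(X) < k:
        raise RegressionError("rank-deficient Fourier design")

    df_correction = np.sqrt(n / max(n - k, 1))
    beta = _weighted_lstsq(X, y, np.ones(n))
    w = np.ones(n)
    scale0 = MAD_SCALE * np.median(np.abs(y - X @ beta)) * df_correction
    converged = False
    n_iter = 0
    if scale0 < 1e-12 * max(1.0, np.median(np.abs(y))):
        converged = True  # essentially exact least-squares fit
    else:
        scale_floor = 0.3 * scale0
        for n_iter in range(1, max_iter + 1):
            resid = y - X @ beta
            scale = max(MAD_SCALE * np.median(np.abs(resid)) * df_correction, scale_floor)
            u = resid / (tuning * scale)
            w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
            if w.sum() < k:  # degenerate: too many points rejected
                w = np.ones(n)
            beta_new = _weighted_lstsq(X, y, w)
            if np.max(np.abs(beta_new - beta)) < tol * max(1.0, np.max(np.abs(beta))):
                beta = beta_new
                converged = True
                break
            beta = beta_new

    fitted = X @ beta
    resid = y - fitted
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return FourierFit(
        a0=float(beta[0]),
        a=beta[1::2].copy(),
        b=beta[2::2].copy(),
        weights=w,
        fitted=fitted,
        residuals=resid,
        r2=float(r2),
        mad=float(np.median(np.abs(resid))),
        converged=converged,
        n_iter=n_iter,
    )


def power_spectrum(fit: FourierFit, n_points: int) -> np.ndarray:
    """Periodogram-style spectrum S(f_l) = (N/4) (a_l^2 + b_l^2).

    The constant factor is immaterial to the g-statistic and the permutation
    p-value; N/4 matches the classical periodogram of a fitted harmonic.
    """
    return 0.25 * n_points * (fit.a**2 + fit.b**2)


def g_statistic(spectrum: np.ndarray) -> float:
    """Fisher's g: max spectral power over total spectral power."""
    s = np.asarray(spectrum, dtype=float)
    total = s.sum()
    if total <= 0:
        raise UndefinedStatisticError("g-statistic undefined for all-zero spectrum")
    return float(s.max() / total)


def _g_of(signal, X, basis, tuning, tol, max_iter):
    fit = fit_fourier_robust(signal, None, basis, tuning, tol, max_iter, design=X)
    return g_statistic(power_spectrum(fit, len(signal)))


def _robust_g_batch(
    Y: np.ndarray,
    X: np.ndarray,
    tuning: float = TUKEY_C,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """g-statistics for a batch of signals sharing one design matrix.

    Vectorizes the same IRLS-with-scale-floor scheme as
    :func:`fit_fourier_robust` across the rows of ``Y`` (shape (B, n)); the
    permutation null re-fits thousands of shuffles of one probe, which all
    share the design.  Columns whose initial least-squares fit is already
    essentially exact keep it.
    """
    B, n = Y.shape
    k = X.shape[1]
    dfc = np.sqrt(n / max(n - k, 1))
    pinv = np.linalg.pinv(X)
    Yt = Y.T  # n x B
    beta = pinv @ Yt  # k x B
    resid0 = Yt - X @ beta
    scale0 = MAD_SCALE * np.median(np.abs(resid0), axis=0) * dfc
    exact = scale0 < 1e-12 * np.maximum(1.0, np.median(np.abs(Yt), axis=0))
    floor = 0.3 * scale0
    active = ~exact
    for _ in range(max_iter):
        if not active.any():
            break
        resid = Yt[:, active] - X @ beta[:, active]
        scale = np.maximum(
            MAD_SCALE * np.median(np.abs(resid), axis=0) * dfc, floor[active]
        )
        u = resid / (tuning * scale[None, :])
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        bad = w.sum(axis=0) < k
        if bad.any():
            w[:, bad] = 1.0
        A = np.einsum("ni,nb,nj->bij", X, w, X)
        # columns whose surviving support cannot determine the coefficients
        # fall back to unit weights (the plain least-squares fit)
        det = np.linalg.det(A)
        gram = X.T @ X
        singular = ~np.isfinite(det) | (det <= 1e-12 * np.linalg.det(gram))
        if singular.any():
            w[:, singular] = 1.0
            A[singular] = gram
        rhs = np.einsum("ni,nb->bi", X, w * Yt[:, active])
        beta_new = np.linalg.solve(A, rhs[..., None])[..., 0].T  # k x n_active
        delta = np.max(np.abs(beta_new - beta[:, active]), axis=0)
        ref = np.maximum(1.0, np.max(np.abs(beta[:, active]), axis=0))
        beta[:, active] = beta_new
        still = delta >= tol * ref
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    a = beta[1::2]
    b = beta[2::2]
    power = a**2 + b**2  # L x B (constant factor cancels in g)
    total = power.sum(axis=0)
    return np.where(total > 0, power.max(axis=0) / np.maximum(total, 1e-300), np.nan)


def gpd_tail_pvalue(
    null_stats: np.ndarray,
    observed: float,
    n_tail: int | None = None,
    min_tail: int = 100,
) -> tuple[float, bool]:
    """Tail p-value from a generalized Pareto fit to extreme null statistics.

    Exceedances over a high threshold (the largest ``n_tail`` null values,
    default 10% of the sample but at least ``min_tail``) are fit by maximum
    likelihood, and P(stat >= observed) is the tail fraction times the GPD
    survival function.  Returns ``(p, used_gpd)``; on failure the caller
    falls back to the empirical estimator.
    """
    null = np.sort(np.asarray(null_stats, dtype=float))
    n = len(null)
    if n_tail is None:
        n_tail = max(min_tail, n // 10)
    n_tail = min(n_tail, n // 2)
    if n_tail < 10:
        return np.nan, False
    # threshold midway between the last kept and first excluded order stat
    thresh = 0.5 * (null[-n_tail] + null[-n_tail - 1])
    excess = null[-n_tail:] - thresh
    if observed <= thresh or np.all(excess <= 0):
        return np.nan, False
    try:
        shape, _, sc = stats.genpareto.fit(excess, floc=0.0)
        p = (n_tail / n) * stats.genpareto.sf(observed - thresh, shape, loc=0.0, scale=sc)
    except Exception:
        return np.nan, False
    if not np.isfinite(p):
        return np.nan, False
    return float(max(p, np.finfo(float).tiny)), True


def permutation_pvalue(
    signal: np.ndarray,
    times: np.ndarray,
    basis: FourierBasis,
    n_perm: int = 1000,
    seed: int = 0,
    n_max: int | None = None,
    min_exceedances: int = 10,
    use_gpd: bool = True,
    tuning: float = TUKEY_C,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[float, int, bool]:
    """Permutation p-value for the g-statistic, with GPD tail refinement.

    Values are shuffled across time points and the whole fit + g pipeline is
    re-run on each shuffle.  With at least ``min_exceedances`` null values at
    or above the observed g the unbiased empirical estimator (b+1)/(n+1) is
    returned directly; otherwise permutations escalate up to ``n_max`` and,
    failing that, a generalized Pareto distribution fit to the null tail
    supplies the p-value.  Returns ``(p, n_used, used_gpd)``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n_max = n_perm if n_max is None else max(n_max, n_perm)
    y = np.asarray(signal, dtype=float)
    X = basis.design_matrix(np.asarray(times, dtype=float))
    # observed statistic comes from the same batched routine as the null so
    # the permutation comparison is exactly exchangeable
    g_obs = float(_robust_g_batch(y[None, :], X, tuning, tol, max_iter)[0])
    if not np.isfinite(g_obs):
        raise UndefinedStatisticError("g-statistic undefined for this signal")

    rng = np.random.default_rng(seed)
    null: list[np.ndarray] = []
    n_done = 0
    batch = n_perm
    while True:
        perms = rng.permuted(np.broadcast_to(y, (batch, len(y))), axis=1)
        null.append(_robust_g_batch(perms, X, tuning, tol, max_iter))
        n_done += batch
        exceed = int(sum((arr >= g_obs).sum() for arr in null))
        if exceed >= min_exceedances or n_done >= n_max:
            break
        batch = min(n_done, n_max - n_done)  # double until the cap

    null_arr = np.concatenate(null)
    exceed = int(np.sum(null_arr >= g_obs))
    if exceed >= min_exceedances or not use_gpd:
        return (exceed + 1) / (n_done + 1), n_done, False
    p, ok = gpd_tail_pvalue(null_arr, g_obs)
    if ok:
        return p, n_done, True
    return (exceed + 1) / (n_done + 1), n_done, False


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def principal_component(fit: FourierFit, basis: FourierBasis, n_points: int) -> tuple[float, float, float]:
    """Dominant-frequency term of the fit: (frequency, amplitude, phase).

    The PPC is A cos(2 pi f t - phi) with A = sqrt(a^2 + b^2) and
    phi = atan2(b, a); spectral ties resolve to the lowest frequency.
    """
    spec = power_spectrum(fit, n_points)
    if spec.sum() <= 0:
        raise UndefinedStatisticError("zero spectrum has no principal component")
    idx = int(np.argmax(spec))  # argmax takes the first (lowest-frequency) max
    a, b = fit.a[idx], fit.b[idx]
    return float(basis.frequencies[idx]), float(np.hypot(a, b)), float(np.arctan2(b, a))


def phase_shift_days(ppc_frequency: float, ppc_phase: float, t_ref: float) -> float:
    """Time from ``t_ref`` to the next maximum of the PPC, in [0, period).

    Maxima of A cos(2 pi f t - phi) sit at t = phi / (2 pi f) mod 1/f.
    """
    period = 1.0 / ppc_frequency
    t_max = ppc_phase / (2.0 * np.pi * ppc_frequency)
    shift = (t_max - t_ref) % period
    return float(shift)


def call_periodicity(
    values: np.ndarray,
    times: np.ndarray,
    probe_ids: np.ndarray,
    basis: FourierBasis | None = None,
    n_perm: int = 1000,
    n_max: int | None = None,
    seed: int = 0,
    fdr: float = 0.10,
    t_ref: float | None = None,
    use_gpd: bool = True,
) -> pd.DataFrame:
    """Run the full detection pipeline over a log2 probe-by-sample matrix.

    Returns one row per probe with the g-statistic, permutation p-value,
    BH q-value, PPC period/phase/amplitude, time-to-next-maximum, fit quality
    and the periodic / low-frequency-oscillator (LFO) flags.  LFOs are calls
    whose PPC period equals the longest period in the grid.  Per-probe
    permutation streams are derived from the master seed by probe index.
    """
    t = np.asarray(times, dtype=float)
    basis = basis or build_frequency_grid(t)
    t_ref = float(t.min()) if t_ref is None else t_ref
    longest_period = float(basis.periods.max())
    X = basis.design_matrix(t)

    rows = []
    for j in range(values.shape[0]):
        y = np.asarray(values[j], dtype=float)
        fit = fit_fourier_robust(y, t, basis, design=X)
        spec = power_spectrum(fit, len(y))
        if spec.sum() <= 0:
            rows.append(
                dict(probe_id=probe_ids[j], g=np.nan, p=1.0, ppc_period=np.nan,
                     ppc_amplitude=np.nan, ppc_phase=np.nan, phase_shift_days=np.nan,
                     r2=fit.r2, mad=fit.mad, used_gpd=False)
            )
            continue
        g = g_statistic(spec)
        p, _, used_gpd = permutation_pvalue(
            y, t, basis, n_perm=n_perm, n_max=n_max, seed=seed + j, use_gpd=use_gpd
        )
        freq, amp, phase = principal_component(fit, basis, len(y))
        rows.append(
            dict(
                probe_id=probe_ids[j],
                g=g,
                p=p,
                ppc_period=1.0 / freq,
                ppc_amplitude=amp,
                ppc_phase=phase,
                phase_shift_days=phase_shift_days(freq, phase, t_ref),
                r2=fit.r2,
                mad=fit.mad,
                used_gpd=used_gpd,
            )
        )
    calls = pd.DataFrame(rows)
    calls["q"] = bh_fdr(calls["p"].to_numpy())
    calls["is_periodic"] = calls["q"] <= fdr
    calls["is_lfo"] = calls["is_periodic"] & np.isclose(calls["ppc_period"], longest_period)
    return calls
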