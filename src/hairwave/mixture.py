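"""Two-population in-silico microdissection of bulk expression.

Bulk samples are modeled as a linear mixture of two cell populations with
static intracellular expression: x_ij = f_i y1_j + (1 - f_i) y2_j, where f_i
is the fraction of the transiently expanding population in sample i and
y1_j, y2_j are gene j's (linear-scale) expression in the expanding and
background populations.  Fractions and expressions are estimated by
alternating exact least-squares solves -- per-gene two-parameter regressions
given f, and per-sample box-constrained scalar solves given the y's -- so
the total squared error never increases.  Differential expression between
the two estimated populations is summarized by a regression t-statistic, and
genes poorly captured by the static-expression assumption but rising in a
short window before the expanding population collapses are screened as
negative-feedback candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hairwave.io import ExpressionDataset, ValidationError
from hairwave.periodicity import bh_fdr
from hairwave.simulate import cycle_phase, simulate_null_dataset


class ScaleError(ValidationError):
    """The mixture model requires linear-scale expression."""


class UnidentifiableError(ValueError):
    """The two populations cannot be distinguished."""


@dataclass
class MixtureFit:
    fractions: np.ndarray  # f_i per sample, in [0, 1]
    y_expanding: np.ndarray  # y1_j per gene
    y_background: np.ndarray  # y2_j per gene
    se_expanding: np.ndarray
    se_background: np.ndarray
    se_diff: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    cod: np.ndarray  # per-gene coefficient of determination
    converged: bool
    n_iter: int
    objective: list[float] = field(default_factory=list)

    def fitted(self) -> np.ndarray:
        f = self.fractions[None, :]
        return f * self.y_expanding[:, None] + (1.0 - f) * self.y_background[:, None]


def solve_fractions(x_col: np.ndarray, y1: np.ndarray, y2: np.ndarray) -> float:
    """Exact box-constrained scalar least squares for one sample's fraction.

    Minimizing sum_j (x_j - f y1_j - (1-f) y2_j)^2 over f in [0, 1] is a 1-D
    convex quadratic; the unconstrained optimum
    f* = sum d (x - y2) / sum d^2 with d = y1 - y2 projects onto the box.
    """
    d = y1 - y2
    denom = np.dot(d, d)
    if denom <= 0:
        raise UnidentifiableError("populations have identical expression for all genes")
    f = np.dot(d, x_col - y2) / denom
    return float(np.clip(f, 0.0, 1.0))


def _solve_expressions(values: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene OLS for (y1, y2) on design [f, 1-f], all genes at once."""
    D = np.column_stack([f, 1.0 - f])
    gram = D.T @ D
    rhs = D.T @ values.T  # 2 x genes
    sol = np.linalg.solve(gram, rhs)
    return sol[0], sol[1]


def fit_mixture(
    ds: ExpressionDataset,
    tol: float = 1e-6,
    max_iter: int = 500,
    fdr: float = 0.10,
) -> MixtureFit:
    """Alternating estimation of sample fractions and population expressions.

    The fraction trajectory is initialized as a linear ramp from 0 to 1 over
    samples in chronological (merged-day) order.  Iteration stops when the
    largest fraction change falls below ``tol``.  Label switching is resolved
    by orienting f so the expanding population is depleted at the end of the
    cycle (terminal fractions low); population 1 is then the expanding one.
    Requires linear-scale input: the mixing model is additive in
    concentrations, not in log space.
    """
    if ds.scale != "linear":
        raise ScaleError("mixture model requires linear-scale expression (no log2)")
    n_genes, n_samples = ds.values.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if n_genes < 2:
        raise ValueError("need at least 2 genes")

    order_days = ds.merged_day if ds.merged_day is not None else ds.sample_day
    rank = np.argsort(np.argsort(order_days, kind="stable"), kind="stable")
    f = rank / (n_samples - 1)

    x = ds.values
    objective: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        y1, y2 = _solve_expressions(x, f)
        d = y1 - y2
        denom = np.dot(d, d)
        if denom <= 0:
            raise UnidentifiableError("populations collapsed to identical expression")
        f_new = np.clip((d @ (x - y2[:, None])) / denom, 0.0, 1.0)
        resid = x - (np.outer(y1, f_new) + np.outer(y2, 1.0 - f_new))
        objective.append(float(np.sum(resid**2)))
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break

    # orient so the expanding population vanishes at the end of the cycle
    k_tail = max(2, n_samples // 5)
    tail_idx = np.argsort(order_days)[-k_tail:]
    if f[tail_idx].mean() > (1.0 - f[tail_idx]).mean():
        f = 1.0 - f
        y1, y2 = _solve_expressions(x, f)

    stats_df = population_expression_stats(ds.values, f)
    cod = cod_per_gene(ds.values, f, stats_df["y1"].to_numpy(), stats_df["y2"].to_numpy())
    q = bh_fdr(stats_df["p"].to_numpy())
    return MixtureFit(
        fractions=f,
        y_expanding=stats_df["y1"].to_numpy(),
        y_background=stats_df["y2"].to_numpy(),
        se_expanding=stats_df["se1"].to_numpy(),
        se_background=stats_df["se2"].to_numpy(),
        se_diff=stats_df["se_diff"].to_numpy(),
        t_stat=stats_df["t"].to_numpy(),
        p_value=stats_df["p"].to_numpy(),
        q_value=q,
        cod=cod,
        converged=converged,
        n_iter=n_iter,
        objective=objective,
    )


def population_expression_stats(values: np.ndarray, f: np.ndarray) -> pd.DataFrame:
    """Per-gene regression of expression on [f, 1-f] with standard errors.

    Standard errors come from the unbiased residual variance and the inverse
    Gram matrix of the shared design; t = (y1 - y2) / se_diff with
    n_samples - 2 degrees of freedom, two-sided p from the t distribution.
    """
    n_genes, n_samples = values.shape
    dof = n_samples - 2
    if dof <= 0:
        raise ValueError("need more than 2 samples for standard errors")
    if np.ptp(f) == 0:
        raise UnidentifiableError("constant fractions cannot separate populations")
    D = np.column_stack([f, 1.0 - f])
    gram_inv = np.linalg.inv(D.T @ D)
    beta = gram_inv @ D.T @ values.T  # 2 x genes
    resid = values.T - D @ beta
    sigma2 = np.sum(resid**2, axis=0) / dof
    var1 = sigma2 * gram_inv[0, 0]
    var2 = sigma2 * gram_inv[1, 1]
    c = np.array([1.0, -1.0])
    var_diff = sigma2 * (c @ gram_inv @ c)
    se_diff = np.sqrt(var_diff)
    # an exactly-fit gene has numerically-zero residual variance; its
    # difference is 0/0 noise, not evidence, so its t is defined as 0
    floor = 1e-10 * np.maximum(np.abs(beta).max(axis=0), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_diff > floor, (beta[0] - beta[1]) / se_diff, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {
            "y1": beta[0],
            "y2": beta[1],
            "se1": np.sqrt(var1),
            "se2": np.sqrt(var2),
            "se_diff": se_diff,
            "t": t,
            "p": p,
        }
    )


def cod_per_gene(values: np.ndarray, f: np.ndarray, y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Coefficient of determination of the mixture fit, per gene.

    Zero-variance genes have no defined COD and are returned as NaN.
    """
    fitted = np.outer(y1, f) + np.outer(y2, 1.0 - f)
    ss_res = np.sum((values - fitted) ** 2, axis=1)
    ss_tot = np.sum((values - values.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cod = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    return cod


def assign_populations(
    t_stat: np.ndarray,
    q_value: np.ndarray,
    lfo_flags: np.ndarray,
    fdr: float = 0.10,
) -> np.ndarray:
    """Assign low-frequency oscillators to their higher-expression population.

    LFO probes whose differential t-statistic survives the BH threshold are
    assigned 'expanding' (t > 0) or 'background' (t < 0); everything else is
    'none'.
    """
    out = np.full(len(t_stat), "none", dtype=object)
    sig = np.asarray(lfo_flags, dtype=bool) & (np.asarray(q_value) <= fdr)
    out[sig & (np.asarray(t_stat) > 0)] = "expanding"
    out[sig & (np.asarray(t_stat) < 0)] = "background"
    return out


def negative_control(ds: ExpressionDataset, seed: int, **fit_kwargs) -> MixtureFit:
    """Permutation negative control: shuffle time courses, refit identically.

    Each probe's values are permuted across time points (separately within
    each cycle group) to destroy any relation between expression and the
    cycle, then the exact same mixture fit is run.
    """
    return fit_mixture(simulate_null_dataset(ds, seed), **fit_kwargs)


def feedback_candidates(
    ds: ExpressionDataset,
    fit: MixtureFit,
    cluster_labels: np.ndarray,
    lfo_flags: np.ndarray,
    window: tuple[float, float] = (14.0, 16.0),
    cod_max: float = 0.60,
    ratio_min: float = 1.0,
) -> pd.DataFrame:
    """Screen for genes that could close the negative-feedback loop.

    Candidates are background-cluster (cluster 2) low-frequency oscillators
    whose expression is poorly described by static intracellular expression
    (COD < ``cod_max``) and whose observed/fitted ratio exceeds
    ``ratio_min`` at every sample whose cycle phase falls ``window`` days
    after initiation -- just before the expanding population collapses.
    Returns the candidate table with per-sample ratio trajectories.
    """
    phase = cycle_phase(ds)
    in_window = (phase >= window[0]) & (phase <= window[1])
    if not np.any(in_window):
        raise ValueError(f"no samples fall in the window {window} days after initiation")
    fitted = fit.fitted()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fitted > 0, ds.values / fitted, np.inf)
    eligible = (
        (np.asarray(cluster_labels) == 2)
        & np.asarray(lfo_flags, dtype=bool)
        & (fit.cod < cod_max)
    )
    bump = np.all(ratio[:, in_window] > ratio_min, axis=1)
    mask = eligible & bump
    out = pd.DataFrame(
        {
            "probe_id": ds.probe_ids[mask],
            "cod": fit.cod[mask],
            "min_window_ratio": ratio[mask][:, in_window].min(axis=1)
            if mask.any()
            else np.array([]),
        }
    )
    ratio_cols = pd.DataFrame(
        ratio[mask], columns=[f"ratio_{s}" for s in ds.sample_ids], index=out.index
    )
    return pd.concat([out, ratio_cols], axis=1)
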