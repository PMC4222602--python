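"""Seeded synthetic expression datasets with known ground truth.

The generator emulates the statistical structure the analysis chain assumes:
two out-of-phase clusters of ~monthly periodic probes with asymmetric sizes,
generated mechanistically by mixing a transiently expanding cell population
with a static background population (each probe having static intracellular
expression), plus non-periodic noise probes and "feedback" probes whose
intracellular background expression bumps upward in a short window before the
expanding population collapses.  Both a natural and an induced cycle are
simulated on a per-cycle grid and merged onto the unified postnatal axis.

The default configuration is the study condition every test runs under; the
time grid is a synthetic default, not the grid of any particular experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from hairwave.io import INDUCED, NATURAL, ExpressionDataset, TimeMap


class ConfigError(ValueError):
    """Simulation configuration is invalid."""


#: Synthetic default sampling grids (days).  Natural days are postnatal; the
#: induced grid is days after depilation and is merged via the study time map.
#: The natural grid spans one full cycle (initiation through late quiescence,
#: ~31 days) so the fundamental period is identifiable on the merged axis.
#: This is a synthetic default, not the grid of any particular experiment.
DEFAULT_NATURAL_DAYS = (
    23.0, 25.0, 27.0, 29.0, 31.0, 33.0, 35.0, 37.0, 39.0, 41.0, 44.0, 47.0, 50.0, 54.0,
)
DEFAULT_INDUCED_DAYS = (3.0, 5.0, 8.0, 12.0, 17.0)

#: Cycle initiation on the postnatal axis: end of morphogenesis.  Days since
#: initiation for natural samples are postnatal day minus this value; induced
#: samples use their day after depilation directly.
INITIATION_DAY = 23.0


@dataclass(frozen=True)
class ExpansionParams:
    """Shape of the expanding-population fraction over one cycle.

    Days are measured since cycle initiation.  The fraction rises smoothly
    (logistic) from 0 at ``onset_day`` to ``peak_fraction`` at ``peak_day``,
    falls along a Gaussian flank to exactly 0 at ``collapse_day`` and stays 0
    afterwards (quiescence).
    """

    onset_day: float = 0.5
    peak_day: float = 13.0
    collapse_day: float = 22.0
    peak_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (self.collapse_day > self.peak_day > self.onset_day):
            raise ConfigError("need collapse_day > peak_day > onset_day")
        if not (0.0 < self.peak_fraction <= 1.0):
            raise ConfigError("peak_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BumpParams:
    """Intracellular upward shift of feedback probes at catagen onset.

    The background-population expression of feedback probes is multiplied by
    a smooth logistic step 1 + (amplitude_fold - 1) * sigmoid((phase -
    center_day) / width_days): baseline 1 through anagen, rising around
    ``center_day`` days after initiation, plateau ``amplitude_fold`` through
    quiescence -- an inhibitory signal switched on just before the expanding
    population collapses and left on.
    """

    center_day: float = 14.0
    width_days: float = 1.0
    amplitude_fold: float = 3.0


@dataclass(frozen=True)
class SimulationConfig:
    n_probes_cluster1: int = 110
    n_probes_cluster2: int = 190
    n_noise_probes: int = 300
    n_feedback_probes: int = 12
    period_days: float = 31.0
    cluster1_peak_day: float = 34.0  # postnatal day the expanding cluster peaks
    cluster2_peak_day: float = 46.0  # postnatal day the background cluster peaks
    # per-probe time shift (days) of the mixing curve for expanding-cluster
    # probes: the expanding lineage peaks at staggered times (differentiation
    # program), so cluster 1 has a broader phase distribution than the purely
    # population-driven background cluster, whose mixture stays exact
    phase_jitter_sd: float = 2.5
    noise_sd_log2: float = 0.2
    expansion_params: ExpansionParams = field(default_factory=ExpansionParams)
    bump_params: BumpParams = field(default_factory=BumpParams)
    natural_days: tuple[float, ...] = DEFAULT_NATURAL_DAYS
    induced_days: tuple[float, ...] = DEFAULT_INDUCED_DAYS
    n_replicates: int = 2  # independent arrays per collection day
    # log2-scale population expression levels for cluster probes: the favored
    # population sits fold_separation above the disfavored one.
    level_log2_mean: float = 8.0
    level_log2_sd: float = 1.0
    fold_separation: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_probes_cluster1,
            self.n_probes_cluster2,
            self.n_noise_probes,
            self.n_feedback_probes,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("probe counts must be nonnegative")
        if sum(counts) == 0:
            raise ConfigError("at least one probe is required")
        if self.period_days <= 0:
            raise ConfigError("period_days must be positive")


@dataclass
class GroundTruth:
    """Oracle values for parameter-recovery tests.

    ``labels`` partitions all probes into cluster1 / cluster2 / noise /
    feedback; ``fractions`` is the true expanding fraction per sample;
    ``y_expanding`` / ``y_background`` are the true static intracellular
    expressions; ``bump_profile`` is the per-sample multiplicative factor
    applied to the background expression of feedback probes; ``phase_days``
    is the day-since-initiation of each probe's expected expression maximum.
    """

    labels: np.ndarray
    fractions: np.ndarray
    y_expanding: np.ndarray
    y_background: np.ndarray
    bump_profile: np.ndarray
    phase_days: np.ndarray

    def mixture_prediction(self) -> np.ndarray:
        """Expected noiseless expression matrix under the two-population model
        with static intracellular expression (feedback bump included)."""
        f = self.fractions[None, :]
        y1 = self.y_expanding[:, None]
        y2 = self.y_background[:, None] * self.bump_profile
        return f * y1 + (1.0 - f) * y2


def expansion_trajectory(days: np.ndarray, params: ExpansionParams) -> np.ndarray:
    """Expanding-population fraction at ``days`` since cycle initiation.

    Piecewise smooth: logistic rise onset->peak, Gaussian-flank collapse
    peak->collapse (pinned to exactly 0 at the collapse day), 0 elsewhere.
    """
    d = np.asarray(days, dtype=float)
    out = np.zeros_like(d)
    onset, peak, collapse = params.onset_day, params.peak_day, params.collapse_day

    rising = (d > onset) & (d <= peak)
    if np.any(rising):
        k = 8.0 / (peak - onset)
        mid = 0.5 * (onset + peak)
        lo, hi = expit(k * (onset - mid)), expit(k * (peak - mid))
        out[rising] = (expit(k * (d[rising] - mid)) - lo) / (hi - lo)

    falling = (d > peak) & (d < collapse)
    if np.any(falling):
        w = (collapse - peak) / 3.0
        g = np.exp(-0.5 * ((d[falling] - peak) / w) ** 2)
        g_end = np.exp(-0.5 * ((collapse - peak) / w) ** 2)
        out[falling] = (g - g_end) / (1.0 - g_end)

    return params.peak_fraction * np.clip(out, 0.0, 1.0)


def simulate_dataset(cfg: SimulationConfig | None = None) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a merged, linear-scale dataset plus its ground truth.

    Expression is built mechanistically as x_ij = f_i*y1_j + (1-f_i)*y2_j
    (cluster1 probes high in the expanding population, cluster2 probes high in
    the background, noise probes equal in both) and then multiplied by
    exp-log2-Gaussian measurement noise.  The expanding fraction follows the
    cycle phase on the merged axis: an induced sample shares the fraction of
    the natural day it was morphology-matched to, which on the induced
    cycle's own day axis appears as a delayed anagen onset.  Same seed, same
    output, bit for bit.
    """
    cfg = cfg or SimulationConfig()
    if cfg.n_replicates < 1:
        raise ConfigError("need at least one replicate per collection day")
    rng = np.random.default_rng(cfg.seed)

    days = np.concatenate([cfg.natural_days, cfg.induced_days])
    cycles = np.array(
        [NATURAL] * len(cfg.natural_days) + [INDUCED] * len(cfg.induced_days), dtype=object
    )
    days = np.repeat(days, cfg.n_replicates)
    cycles = np.repeat(cycles, cfg.n_replicates)
    replicate = np.tile(
        np.arange(1, cfg.n_replicates + 1), len(days) // cfg.n_replicates
    )
    tmap = TimeMap()
    merged = np.array(
        [d if c == NATURAL else tmap[d] for c, d in zip(cycles, days)], dtype=float
    )
    order = np.lexsort((replicate, np.where(cycles == NATURAL, 0, 1), merged))
    days, cycles, merged, replicate = (
        days[order], cycles[order], merged[order], replicate[order],
    )

    n_samples = len(days)
    phase = merged - INITIATION_DAY  # cycle phase shared by both cycles
    fractions = expansion_trajectory(phase, cfg.expansion_params)

    n1, n2 = cfg.n_probes_cluster1, cfg.n_probes_cluster2
    nn, nf = cfg.n_noise_probes, cfg.n_feedback_probes
    labels = np.array(
        ["cluster1"] * n1 + ["cluster2"] * n2 + ["noise"] * nn + ["feedback"] * nf,
        dtype=object,
    )
    n_probes = len(labels)

    base = 2.0 ** rng.normal(cfg.level_log2_mean, cfg.level_log2_sd, size=n_probes)
    # feedback probes model secreted signaling transcripts, expressed well
    # below structural genes (4x lower base level)
    base[labels == "feedback"] /= 4.0
    half_sep = np.sqrt(cfg.fold_separation)
    y1 = base.copy()  # expanding population
    y2 = base.copy()  # background population
    is_c1 = labels == "cluster1"
    is_c2like = (labels == "cluster2") | (labels == "feedback")
    y1[is_c1] *= half_sep
    y2[is_c1] /= half_sep
    y1[is_c2like] /= half_sep
    y2[is_c2like] *= half_sep

    bump = np.ones((n_probes, n_samples))
    if nf:
        bp = cfg.bump_params
        profile = 1.0 + (bp.amplitude_fold - 1.0) * expit(
            (phase - bp.center_day) / bp.width_days
        )
        bump[labels == "feedback", :] = profile[None, :]

    f_probe = np.broadcast_to(fractions, (n_probes, n_samples)).copy()
    if cfg.phase_jitter_sd > 0.0:
        # staggered peak timing within the expanding cluster only; the
        # shared-fraction mixture remains exact for all other probes
        shifts = rng.normal(0.0, cfg.phase_jitter_sd, size=int(is_c1.sum()))
        f_probe[is_c1] = np.vstack(
            [expansion_trajectory(phase - s, cfg.expansion_params) for s in shifts]
        )

    x = f_probe * y1[:, None] + (1.0 - f_probe) * y2[:, None] * bump
    if cfg.noise_sd_log2 > 0.0:
        x = x * 2.0 ** rng.normal(0.0, cfg.noise_sd_log2, size=x.shape)

    # expected maximum day (since initiation) per probe: expanding-cluster
    # probes peak with the expansion, background-cluster probes when f ~ 0
    peak1 = cfg.cluster1_peak_day - INITIATION_DAY
    peak2 = cfg.cluster2_peak_day - INITIATION_DAY
    phase_days = np.where(is_c1, peak1, peak2).astype(float)
    phase_days[labels == "noise"] = np.nan

    ds = ExpressionDataset(
        values=x,
        scale="linear",
        probe_ids=np.array([f"probe_{i:05d}" for i in range(n_probes)], dtype=object),
        sample_ids=np.array(
            [f"{c[:3]}_{d:g}_r{r}" for c, d, r in zip(cycles, days, replicate)],
            dtype=object,
        ),
        sample_day=days,
        sample_cycle=cycles,
        merged_day=merged,
    )

    truth = GroundTruth(
        labels=labels,
        fractions=fractions,
        y_expanding=y1,
        y_background=y2,
        bump_profile=bump,
        phase_days=phase_days,
    )
    return ds, truth


def days_since_initiation(ds: ExpressionDataset) -> np.ndarray:
    """Per-sample days since cycle initiation on each cycle's own clock
    (after morphogenesis for the natural cycle, after depilation for the
    induced one).  Used for per-cycle reporting of population trajectories."""
    return np.where(
        ds.sample_cycle == NATURAL, ds.sample_day - INITIATION_DAY, ds.sample_day
    )


def cycle_phase(ds: ExpressionDataset) -> np.ndarray:
    """Per-sample cycle phase in days since initiation on the merged axis.

    Both cycles share this axis: an induced sample inherits the phase of the
    natural day it was morphology-matched to.
    """
    if ds.merged_day is None:
        raise ValueError("dataset has no merged time axis; run merge_cycles first")
    return ds.merged_day - INITIATION_DAY


def simulate_null_dataset(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Permutation negative control: shuffle each probe's values across time.

    Shuffling is independent per probe and kept separate within each cycle
    group, so natural-cycle values never migrate to induced samples and each
    probe's marginal distribution is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    out = ds.copy()
    for cycle in (NATURAL, INDUCED):
        cols = np.flatnonzero(ds.sample_cycle == cycle)
        if cols.size == 0:
            continue
        for j in range(ds.n_probes):
            out.values[j, cols] = ds.values[j, rng.permutation(cols)]
    return out
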