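"""End-to-end analysis driver.

Runs the full chain on one configuration: simulate (or load) a dataset,
detect periodic probes, characterize the low-frequency oscillators and split
them into two phase clusters, fit the two-group coupled-oscillator model and
check both coupling configurations, scan the bifurcation diagram, deconvolve
the expression matrix into expanding/background populations, assign probes,
and screen negative-feedback candidates.  Every stage writes a TSV and the
run ends with a machine-readable JSON report.  All randomness derives from
one master seed; stage seeds are stable hashes of the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hairwave import coupled, mixture, oscillator, periodicity
from hairwave.io import ExpressionDataset, TimeMap, merge_cycles, read_expression
from hairwave.simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("hairwave")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_dataset(cfg: dict) -> tuple[ExpressionDataset, object | None]:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", stage_seed(cfg.get("seed", 0), "simulate"))
        ds, truth = simulate_dataset(SimulationConfig(**sim_kwargs))
        return ds, truth
    if "matrix" in cfg and "metadata" in cfg:
        ds = read_expression(cfg["matrix"], cfg["metadata"], cfg.get("scale", "linear"))
        return merge_cycles(ds, TimeMap()), None
    raise ValueError("config needs either a 'simulate' block or 'matrix' + 'metadata' paths")


def run_all(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report.

    ``config`` is a dict or a YAML file path.  Recognized keys: ``seed``,
    ``simulate`` (generator overrides) or ``matrix``/``metadata``/``scale``,
    ``n_perm``, ``fdr``, ``bifurcation`` (bool), ``negative_control`` (bool).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "config": _jsonable(config), "stages": {}}

    def done(stage: str, **info):
        report["stages"][stage] = {"status": "ok", **info}
        log.info("stage %s done: %s", stage, info)

    # ---- data ------------------------------------------------------------
    ds, truth = _load_dataset(config)
    if ds.scale == "linear":
        ds_log = ds.to_log2()
        ds_lin = ds
    else:
        ds_log = ds
        ds_lin = ds.to_linear()
    done("data", n_probes=ds.n_probes, n_samples=ds.n_samples)

    # ---- periodicity -----------------------------------------------------
    times = ds.merged_day
    basis = periodicity.build_frequency_grid(times)
    calls = periodicity.call_periodicity(
        ds_log.values,
        times,
        ds.probe_ids,
        basis=basis,
        n_perm=int(config.get("n_perm", 500)),
        seed=stage_seed(seed, "periodicity"),
        fdr=float(config.get("fdr", 0.10)),
    )
    if out is not None:
        calls.to_csv(out / "periodicity_calls.tsv", sep="\t", index=False)
    n_periodic = int(calls["is_periodic"].sum())
    n_lfo = int(calls["is_lfo"].sum())
    done("periodicity", n_periodic=n_periodic, n_lfo=n_lfo)

    # ---- oscillators -----------------------------------------------------
    lfo_idx = np.flatnonzero(calls["is_lfo"].to_numpy())
    longest = float(basis.periods.max())
    split = oscillator.cluster_by_phase(
        calls["phase_shift_days"].to_numpy()[lfo_idx], longest, t_ref=float(times.min())
    )
    cluster_labels = np.zeros(ds.n_probes, dtype=int)  # 0 = not an LFO
    cluster_labels[lfo_idx] = split.labels

    grid = np.arange(times.min(), times.max() + 1e-9, float(config.get("phase_step", 0.25)))
    fits = [
        periodicity.fit_fourier_robust(ds_log.values[j], times, basis) for j in lfo_idx
    ]
    phases = oscillator.ensemble_phases(fits, basis, grid)
    ops = oscillator.cluster_order_parameters(phases, split.labels)
    r1_traj = np.abs(ops["Z1"])
    r_c1 = float(np.mean(np.abs(ops["z_c1"])))
    r_c2 = float(np.mean(np.abs(ops["z_c2"])))
    rand = oscillator.randomize_phases(phases, stage_seed(seed, "randomize"))
    r1_rand = float(np.mean(np.abs(oscillator.order_parameter(rand, 1))))
    n1, n2 = int((split.labels == 1).sum()), int((split.labels == 2).sum())
    if out is not None:
        pd.DataFrame(
            {
                "day": grid,
                "R1": np.abs(ops["Z1"]),
                "R2": np.abs(ops["Z2"]),
                "r_c1": np.abs(ops["z_c1"]),
                "r_c2": np.abs(ops["z_c2"]),
            }
        ).to_csv(out / "order_parameters.tsv", sep="\t", index=False)
    done(
        "oscillator",
        n_cluster1=n1,
        n_cluster2=n2,
        separation_days=split.separation_days,
        mean_R1=float(r1_traj.mean()),
        r_c1=r_c1,
        r_c2=r_c2,
        randomized_R1=r1_rand,
        ambiguous=split.ambiguous,
    )

    # ---- coupled model ---------------------------------------------------
    q1 = n1 / max(n1 + n2, 1)
    verdict = coupled.check_configuration(r_c1, r_c2, q1)
    omega0 = 2.0 * np.pi / longest
    model_info = {
        "stable_configuration": verdict.stable_configuration,
        "omega0_rad_per_day": omega0,
        "p_positive": 1.0 - q1,
    }
    for name, fit in verdict.fits.items():
        model_info[name] = {
            "K": fit.K,
            "gamma": fit.gamma,
            "coupling_ratio": fit.coupling_ratio,
            "realizable": fit.realizable,
            "note": verdict.details.get(name, ""),
        }
    bif_summary = None
    if config.get("bifurcation", True) and verdict.stable_configuration is not None:
        fit = verdict.fits[verdict.stable_configuration]
        bif = coupled.bifurcation_diagram(
            fit.K,
            fit.gamma,
            np.asarray(config.get("p_grid", np.linspace(0.1, 0.9, 17))),
            omega0=omega0,
            coupling_ratio=fit.coupling_ratio,
            seed=stage_seed(seed, "bifurcation"),
        )
        bif_summary = {
            "states": [str(s) for s in bif.state],
            "boundaries": bif.boundaries,
        }
        if out is not None:
            pd.DataFrame(
                {
                    "p": bif.p_grid,
                    "steady_R1": bif.steady_r1,
                    "state": bif.state,
                    "rotation_rad_per_day": bif.rotation,
                    "period_days": bif.period_days,
                }
            ).to_csv(out / "bifurcation.tsv", sep="\t", index=False)
    done("coupled_model", **model_info, bifurcation=bif_summary)

    # ---- mixture deconvolution -------------------------------------------
    fit = mixture.fit_mixture(ds_lin, fdr=float(config.get("fdr", 0.10)))
    assignments = mixture.assign_populations(
        fit.t_stat, fit.q_value, calls["is_lfo"].to_numpy(), fdr=float(config.get("fdr", 0.10))
    )
    if out is not None:
        pd.DataFrame(
            {
                "sample_id": ds.sample_ids,
                "cycle": ds.sample_cycle,
                "day": ds.sample_day,
                "merged_day": ds.merged_day,
                "fraction_expanding": fit.fractions,
            }
        ).to_csv(out / "fractions.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "probe_id": ds.probe_ids,
                "y_expanding": fit.y_expanding,
                "y_background": fit.y_background,
                "t": fit.t_stat,
                "p": fit.p_value,
                "q": fit.q_value,
                "cod": fit.cod,
                "assignment": assignments,
                "cluster": cluster_labels,
            }
        ).to_csv(out / "populations.tsv", sep="\t", index=False)
    lfo_mask = calls["is_lfo"].to_numpy()
    assigned_frac = float(np.mean(assignments[lfo_mask] != "none")) if lfo_mask.any() else 0.0
    done(
        "mixture",
        converged=fit.converged,
        n_iter=fit.n_iter,
        assigned_lfo_fraction=assigned_frac,
        median_lfo_cod=float(np.nanmedian(fit.cod[lfo_mask])) if lfo_mask.any() else None,
    )

    # ---- feedback screen -------------------------------------------------
    candidates = mixture.feedback_candidates(
        ds_lin,
        fit,
        cluster_labels,
        lfo_mask,
        window=tuple(config.get("feedback_window", (14.0, 16.0))),
        cod_max=float(config.get("cod_max", 0.60)),
        ratio_min=float(config.get("ratio_min", 1.0)),
    )
    if out is not None:
        candidates.to_csv(out / "feedback_candidates.tsv", sep="\t", index=False)
    done("feedback", n_candidates=len(candidates))

    # ---- negative control (optional) -------------------------------------
    if config.get("negative_control", False):
        null_fit = mixture.negative_control(ds_lin, stage_seed(seed, "negative_control"))
        done(
            "negative_control",
            fraction_range=float(np.ptp(null_fit.fractions)),
            median_lfo_cod=float(np.nanmedian(null_fit.cod[lfo_mask])) if lfo_mask.any() else None,
        )

    if truth is not None:
        report["ground_truth_labels"] = {
            lab: int((truth.labels == lab).sum()) for lab in np.unique(truth.labels)
        }
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
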