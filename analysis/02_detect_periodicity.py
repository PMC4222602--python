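"""Detect periodic probes in the simulated dataset.

Robust Fourier-series regression on the merged non-uniform grid, Fisher's
g-statistic, GPD-refined permutation p-values and Benjamini-Hochberg control
at 10% FDR.  Writes per-probe calls (g, p, q, principal period, phase shift)
and prints the detection summary against the ground-truth labels.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hairwave.io import merge_cycles, read_expression
from hairwave.periodicity import call_periodicity

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(n_perm: int = 500, seed: int = 1) -> None:
    ds = read_expression(
        RESULTS / "expression_matrix.tsv", RESULTS / "sample_metadata.tsv", "linear"
    )
    ds = merge_cycles(ds)
    calls = call_periodicity(
        np.log2(ds.values), ds.merged_day, ds.probe_ids, n_perm=n_perm, seed=seed
    )
    calls.to_csv(RESULTS / "periodicity_calls.tsv", sep="\t", index=False)

    truth = pd.read_csv(RESULTS / "ground_truth_probes.tsv", sep="\t")
    merged = calls.merge(truth, on="probe_id")
    print(f"{int(calls['is_periodic'].sum())} probes periodic at 10% FDR, "
          f"{int(calls['is_lfo'].sum())} low-frequency oscillators")
    for lab, grp in merged.groupby("label"):
        print(f"  {lab:9s}: periodic {grp['is_periodic'].mean():.2f}, "
              f"LFO {grp['is_lfo'].mean():.2f}, median period "
              f"{grp.loc[grp['is_periodic'], 'ppc_period'].median():.1f} d")


if __name__ == "__main__":
    main()
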