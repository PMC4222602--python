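"""Screen for negative-feedback candidate genes and test set enrichment.

Candidates are background-cluster LFOs poorly described by static
intracellular expression whose observed/fitted ratio exceeds 1 at every
sample 14-16 days after initiation.  A hypergeometric test then checks
whether the candidates are enriched for the planted feedback probes, and a
small constructed count table demonstrates the literature-distance screen.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hairwave import mixture
from hairwave.enrichment import hypergeom_enrichment, ngd
from hairwave.io import merge_cycles, read_expression

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = merge_cycles(
        read_expression(
            RESULTS / "expression_matrix.tsv", RESULTS / "sample_metadata.tsv", "linear"
        )
    )
    calls = pd.read_csv(RESULTS / "periodicity_calls.tsv", sep="\t")
    clusters_df = pd.read_csv(RESULTS / "phase_clusters.tsv", sep="\t")
    truth = pd.read_csv(RESULTS / "ground_truth_probes.tsv", sep="\t")

    cluster = np.zeros(ds.n_probes, dtype=int)
    pos = {p: i for i, p in enumerate(ds.probe_ids)}
    for p, c in zip(clusters_df["probe_id"], clusters_df["cluster"]):
        cluster[pos[p]] = c

    fit = mixture.fit_mixture(ds)
    table = mixture.feedback_candidates(ds, fit, cluster, calls["is_lfo"].to_numpy())
    table.to_csv(RESULTS / "feedback_candidates.tsv", sep="\t", index=False)

    planted = set(truth.loc[truth["label"] == "feedback", "probe_id"])
    hits = set(table["probe_id"])
    print(f"{len(hits)} candidate signals ({len(hits & planted)}/{len(planted)} "
          f"planted feedback probes recovered, {len(hits - planted)} false positives)")

    res = hypergeom_enrichment(sorted(hits), sorted(planted), list(ds.probe_ids))
    print(f"enrichment of planted feedback probes among candidates: "
          f"p = {res.p_value:.3g} ({res.n_overlap}/{res.n_target} in a "
          f"background of {res.n_background})")

    # literature-distance sanity check on a constructed count table
    print(f"NGD of independent terms: "
          f"{ngd(1000, 2000, 1000 * 2000 / 1e6, 1e6):.3f} (threshold for relatedness: < 1)")


if __name__ == "__main__":
    main()
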