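"""Compute normalized variant enrichments and sweep processing parameters.

Reads the simulated count tables from step 01, runs a small
(c_min, alpha_p) sweep scored by mean pairwise replicate correlation,
then computes normalized enrichments (wild type = 1, dead panel = 0) at
the selected parameters and reports the replicate concordance.
"""

from pathlib import Path

import numpy as np

import rubiscan as rb
from rubiscan.io import read_tsv, write_tsv

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_tsv(BASE / "simulation" / "counts.tsv")
    truth = read_tsv(BASE / "simulation" / "ground_truth.tsv")
    dead = list(truth.loc[truth["is_dead"], "variant_id"])

    best, surface = rb.sweep_processing_params(
        counts, dead, c_min_grid=(0, 10, 25, 50), alpha_grid=tuple(np.logspace(-9, -6, 4))
    )
    write_tsv(surface, BASE / "sweep_surface.tsv")
    print(f"sweep evaluated {len(surface)} (c_min, alpha_p) combinations")
    print(f"optimum: c_min={best.c_min}, alpha_p={best.alpha_p:.3g}")

    table = rb.enrichment_by_replicate(counts, dead, best)
    write_tsv(table, BASE / "enrichments.tsv", {"c_min": best.c_min, "alpha_p": best.alpha_p})

    corrs = []
    for co2, sub in table.groupby("co2_percent"):
        reps = {r: s.set_index("variant_id")["e_norm"] for r, s in sub.groupby("replicate")}
        corrs.append((co2, rb.pairwise_replicate_correlation(reps)))
    for co2, r in corrs:
        print(f"  {co2:>5}% CO2: mean pairwise Pearson r = {r:.4f}")
    print(f"mean across conditions: {np.mean([r for _, r in corrs]):.4f}")
    print(f"enrichments written to {BASE / 'enrichments.tsv'}")


if __name__ == "__main__":
    main()
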