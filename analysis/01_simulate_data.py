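"""Generate the synthetic study datasets used by the downstream analyses.

Produces, under results/data/:
  * an exometabolome feature table (blanks + seawater controls + CCA-style
    treatments) with planted background/transient features, enriched and
    treatment-only subnetworks, plus the ground-truth labels;
  * a single-control settlement assay (treatment 0.8 vs control 0.2) and a
    fractionation-style dual-control assay.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from exocue.core_model import (
    write_annotations,
    write_feature_table,
    write_sample_metadata,
)
from exocue.synthetic_data import SimulationSpec, simulate_feature_table, simulate_settlement

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(rng_seed=SEED, n_subnetworks=120, treatment_only_fraction=0.025)
    matrix, features, samples, annotations, truth = simulate_feature_table(spec)
    write_feature_table(matrix, features, OUT / "features.csv")
    write_sample_metadata(samples, OUT / "metadata.csv")
    write_annotations(annotations, OUT / "annotations.csv")
    f_truth, s_truth = truth.to_frames()
    f_truth.to_csv(OUT / "truth_features.csv", index=False)
    s_truth.to_csv(OUT / "truth_subnetworks.csv", index=False)

    table, _ = simulate_settlement(spec)
    table.to_csv(OUT / "settlement_single_control.csv", index=False)

    # fractionation layout: 2 resins x 2 concentrations + dual controls,
    # with C18 at 10x genuinely elevated
    rng = np.random.default_rng(SEED)
    rows = []
    layout = [
        ("C18", "1x", "none", 0.2), ("C18", "10x", "none", 0.8),
        ("PPL", "1x", "none", 0.2), ("PPL", "10x", "none", 0.2),
        ("C18", "control", "resin_control", 0.2),
        ("PPL", "control", "resin_control", 0.2),
        ("seawater", "control", "seawater_control", 0.2),
    ]
    well = 0
    for fa, fb, role, p in layout:
        for _ in range(5):
            well += 1
            rows.append(
                {
                    "well_id": f"W{well:03d}",
                    "coral_species": "synthetic_coral",
                    "factor_a": fa,
                    "factor_b": fb,
                    "control_role": role,
                    "larvae_added": 10,
                    "larvae_settled": int(rng.binomial(10, p)),
                    "day": 3,
                }
            )
    pd.DataFrame(rows).to_csv(OUT / "settlement_dual_control.csv", index=False)

    n_planted = int(truth.subnetwork_labels.isin(
        ["enriched_treatment", "treatment_only"]).sum())
    print(f"wrote {len(matrix)} features / {spec.n_subnetworks} subnetworks "
          f"({n_planted} planted enriched) and two settlement assays -> {OUT}")


if __name__ == "__main__":
    main()
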