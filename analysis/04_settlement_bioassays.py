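"""Settlement bioassay statistics for the two simulated experiments.

Experiment 1 (single control): angular transform, factorial ANOVA and a
Dunnett comparison of each treatment against the seawater control.
Experiment 2 (fractionation): each resin x concentration treatment is
tested against both the seawater control and its own resin control; it
counts as settlement-inducing only if both FDR-corrected comparisons are
significant.  Writes comparison tables to results/settlement/.
"""

from pathlib import Path

from exocue.core_model import PipelineConfig
from exocue.settlement_stats import (
    dual_control_assessment,
    read_settlement_table,
    single_control_assessment,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 17


def main() -> None:
    out = ROOT / "settlement"
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(rng_seed=SEED)

    exp1 = read_settlement_table(ROOT / "data" / "settlement_single_control.csv")
    res1 = single_control_assessment(exp1, cfg)
    res1.comparisons.to_csv(out / "experiment1_dunnett.csv", index=False)
    res1.anova.to_csv(out / "experiment1_anova.csv")
    for row in res1.comparisons.itertuples():
        verdict = "induced settlement" if row.significant else "no effect"
        print(
            f"exp1 {row.factor_a}: estimate {row.estimate:+.3f} rad, "
            f"Dunnett FDR p = {row.p_fdr:.4g} -> {verdict}"
        )

    exp2 = read_settlement_table(ROOT / "data" / "settlement_dual_control.csv")
    res2 = dual_control_assessment(exp2, cfg)
    res2.comparisons.to_csv(out / "experiment2_dual_dunnett.csv", index=False)
    res2.anova.to_csv(out / "experiment2_anova.csv")
    for row in res2.comparisons.itertuples():
        verdict = "both controls beaten" if row.significant else "not significant"
        print(
            f"exp2 {row.factor_a} {row.factor_b}: seawater FDR p = "
            f"{row.p_seawater_fdr:.4g}, resin FDR p = {row.p_resin_fdr:.4g} "
            f"-> {verdict}"
        )


if __name__ == "__main__":
    main()
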