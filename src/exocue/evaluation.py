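"""Simulation studies that quantify the pipeline's operating characteristics.

Each function runs a self-contained study on synthetic data -- oracle
agreement of the filter cascade, planted-label recovery, enrichment
recovery and false-discovery control, Dunnett accuracy, settlement null
calibration -- and returns plain numbers.  The studies use a reduced
random-forest profile (300 trees, 1,000 permutation repetitions) so a full
battery runs in minutes on one CPU; the 29,188-tree / 10,000-permutation
configuration of the main analysis remains available through
:class:`~exocue.core_model.PipelineConfig`.

The reference ("oracle") recomputations in this module are written as
naive loops straight from the rule definitions, independent of the
vectorized implementations they are compared against.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_model import PipelineConfig, ROLE_BLANK
from .feature_filtering import (
    flag_background_features,
    flag_background_subnetworks,
    flag_rare_subnetworks,
    flag_transient_features,
)
from .settlement_stats import dual_control_assessment, dunnett_many_to_one
from .subnetwork_enrichment import (
    aggregate_subnetworks,
    enrichment_ttests,
    profile_log10,
    rf_screen,
)
from .synthetic_data import SimulationSpec, simulate_feature_table

# reduced-forest profile used by every simulation study
STUDY_TREES = 300
STUDY_IMPORTANCE_REPS = 1000


def _seed_stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


# ---------------------------------------------------------------------------
# naive reference recomputations (loop-level, definition-first)


def _naive_background(matrix, samples, cfg):
    blanks = [c for c in matrix.columns if samples.at[c, "role"] == ROLE_BLANK]
    others = [c for c in matrix.columns if c not in blanks]
    flagged = set()
    for fid in matrix.index:
        logs = []
        for c in others:
            v = matrix.at[fid, c]
            logs.append(math.log10(v) if v > 0 else cfg.nondetect_log_value)
        blank_max = max(
            (math.log10(matrix.at[fid, c]) if matrix.at[fid, c] > 0
             else cfg.nondetect_log_value)
            for c in blanks
        )
        if sum(logs) / len(logs) <= cfg.blank_multiplier * blank_max:
            flagged.add(str(fid))
    return flagged


def _naive_background_subnetworks(flags, features, cfg):
    out = set()
    for sub, members in features.groupby("subnetwork_id").groups.items():
        hit = sum(1 for fid in members if str(fid) in flags)
        if hit / len(members) > cfg.background_subnetwork_fraction:
            out.add(str(sub))
    return out


def _naive_transient(matrix, cfg):
    flagged = set()
    for fid in matrix.index:
        row = [matrix.at[fid, c] for c in matrix.columns]
        present = sum(1 for v in row if v > 0)
        if present <= cfg.transient_max_samples and max(row) < cfg.transient_intensity_threshold:
            flagged.add(str(fid))
    return flagged


def _naive_rare(matrix, features, cfg):
    nonzero = [v for fid in matrix.index for v in matrix.loc[fid] if v > 0]
    reference = sum(nonzero) / len(nonzero)
    sub_max: dict[str, float] = {}
    for fid in matrix.index:
        sub = str(features.at[fid, "subnetwork_id"])
        sub_max[sub] = max(sub_max.get(sub, 0.0), max(matrix.loc[fid]))
    return {s for s, peak in sub_max.items() if peak < reference}


# ---------------------------------------------------------------------------
# studies


def filter_oracle_agreement(seed: int, n_matrices: int = 100) -> dict:
    """Exact agreement of all three flag sets with naive recomputations.

    Random matrices of up to 50 features x 12 samples with zeros, blank
    contamination and random subnetwork structure.
    """
    rng = _seed_stream(seed, 1)
    cfg = PipelineConfig()
    agree = 0
    for _ in range(n_matrices):
        n_feat = int(rng.integers(5, 51))
        n_blank = int(rng.integers(1, 4))
        n_other = int(rng.integers(4, 13 - n_blank))
        ids = [f"F{i}" for i in range(n_feat)]
        cols = [f"B{i}" for i in range(n_blank)] + [f"S{i}" for i in range(n_other)]
        roles = ["blank"] * n_blank + (
            ["control"] * (n_other // 2)
            + ["treatment"] * (n_other - n_other // 2)
        )
        samples = pd.DataFrame(
            {"role": roles, "group_label": "", "replicate": 1},
            index=pd.Index(cols, name="sample_id"),
        )
        values = 10 ** rng.normal(4.0, 1.5, size=(n_feat, len(cols)))
        values[rng.random(values.shape) < 0.4] = 0.0
        values[:, :n_blank] *= rng.random((n_feat, n_blank)) < 0.2
        matrix = pd.DataFrame(values, index=ids, columns=cols)
        features = pd.DataFrame(
            {
                "mz": 300.0,
                "rt": 100.0,
                "subnetwork_id": [f"SN{rng.integers(8)}" for _ in ids],
            },
            index=pd.Index(ids, name="feature_id"),
        )
        bg = flag_background_features(matrix, samples, cfg)
        ok = bg == _naive_background(matrix, samples, cfg)
        ok &= flag_background_subnetworks(bg, features, cfg) == (
            _naive_background_subnetworks(bg, features, cfg)
        )
        nonblank = matrix[[c for c in cols if not c.startswith("B")]]
        ok &= flag_transient_features(nonblank, cfg) == _naive_transient(nonblank, cfg)
        ok &= flag_rare_subnetworks(nonblank, features, cfg) == _naive_rare(
            nonblank, features, cfg
        )
        agree += bool(ok)
    return {"agreement_fraction": agree / n_matrices, "n": n_matrices}


def planted_label_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Sensitivity/specificity of background and transient flagging.

    Datasets planted with background fraction 0.2 and transient fraction
    0.1 at otherwise-default generator settings; flags from default
    pipeline configuration are scored against the planted labels.
    """
    cfg = PipelineConfig()
    counts = {k: 0 for k in ("bg_tp", "bg_fn", "bg_fp", "bg_tn",
                             "tr_tp", "tr_fn", "tr_fp", "tr_tn")}
    base = int(seed) % 2**31
    for i in range(n_seeds):
        spec = SimulationSpec(
            rng_seed=base + i,
            n_subnetworks=100,
            background_fraction=0.2,
            transient_fraction=0.1,
        )
        matrix, features, samples, _, truth = simulate_feature_table(spec)
        labels = truth.feature_labels
        bg = flag_background_features(matrix, samples, cfg)
        nonblank = matrix[
            [c for c in matrix.columns if samples.at[c, "role"] != ROLE_BLANK]
        ]
        tr = flag_transient_features(nonblank, cfg)
        for fid, label in labels.items():
            in_bg, in_tr = fid in bg, fid in tr
            if label == "background":
                counts["bg_tp" if in_bg else "bg_fn"] += 1
            else:
                counts["bg_fp" if in_bg else "bg_tn"] += 1
            if label == "transient":
                counts["tr_tp" if in_tr else "tr_fn"] += 1
            else:
                counts["tr_fp" if in_tr else "tr_tn"] += 1
    return {
        "background_sensitivity": counts["bg_tp"] / (counts["bg_tp"] + counts["bg_fn"]),
        "background_specificity": counts["bg_tn"] / (counts["bg_tn"] + counts["bg_fp"]),
        "transient_sensitivity": counts["tr_tp"] / (counts["tr_tp"] + counts["tr_fn"]),
        "transient_specificity": counts["tr_tn"] / (counts["tr_tn"] + counts["tr_fp"]),
        "n": n_seeds,
    }


def _enrichment_run(seed: int, enriched_fraction: float, effect: float,
                    n_subnetworks: int, n_per_group: int):
    spec = SimulationSpec(
        rng_seed=seed,
        n_subnetworks=n_subnetworks,
        n_blanks=0,
        n_controls=n_per_group,
        n_treatments=n_per_group,
        background_fraction=0.0,
        transient_fraction=0.0,
        enriched_fraction=enriched_fraction,
        effect_log10=effect if enriched_fraction > 0 else 0.0,
    )
    matrix, features, samples, _, truth = simulate_feature_table(spec)
    cfg = PipelineConfig(
        n_trees=STUDY_TREES, n_importance_reps=STUDY_IMPORTANCE_REPS, rng_seed=seed
    )
    profiles = profile_log10(aggregate_subnetworks(matrix, features), cfg)
    mda, selected = rf_screen(profiles, samples, cfg)
    results = enrichment_ttests(profiles, samples, mda, selected, cfg)
    called = set(results.index[results["direction"] == "treatment"])
    planted = set(
        truth.subnetwork_labels.index[
            truth.subnetwork_labels == "enriched_treatment"
        ]
    )
    return called, planted, n_subnetworks


def enrichment_recovery(seed: int, n_seeds: int = 50, n_subnetworks: int = 200,
                        enriched_fraction: float = 0.1, effect: float = 0.602,
                        n_per_group: int = 5) -> dict:
    """Recovery and empirical FDR for planted 4-fold subnetwork enrichment."""
    base = int(seed) % 2**31
    recoveries, fdrs = [], []
    for i in range(n_seeds):
        called, planted, _ = _enrichment_run(
            base + i, enriched_fraction, effect, n_subnetworks, n_per_group
        )
        recoveries.append(len(called & planted) / len(planted))
        fdrs.append(len(called - planted) / len(called) if called else 0.0)
    return {
        "recovery": float(np.mean(recoveries)),
        "empirical_fdr": float(np.mean(fdrs)),
        "n": n_seeds,
    }


def null_calibration(seed: int, n_datasets: int = 200,
                     n_subnetworks: int = 200, n_per_group: int = 5) -> dict:
    """Fraction of subnetworks called enriched when no effect exists."""
    base = int(seed) % 2**31
    total_called = 0
    for i in range(n_datasets):
        called, _, n_sub = _enrichment_run(base + i, 0.0, 0.0, n_subnetworks,
                                           n_per_group)
        total_called += len(called)
    return {
        "null_call_fraction": total_called / (n_datasets * n_subnetworks),
        "n": n_datasets,
    }


def dunnett_accuracy(seed: int, oracle_draws: int = 1_000_000) -> dict:
    """Degenerate-family exactness and k=3 Monte-Carlo agreement.

    The k=3 oracle simulates raw Gaussian datasets under the null and
    recomputes the max-t exceedance frequency from the definition,
    independently of the multivariate-t sampling the implementation uses.
    """
    from scipy import stats

    rng = _seed_stream(seed, 5)
    cfg = PipelineConfig(rng_seed=int(seed) % 2**31)

    # degenerate family: p must equal the one-sided pooled t-test p
    treatment = rng.normal(0.8, 0.2, 6)
    control = rng.normal(0.5, 0.2, 6)
    p_impl = dunnett_many_to_one([treatment], control, cfg)[0]
    t, p_two = stats.ttest_ind(treatment, control, equal_var=True)
    p_ref = p_two / 2 if t > 0 else 1 - p_two / 2
    degenerate_err = abs(p_impl - p_ref)

    # k = 3 family against the simulation oracle
    control = rng.normal(0.4, 0.15, 5)
    groups = [
        control + 0.18 + rng.normal(0, 0.02, 5),
        rng.normal(0.45, 0.15, 5),
        rng.normal(0.35, 0.15, 5),
    ]
    p_impl3 = dunnett_many_to_one(groups, control, cfg)
    all_groups = groups + [control]
    ss = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    df = sum(len(g) - 1 for g in all_groups)
    s = math.sqrt(ss / df)
    t_obs = [
        (g.mean() - control.mean()) / (s * math.sqrt(1 / len(g) + 1 / len(control)))
        for g in groups
    ]
    oracle_rng = _seed_stream(seed, 6)
    n0 = len(control)
    sizes = [len(g) for g in groups]
    sim_control = oracle_rng.standard_normal((oracle_draws, n0))
    sims = [oracle_rng.standard_normal((oracle_draws, m)) for m in sizes]
    ss_sim = ((sim_control - sim_control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    for g in sims:
        ss_sim += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s_sim = np.sqrt(ss_sim / df)
    t_sim = np.column_stack(
        [
            (g.mean(axis=1) - sim_control.mean(axis=1))
            / (s_sim * math.sqrt(1 / m + 1 / n0))
            for g, m in zip(sims, sizes)
        ]
    )
    max_t = t_sim.max(axis=1)
    p_oracle = [float((max_t >= t).mean()) for t in t_obs]
    k3_err = float(np.max(np.abs(np.asarray(p_impl3) - np.asarray(p_oracle))))
    return {
        "degenerate_abs_error": float(degenerate_err),
        "k3_max_abs_error": k3_err,
        "n": oracle_draws,
    }


def _null_settlement_table(rng: np.random.Generator, p_settle: float = 0.3,
                           n_wells: int = 5, larvae: int = 10) -> pd.DataFrame:
    rows = []
    well = 0
    layout = [
        ("C18", "1x", "none"), ("C18", "10x", "none"),
        ("PPL", "1x", "none"), ("PPL", "10x", "none"),
        ("C18", "control", "resin_control"), ("PPL", "control", "resin_control"),
        ("seawater", "control", "seawater_control"),
    ]
    for fa, fb, role in layout:
        for _ in range(n_wells):
            well += 1
            rows.append(
                {
                    "well_id": f"W{well:03d}",
                    "coral_species": "synthetic_coral",
                    "factor_a": fa,
                    "factor_b": fb,
                    "control_role": role,
                    "larvae_added": larvae,
                    "larvae_settled": int(rng.binomial(larvae, p_settle)),
                    "day": 3,
                }
            )
    return pd.DataFrame(rows)


def dual_control_null_rate(seed: int, n_datasets: int = 500) -> dict:
    """Any-flag rate of the dual-control conjunction under a global null.

    All groups settle at probability 0.3 (5 wells of 10 larvae); a flagged
    treatment is a false positive by construction.
    """
    rng = _seed_stream(seed, 7)
    cfg = PipelineConfig(rng_seed=int(seed) % 2**31, dunnett_draws=20_000)
    flagged = 0
    for _ in range(n_datasets):
        table = _null_settlement_table(rng)
        result = dual_control_assessment(table, cfg)
        flagged += bool(result.comparisons["significant"].any())
    return {"any_flag_rate": flagged / n_datasets, "n": n_datasets}


def dual_control_power(seed: int, n_seeds: int = 100) -> dict:
    """Detection rate for one treatment elevated to 0.8 over 0.2 controls."""
    rng = _seed_stream(seed, 8)
    cfg = PipelineConfig(rng_seed=int(seed) % 2**31, dunnett_draws=20_000)
    hits = 0
    for _ in range(n_seeds):
        table = _null_settlement_table(rng, p_settle=0.2)
        elevated = (table["factor_a"] == "C18") & (table["factor_b"] == "10x")
        table.loc[elevated, "larvae_settled"] = rng.binomial(
            10, 0.8, int(elevated.sum())
        )
        result = dual_control_assessment(table, cfg)
        comp = result.comparisons.set_index(["factor_a", "factor_b"])
        hits += bool(comp.at[("C18", "10x"), "significant"])
    return {"detection_rate": hits / n_seeds, "n": n_seeds}
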