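"""Subnetwork-level differential-abundance inference.

Features are aggregated to molecular subnetworks by summing XIC intensity
per sample; all statistics run on log10 summed intensity.  Inference is
two-stage, mirroring a screen-then-test design:

1. a random-forest classifier (seawater control vs treatment) ranks
   subnetworks by permutation mean-decrease-accuracy (MDA); subnetworks at
   or above ``mean(MDA) + 1 SD`` are carried forward;
2. the selected subnetworks are compared between groups with two-tailed
   two-sample t-tests (pooled variance by default) and Benjamini-Hochberg
   FDR correction within the selected family.

MDA is the classical out-of-bag formulation: for each tree, accuracy on
its out-of-bag samples is compared before and after permuting one
predictor; the drop is averaged over trees and over
``n_importance_reps / n_predictors`` independent permutations per
predictor.  With the seed fixed the whole screen is bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .core_model import (
    PipelineConfig,
    ROLE_CONTROL,
    ROLE_TREATMENT,
    ValidationError,
)
from .feature_filtering import log10_intensity

__all__ = [
    "aggregate_subnetworks",
    "rf_screen",
    "select_by_mda",
    "enrichment_ttests",
    "detect_treatment_only",
    "ontology_composition",
]

RESULT_COLUMNS = [
    "mda",
    "selected",
    "t_stat",
    "p_raw",
    "q_fdr",
    "direction",
    "treatment_only",
]


def aggregate_subnetworks(
    matrix: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Sum feature XIC intensities per subnetwork and sample.

    Returns a subnetworks x samples DataFrame of raw summed intensities.
    Use :func:`profile_log10` for the log-scale view used by the tests.
    """
    if not set(matrix.index) <= set(features.index):
        raise ValidationError("matrix features missing from feature table")
    groups = features.loc[matrix.index, "subnetwork_id"].astype(str)
    profiles = matrix.groupby(groups).sum()
    profiles.index.name = "subnetwork_id"
    return profiles


def profile_log10(profiles: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """log10 of summed intensities with the shared non-detection convention."""
    return pd.DataFrame(
        log10_intensity(profiles.to_numpy(), cfg.nondetect_log_value),
        index=profiles.index,
        columns=profiles.columns,
    )


def _class_vector(profiles: pd.DataFrame, samples: pd.DataFrame) -> np.ndarray:
    roles = samples.loc[profiles.columns, "role"]
    bad = set(roles) - {ROLE_CONTROL, ROLE_TREATMENT}
    if bad:
        raise ValidationError(
            f"profiles contain samples with roles {sorted(bad)}; drop blanks first"
        )
    return (roles == ROLE_TREATMENT).to_numpy().astype(int)


def _oob_masks(forest: RandomForestClassifier, n_samples: int) -> np.ndarray:
    """Out-of-bag indicator per (tree, sample), recomputed from tree seeds.

    scikit-learn draws each tree's bootstrap as
    ``RandomState(tree.random_state).randint(0, n, n)``; the complement is
    the tree's out-of-bag set.
    """
    masks = np.ones((forest.n_estimators, n_samples), dtype=bool)
    for i, est in enumerate(forest.estimators_):
        idx = np.random.RandomState(est.random_state).randint(
            0, n_samples, n_samples
        )
        masks[i, idx] = False
    return masks


def rf_screen(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[pd.Series, set[str]]:
    """Random-forest screen for subnetworks that separate the two groups.

    ``profiles`` is the log10 subnetwork x sample table (blank-free).
    Returns the per-subnetwork MDA importance and the selected set
    ``{s : MDA_s >= mean(MDA) + mda_sd_multiplier * sd(MDA)}`` (sample SD).
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 subnetworks for the screen")
    y = _class_vector(profiles, samples)
    if len(np.unique(y)) < 2:
        raise ValidationError("both control and treatment samples are required")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValidationError("need >= 2 samples per class")

    X = profiles.to_numpy(dtype=float).T  # samples x subnetworks
    n, p = X.shape
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        random_state=cfg.rng_seed,
        n_jobs=1,
    ).fit(X, y)

    n_repeats = max(1, cfg.n_importance_reps // p)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0x0BB]))
    masks = _oob_masks(forest, n)

    # evaluate all permuted variants in one stacked prediction pass per tree;
    # chunk over predictors to bound memory
    mda = np.zeros(p)
    chunk = max(1, int(2_000_000 / max(1, n_repeats * n)))
    tree_weight = masks.any(axis=1)  # trees with a nonempty OOB set
    n_valid_trees = int(tree_weight.sum())
    if n_valid_trees == 0:
        raise ValidationError("no tree has out-of-bag samples; increase n samples")
    for start in range(0, p, chunk):
        cols = range(start, min(start + chunk, p))
        variants = [X]
        for j in cols:
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(n), j]
                variants.append(Xp)
        Xbig = np.vstack(variants)
        q = len(variants)
        drops = np.zeros(len(list(cols)))
        for t_i, est in enumerate(forest.estimators_):
            m = masks[t_i]
            if not m.any():
                continue
            pred = est.predict(Xbig).reshape(q, n)[:, m]
            acc = (pred == y[m]).mean(axis=1)
            drops += acc[0] - acc[1:].reshape(-1, n_repeats).mean(axis=1)
        mda[start : start + len(drops)] = drops / n_valid_trees

    mda_series = pd.Series(mda, index=profiles.index, name="mda")
    selected = select_by_mda(mda_series, cfg)
    return mda_series, selected


def select_by_mda(mda: pd.Series, cfg: PipelineConfig) -> set[str]:
    """Apply the mean + k*SD importance threshold (inclusive)."""
    if len(mda) < 2:
        raise ValidationError("need at least 2 MDA values")
    threshold = mda.mean() + cfg.mda_sd_multiplier * mda.std(ddof=1)
    return set(mda.index[mda >= threshold].astype(str))


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    """Two-tailed two-sample t-test with explicit zero-variance handling."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero variance in both groups with unequal means; p set to 0",
            stacklevel=3,
        )
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def enrichment_ttests(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    mda: pd.Series,
    selected: set[str],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """t-tests with BH FDR over the screened subnetworks.

    ``profiles`` is the log10 table.  Only selected subnetworks are
    tested; the BH family is the selected set.  Returns one row per
    subnetwork (selected or not) with columns
    ``mda, selected, t_stat, p_raw, q_fdr, direction, treatment_only``;
    unselected rows carry NaN statistics and direction ``"none"``.
    Direction is ``treatment``/``control`` when ``q_fdr < alpha`` and the
    corresponding group mean is higher.
    """
    unknown = set(selected) - set(profiles.index.astype(str))
    if unknown:
        raise ValidationError(f"selected subnetworks not in profiles: {sorted(unknown)}")
    y = _class_vector(profiles, samples)
    values = profiles.to_numpy(dtype=float)
    treat, ctrl = values[:, y == 1], values[:, y == 0]

    results = pd.DataFrame(index=profiles.index.astype(str), columns=RESULT_COLUMNS)
    results.index.name = "subnetwork_id"
    results["mda"] = mda.reindex(results.index).to_numpy(dtype=float)
    results["selected"] = results.index.isin(selected)
    results["t_stat"] = np.nan
    results["p_raw"] = np.nan
    results["q_fdr"] = np.nan
    results["direction"] = "none"
    results["treatment_only"] = False

    sel = sorted(selected)
    if not sel:
        return results
    loc = {s: i for i, s in enumerate(profiles.index.astype(str))}
    t_stats, p_raws = [], []
    for s in sel:
        i = loc[s]
        t, p = _two_sample_t(treat[i], ctrl[i], cfg.welch)
        t_stats.append(t)
        p_raws.append(p)
    _, q_fdr, _, _ = multipletests(p_raws, alpha=cfg.alpha, method="fdr_bh")
    for s, t, p, q in zip(sel, t_stats, p_raws, q_fdr):
        i = loc[s]
        results.at[s, "t_stat"] = t
        results.at[s, "p_raw"] = p
        results.at[s, "q_fdr"] = q
        if q < cfg.alpha:
            if treat[i].mean() > ctrl[i].mean():
                results.at[s, "direction"] = ROLE_TREATMENT
            elif ctrl[i].mean() > treat[i].mean():
                results.at[s, "direction"] = ROLE_CONTROL
    return results


def detect_treatment_only(
    matrix: pd.DataFrame,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    results: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Flag treatment-enriched subnetworks absent from all control samples.

    A subnetwork is treatment-only when at least
    ``treatment_only_fraction`` (default 1.0, i.e. all) of its member
    features have zero XIC in every control sample.  Only subnetworks with
    ``direction == "treatment"`` are eligible.
    """
    results = results.copy()
    ctrl_cols = [c for c in matrix.columns if samples.at[c, "role"] == ROLE_CONTROL]
    if not ctrl_cols:
        raise ValidationError("no control samples in matrix")
    absent = (matrix[ctrl_cols].to_numpy() == 0).all(axis=1)
    absent = pd.Series(absent, index=matrix.index)
    frac_absent = absent.groupby(features.loc[matrix.index, "subnetwork_id"]).mean()
    for s in results.index[results["direction"] == ROLE_TREATMENT]:
        if s in frac_absent.index and frac_absent[s] >= cfg.treatment_only_fraction:
            results.at[s, "treatment_only"] = True
    return results


def ontology_composition(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    results: pd.DataFrame,
    annotations: pd.DataFrame | None,
) -> pd.DataFrame:
    """Superclass composition of the treatment-enriched intensity pool.

    For each treatment sample, the summed raw intensity of the enriched
    subnetworks (``direction == "treatment"``) is partitioned by consensus
    superclass (missing annotations pooled as ``"unclassified"``) and
    expressed as percentages; the summary reports mean and sample SD of
    those percentages across treatment samples, sorted descending by mean.
    """
    enriched = results.index[results["direction"] == ROLE_TREATMENT].astype(str)
    if len(enriched) == 0:
        warnings.warn("no treatment-enriched subnetworks; empty ontology summary",
                      stacklevel=2)
        return pd.DataFrame(columns=["superclass", "mean_pct", "sd_pct"])
    treat_cols = [c for c in profiles.columns if samples.at[c, "role"] == ROLE_TREATMENT]
    if not treat_cols:
        raise ValidationError("no treatment samples")
    sub = profiles.loc[profiles.index.astype(str).isin(set(enriched)), treat_cols]

    if annotations is not None:
        superclass = (
            annotations["superclass"].reindex(sub.index.astype(str)).fillna("unclassified")
        )
    else:
        superclass = pd.Series("unclassified", index=sub.index.astype(str))
    by_class = sub.groupby(superclass.to_numpy()).sum()
    totals = by_class.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("a treatment sample has zero enriched intensity")
    pct = by_class / totals * 100.0  # per-sample percentages, columns sum to 100
    summary = pd.DataFrame(
        {
            "superclass": pct.index,
            "mean_pct": pct.mean(axis=1).to_numpy(),
            "sd_pct": pct.std(axis=1, ddof=1).to_numpy(),
        }
    )
    return (
        summary.sort_values(["mean_pct", "superclass"], ascending=[False, True])
        .reset_index(drop=True)
    )
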