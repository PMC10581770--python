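"""Three-stage noise-filtering cascade for untargeted LC-MS/MS feature tables.

Stage 1 (**background**): a feature is procedural contamination when its
mean log10 XIC intensity across non-blank samples does not exceed
``blank_multiplier`` (default 2) times the maximum log10 intensity seen in
the extraction blanks; a subnetwork with more than half its members
flagged is removed wholesale.  Blank samples leave the analysis set here.

Stage 2 (**transient**): features detected in at most
``transient_max_samples`` (default 2) samples, with every detection below
``transient_intensity_threshold`` (default 5e4) XIC counts, are noise.

Stage 3 (**rare**): subnetworks whose maximum feature intensity falls
below the average ion intensity of the remaining matrix are removed.

Non-detections (zeros) enter log-scale means as ``nondetect_log_value``
(default 0, i.e. log10 of one count); excluding them would make sparsely
detected contaminants unfilterable.  All threshold comparisons keep their
stated tie semantics: "not greater than" is ``<=``, "below" is ``<``,
"greater than 50%" is strict ``>``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core_model import (
    PipelineConfig,
    ROLE_BLANK,
    ValidationError,
    require_roles,
)

__all__ = [
    "FilterReport",
    "log10_intensity",
    "flag_background_features",
    "flag_background_subnetworks",
    "remove_background",
    "flag_transient_features",
    "flag_rare_subnetworks",
    "run_filter_cascade",
]


@dataclass
class FilterReport:
    """Feature/subnetwork bookkeeping across the filter cascade."""

    n_input_features: int = 0
    n_background_features: int = 0
    n_background_subnetworks: int = 0
    n_after_background: int = 0
    n_transient_features: int = 0
    n_after_transient: int = 0
    n_rare_subnetworks: int = 0
    n_after_rare: int = 0
    n_subnetworks_retained: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def log10_intensity(x, nondetect_log_value: float = 0.0):
    """log10 of an XIC intensity, with zeros mapped to ``nondetect_log_value``.

    Accepts scalars or arrays; negative intensities are invalid.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative XIC intensity")
    with np.errstate(divide="ignore"):
        out = np.where(arr > 0, np.log10(np.where(arr > 0, arr, 1.0)), nondetect_log_value)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def _split_blank(matrix: pd.DataFrame, samples: pd.DataFrame):
    blank_cols = [c for c in matrix.columns if samples.at[c, "role"] == ROLE_BLANK]
    sample_cols = [c for c in matrix.columns if c not in blank_cols]
    return blank_cols, sample_cols


def flag_background_features(
    matrix: pd.DataFrame, samples: pd.DataFrame, cfg: PipelineConfig
) -> set[str]:
    """Features whose sample signal is explained by the extraction blanks.

    Feature ``f`` is flagged iff its mean log10 intensity over non-blank
    samples (non-detections included as ``nondetect_log_value``) is at most
    ``blank_multiplier`` times the maximum blank log10 intensity.  Features
    never detected in any blank (blank max log = 0) are flagged only in the
    degenerate case of a non-positive mean log signal.

    With ``blank_max_on_log_scale=False`` the right-hand side uses the raw
    blank maximum instead (scale-inconsistent, provided for sensitivity
    analysis only).
    """
    blank_cols, sample_cols = _split_blank(matrix, samples)
    if not blank_cols:
        raise ValidationError(
            "no blank samples: cannot define background features; skip this "
            "stage explicitly if the design has no blanks"
        )
    if not sample_cols:
        raise ValidationError("no non-blank samples")
    log_samples = log10_intensity(
        matrix[sample_cols].to_numpy(), cfg.nondetect_log_value
    )
    mean_log = log_samples.mean(axis=1)
    if cfg.blank_max_on_log_scale:
        blank_ref = log10_intensity(
            matrix[blank_cols].to_numpy(), cfg.nondetect_log_value
        ).max(axis=1)
    else:
        blank_ref = matrix[blank_cols].to_numpy().max(axis=1)
    flagged = mean_log <= cfg.blank_multiplier * blank_ref
    return set(matrix.index[flagged].astype(str))


def flag_background_subnetworks(
    flags: set[str], features: pd.DataFrame, cfg: PipelineConfig
) -> set[str]:
    """Subnetworks with strictly more than the allowed fraction of flagged members."""
    unknown = flags - set(features.index.astype(str))
    if unknown:
        raise ValidationError(f"flags reference unknown features: {sorted(unknown)}")
    is_flagged = features.index.astype(str).isin(flags)
    frac = pd.Series(is_flagged, index=features.index).groupby(
        features["subnetwork_id"]
    ).mean()
    return set(frac.index[frac > cfg.background_subnetwork_fraction].astype(str))


def remove_background(
    matrix: pd.DataFrame,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Drop individually flagged features plus all members of flagged subnetworks."""
    flags = flag_background_features(matrix, samples, cfg)
    sub_flags = flag_background_subnetworks(flags, features, cfg)
    in_flagged_subnetwork = features["subnetwork_id"].astype(str).isin(sub_flags)
    drop = features.index[in_flagged_subnetwork].astype(str).tolist()
    removed = set(drop) | flags
    keep = [f for f in matrix.index.astype(str) if f not in removed]
    if not keep:
        raise ValidationError("background filtering removed every feature")
    report = FilterReport(
        n_input_features=len(matrix),
        n_background_features=len(flags),
        n_background_subnetworks=len(sub_flags),
        n_after_background=len(keep),
    )
    return matrix.loc[keep], features.loc[keep], report


def flag_transient_features(matrix: pd.DataFrame, cfg: PipelineConfig) -> set[str]:
    """Features present in few samples, all at low intensity.

    ``matrix`` must already exclude blank columns (they leave the analysis
    at the background stage).  Presence means XIC strictly greater than 0;
    the intensity condition is strict ``<`` on the per-feature maximum.
    """
    if matrix.empty:
        raise ValidationError("empty intensity matrix")
    values = matrix.to_numpy(dtype=float)
    n_present = (values > 0).sum(axis=1)
    max_xic = values.max(axis=1)
    flagged = (n_present <= cfg.transient_max_samples) & (
        max_xic < cfg.transient_intensity_threshold
    )
    return set(matrix.index[flagged].astype(str))


def rare_reference_value(matrix: pd.DataFrame, cfg: PipelineConfig) -> float:
    """The "average ion intensity" against which rare subnetworks are judged."""
    values = matrix.to_numpy(dtype=float)
    if cfg.rare_reference == "grand_mean_nonzero":
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValidationError("all-zero matrix: rare reference undefined")
        return float(nonzero.mean())
    if cfg.rare_reference == "grand_mean_all":
        if values.size == 0:
            raise ValidationError("empty matrix")
        return float(values.mean())
    # mean_of_feature_max
    if values.size == 0:
        raise ValidationError("empty matrix")
    return float(values.max(axis=1).mean())


def flag_rare_subnetworks(
    matrix: pd.DataFrame, features: pd.DataFrame, cfg: PipelineConfig
) -> set[str]:
    """Subnetworks whose maximum feature intensity is below the average ion intensity."""
    reference = rare_reference_value(matrix, cfg)
    sub_max = (
        matrix.max(axis=1).groupby(features.loc[matrix.index, "subnetwork_id"]).max()
    )
    return set(sub_max.index[sub_max < reference].astype(str))


def run_filter_cascade(
    matrix: pd.DataFrame,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Background -> transient -> rare filtering, in that order.

    Blank columns are dropped from the returned matrix after the
    background stage.  The report is fully populated and satisfies
    ``n_after_background - n_transient_features == n_after_transient``.
    """
    require_roles(samples, ROLE_BLANK)
    matrix, features, report = remove_background(matrix, features, samples, cfg)
    _, sample_cols = _split_blank(matrix, samples)
    matrix = matrix[sample_cols]

    transient = flag_transient_features(matrix, cfg)
    keep = [f for f in matrix.index.astype(str) if f not in transient]
    report.n_transient_features = len(transient)
    report.n_after_transient = len(keep)
    if not keep:
        raise ValidationError("transient filtering removed every feature")
    matrix, features = matrix.loc[keep], features.loc[keep]

    rare = flag_rare_subnetworks(matrix, features, cfg)
    keep = [
        f
        for f in matrix.index.astype(str)
        if str(features.at[f, "subnetwork_id"]) not in rare
    ]
    report.n_rare_subnetworks = len(rare)
    report.n_after_rare = len(keep)
    if not keep:
        raise ValidationError("rare-subnetwork filtering removed every feature")
    matrix, features = matrix.loc[keep], features.loc[keep]
    report.n_subnetworks_retained = features["subnetwork_id"].nunique()
    if report.n_after_background - report.n_transient_features != report.n_after_transient:
        # internal consistency check; should be unreachable
        warnings.warn("filter report stage counts inconsistent", stacklevel=2)
    return matrix, features, report
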