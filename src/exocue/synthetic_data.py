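"""Synthetic feature tables and settlement assays with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real exudate LC-MS/MS data:

* per-feature baseline log10 XIC intensity drawn from N(mu, sigma_feature)
  across features (defaults 5.0, 0.8), with replicate noise
  N(0, sigma_replicate) across samples;
* intensity-dependent detection dropout (logistic in log10 intensity), so
  faint features plausibly trigger the transient rule;
* background contamination: a fraction of features carry blank intensities
  comparable to their sample intensities (carry-over ratio), so the
  blank-based background rule flags them by construction;
* subnetwork grouping (geometric member counts) with subnetwork-level
  log10 group shifts of ``effect_log10`` planted in a fraction of
  subnetworks, and optional treatment-only subnetworks whose control
  entries are zeroed;
* binomial settlement counts per well with cumulative daily scoring.

Every output is deterministic given ``rng_seed`` and passes the
``core_model`` validators; ground-truth labels are returned alongside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    ANNOTATION_COLUMNS,
    ROLE_BLANK,
    ROLE_CONTROL,
    ROLE_TREATMENT,
    ValidationError,
)

__all__ = ["SimulationSpec", "GroundTruth", "simulate_feature_table", "simulate_settlement"]

DEFAULT_SUPERCLASSES = (
    "Lipids and lipid-like molecules",
    "Benzenoids",
    "Organic acids and derivatives",
    "Organoheterocyclic compounds",
    "Organic oxygen compounds",
    "Phenylpropanoids and polyketides",
)
DEFAULT_SUPERCLASS_WEIGHTS = (0.35, 0.2, 0.15, 0.12, 0.1, 0.08)


@dataclass
class SimulationSpec:
    """Parameters of the synthetic exometabolome and settlement assay.

    Intensity-model defaults describe a typical untargeted seawater-exudate
    run: baseline log10 intensity N(5.0, 0.8) across features and
    replicate-to-replicate noise of 0.2 log10 units (~60% CV).  The planted
    enrichment (10% of subnetworks at a 4-fold, 0.602 log10, treatment
    shift with 5 samples per group) matches the scale of the group design
    the pipeline is meant to resolve.
    """

    n_subnetworks: int = 200
    mean_features_per_subnetwork: float = 5.0
    n_blanks: int = 3
    n_controls: int = 5
    n_treatments: int = 5
    base_log10_mean: float = 5.0
    base_log10_sd: float = 0.8
    replicate_log10_sd: float = 0.2
    within_subnetwork_log10_sd: float = 0.8
    dropout_midpoint_log10: float = 3.0
    dropout_scale_log10: float = 0.4
    background_fraction: float = 0.1
    blank_carryover_ratio: float = 1.0
    transient_fraction: float = 0.05
    transient_log10_range: tuple[float, float] = (3.0, 4.6)
    rare_fraction: float = 0.0
    rare_log10_offset: float = -1.5
    enriched_fraction: float = 0.1
    effect_log10: float = 0.602
    treatment_only_fraction: float = 0.0
    annotation_probability: float = 0.85
    superclasses: tuple[str, ...] = DEFAULT_SUPERCLASSES
    superclass_weights: tuple[float, ...] = DEFAULT_SUPERCLASS_WEIGHTS
    # settlement assay
    settlement_probabilities: dict = field(
        default_factory=lambda: {"control": 0.2, "treatment": 0.8}
    )
    n_wells: int = 5
    larvae_per_well: int = 10
    n_days: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "background_fraction",
            "transient_fraction",
            "rare_fraction",
            "enriched_fraction",
            "treatment_only_fraction",
            "annotation_probability",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_controls < 1 or self.n_treatments < 1 or self.n_blanks < 0:
            raise ValidationError("need n_controls, n_treatments >= 1 and n_blanks >= 0")
        if self.base_log10_sd <= 0 or self.replicate_log10_sd < 0:
            raise ValidationError("intensity SDs must be positive")
        if (self.enriched_fraction > 0 or self.treatment_only_fraction > 0) and (
            self.effect_log10 <= 0
        ):
            raise ValidationError(
                "enriched subnetworks require a positive effect_log10"
            )
        for p in self.settlement_probabilities.values():
            if not 0 <= p <= 1:
                raise ValidationError("settlement probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted labels serialized alongside every simulated dataset."""

    feature_labels: pd.Series  # background | transient | clean
    subnetwork_labels: pd.Series  # enriched_treatment | treatment_only | rare | null
    settlement_probabilities: dict = field(default_factory=dict)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        f = self.feature_labels.rename("label").rename_axis("feature_id").reset_index()
        s = (
            self.subnetwork_labels.rename("label")
            .rename_axis("subnetwork_id")
            .reset_index()
        )
        return f, s


def simulate_feature_table(spec: SimulationSpec):
    """Generate ``(matrix, features, samples, annotations, truth)``.

    See the module docstring for the generative model.  Feature and sample
    identifiers are stable and sorted; the same seed always yields the
    same tables.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_sub = spec.n_subnetworks
    if n_sub < 2:
        raise ValidationError("need at least 2 subnetworks")

    sub_ids = [f"SN{i:04d}" for i in range(n_sub)]
    geo_p = 1.0 / spec.mean_features_per_subnetwork
    members = np.maximum(1, rng.geometric(geo_p, n_sub))

    # subnetwork labels: enriched / treatment_only / rare drawn disjointly
    n_enriched = int(round(spec.enriched_fraction * n_sub))
    n_tonly = int(round(spec.treatment_only_fraction * n_sub))
    n_rare = int(round(spec.rare_fraction * n_sub))
    if n_enriched + n_tonly + n_rare > n_sub:
        raise ValidationError("label fractions exceed the number of subnetworks")
    order = rng.permutation(n_sub)
    labels = np.array(["null"] * n_sub, dtype=object)
    labels[order[:n_enriched]] = "enriched_treatment"
    labels[order[n_enriched : n_enriched + n_tonly]] = "treatment_only"
    labels[order[n_enriched + n_tonly : n_enriched + n_tonly + n_rare]] = "rare"
    sub_labels = pd.Series(labels, index=sub_ids)

    samples = pd.DataFrame(
        {
            "role": [ROLE_BLANK] * spec.n_blanks
            + [ROLE_CONTROL] * spec.n_controls
            + [ROLE_TREATMENT] * spec.n_treatments,
            "group_label": ["extraction_blank"] * spec.n_blanks
            + ["seawater"] * spec.n_controls
            + ["cca_exudate"] * spec.n_treatments,
            "replicate": list(range(1, spec.n_blanks + 1))
            + list(range(1, spec.n_controls + 1))
            + list(range(1, spec.n_treatments + 1)),
        },
        index=[f"BLK{i + 1}" for i in range(spec.n_blanks)]
        + [f"CTL{i + 1}" for i in range(spec.n_controls)]
        + [f"TRT{i + 1}" for i in range(spec.n_treatments)],
    )
    samples.index.name = "sample_id"
    blank_cols = samples.index[samples["role"] == ROLE_BLANK]
    ctrl_cols = samples.index[samples["role"] == ROLE_CONTROL]
    treat_cols = samples.index[samples["role"] == ROLE_TREATMENT]
    n_samples = len(samples)

    feature_rows = []
    intensity_rows = []
    feature_labels = {}
    fid_counter = 0
    for s_i, sid in enumerate(sub_ids):
        base_center = rng.normal(spec.base_log10_mean, spec.base_log10_sd)
        if sub_labels[sid] == "rare":
            base_center = rng.normal(
                spec.base_log10_mean + spec.rare_log10_offset, 0.3
            )
        shift = (
            spec.effect_log10
            if sub_labels[sid] in ("enriched_treatment", "treatment_only")
            else 0.0
        )
        for _ in range(members[s_i]):
            fid = f"F{fid_counter:05d}"
            fid_counter += 1
            is_background = (
                sub_labels[sid] == "null" and rng.random() < spec.background_fraction
            )
            is_transient = (
                not is_background
                and sub_labels[sid] == "null"
                and rng.random() < spec.transient_fraction
            )
            row = np.zeros(n_samples)
            if is_transient:
                n_present = rng.integers(1, 3)  # 1 or 2 non-blank samples
                present = rng.choice(
                    np.arange(spec.n_blanks, n_samples), size=n_present, replace=False
                )
                lo, hi = spec.transient_log10_range
                row[present] = 10 ** rng.uniform(lo, hi, n_present)
                feature_labels[fid] = "transient"
            else:
                b = rng.normal(base_center, spec.within_subnetwork_log10_sd)
                log_int = b + rng.normal(0, spec.replicate_log10_sd, n_samples)
                log_int[spec.n_blanks + spec.n_controls :] += shift
                row = 10.0**log_int
                row[: spec.n_blanks] = 0.0
                if is_background:
                    # procedural contaminant: blanks carry comparable signal
                    blank_log = b + np.log10(spec.blank_carryover_ratio) + rng.normal(
                        0, spec.replicate_log10_sd, spec.n_blanks
                    )
                    row[: spec.n_blanks] = 10.0**blank_log
                    feature_labels[fid] = "background"
                else:
                    feature_labels[fid] = "clean"
                # intensity-dependent dropout
                with np.errstate(over="ignore"):
                    p_detect = 1.0 / (
                        1.0
                        + np.exp(
                            -(log_int - spec.dropout_midpoint_log10)
                            / spec.dropout_scale_log10
                        )
                    )
                detected = rng.random(n_samples) < p_detect
                row = np.where(detected, row, 0.0)
                if sub_labels[sid] == "treatment_only":
                    row[spec.n_blanks : spec.n_blanks + spec.n_controls] = 0.0
            intensity_rows.append(row)
            feature_rows.append(
                {
                    "feature_id": fid,
                    "mz": float(rng.uniform(150.0, 1500.0)),
                    "rt": float(rng.uniform(30.0, 720.0)),
                    "subnetwork_id": sid,
                }
            )

    features = pd.DataFrame(feature_rows).set_index("feature_id")
    matrix = pd.DataFrame(
        np.array(intensity_rows), index=features.index, columns=samples.index
    )

    ann_rows = []
    for sid in sub_ids:
        if rng.random() < spec.annotation_probability:
            superclass = rng.choice(
                spec.superclasses, p=np.array(spec.superclass_weights) / sum(spec.superclass_weights)
            )
            ann_rows.append(
                {
                    "subnetwork_id": sid,
                    "superclass": superclass,
                    "class": f"{superclass} / class",
                    "subclass": f"{superclass} / subclass",
                    "source": "consensus",
                }
            )
    annotations = (
        pd.DataFrame(ann_rows).set_index("subnetwork_id")[ANNOTATION_COLUMNS]
        if ann_rows
        else pd.DataFrame(columns=ANNOTATION_COLUMNS)
    )

    truth = GroundTruth(
        feature_labels=pd.Series(feature_labels).reindex(features.index),
        subnetwork_labels=sub_labels,
        settlement_probabilities=dict(spec.settlement_probabilities),
    )
    return matrix, features, samples, annotations, truth


def simulate_settlement(spec: SimulationSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-well settlement counts with cumulative daily scoring.

    Each treatment label in ``spec.settlement_probabilities`` receives
    ``n_wells`` wells of ``larvae_per_well`` larvae; the day-``n_days``
    cumulative settled count is Binomial(larvae, p) and each settled larva
    is assigned a uniform settlement day, so daily counts are monotone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0x5E7]))
    rows = []
    well = 0
    for label, p in spec.settlement_probabilities.items():
        control_role = "seawater_control" if label == "control" else "none"
        for _ in range(spec.n_wells):
            well += 1
            total = rng.binomial(spec.larvae_per_well, p)
            days = rng.integers(1, spec.n_days + 1, size=total)
            for day in range(1, spec.n_days + 1):
                rows.append(
                    {
                        "well_id": f"W{well:03d}",
                        "coral_species": "synthetic_coral",
                        "factor_a": label,
                        "factor_b": "exometabolite",
                        "control_role": control_role,
                        "larvae_added": spec.larvae_per_well,
                        "larvae_settled": int((days <= day).sum()),
                        "day": day,
                    }
                )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        feature_labels=pd.Series(dtype=object),
        subnetwork_labels=pd.Series(dtype=object),
        settlement_probabilities=dict(spec.settlement_probabilities),
    )
    return table, truth
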