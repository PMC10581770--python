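"""Domain types, table I/O and validation shared by all pipeline stages.

The pipeline operates on three aligned tables:

* an **intensity matrix** -- a :class:`pandas.DataFrame` of non-negative
  extracted-ion-chromatogram (XIC) intensities, indexed by ``feature_id``
  with one column per ``sample_id``; zero encodes non-detection;
* a **feature table** -- one row per ion feature carrying ``mz`` (Da),
  ``rt`` (seconds) and the molecular subnetwork the feature belongs to;
* a **sample table** -- one row per sample carrying its ``role``
  (``blank`` / ``control`` / ``treatment``), a free-text group label and a
  replicate number.

Feature quantification tables in the wide MzMine export dialect
(``row ID, row m/z, row retention time, subnetwork, <sample>.mzXML Peak
area``) are read with :func:`read_feature_table`.  Features without a
subnetwork assignment are treated as singletons (``S:<feature_id>``),
mirroring how unclustered self-loop nodes come out of feature-based
molecular networking.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ROLE_BLANK = "blank"
ROLE_CONTROL = "control"
ROLE_TREATMENT = "treatment"
ROLES = (ROLE_BLANK, ROLE_CONTROL, ROLE_TREATMENT)

#: default acquisition window for m/z sanity checks (Da)
DEFAULT_MZ_RANGE = (150.0, 1500.0)

FEATURE_COLUMNS = ["mz", "rt", "subnetwork_id"]
SAMPLE_COLUMNS = ["role", "group_label", "replicate"]
ANNOTATION_COLUMNS = ["superclass", "class", "subclass", "source"]
ANNOTATION_SOURCES = ("library_match", "in_silico", "consensus", "none")

_PEAK_AREA_SUFFIX = re.compile(r"\s*(\.mzX?ML)?\s*Peak (area|height)\s*$", re.I)

# column-name aliases for the wide MzMine quantification dialect
DEFAULT_ALIASES = {
    "feature_id": ("row ID", "feature_id", "id"),
    "mz": ("row m/z", "mz"),
    "rt": ("row retention time", "rt"),
    "subnetwork_id": ("subnetwork", "subnetwork_id", "componentindex", "network"),
}


class ValidationError(ValueError):
    """A table violated a structural invariant of the pipeline."""


@dataclass(frozen=True)
class FeatureRecord:
    """One ion feature: an (m/z, retention time) signal with a subnetwork."""

    feature_id: str
    mz: float
    rt: float  # seconds
    subnetwork_id: str


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    role: str  # blank | control | treatment
    group_label: str = ""
    replicate: int = 1


@dataclass
class PipelineConfig:
    """All numeric constants of the filtering and enrichment procedure.

    Defaults are the values used throughout the analysis: background
    features are those whose mean non-blank log10 intensity does not exceed
    ``blank_multiplier`` times the maximum blank log10 intensity; a
    subnetwork with more than ``background_subnetwork_fraction`` background
    members is removed wholesale; transient features are present in at most
    ``transient_max_samples`` samples with every XIC below
    ``transient_intensity_threshold``; the random-forest screen uses
    ``n_trees`` trees and ``n_importance_reps`` total permutation
    repetitions, selecting subnetworks whose mean-decrease-accuracy is at
    least ``mda_sd_multiplier`` standard deviations above the mean.
    """

    blank_multiplier: float = 2.0
    background_subnetwork_fraction: float = 0.5
    transient_max_samples: int = 2
    transient_intensity_threshold: float = 5e4
    nondetect_log_value: float = 0.0
    n_trees: int = 29188
    n_importance_reps: int = 10000
    mda_sd_multiplier: float = 1.0
    alpha: float = 0.05
    rng_seed: int = 0
    # sensitivity / variant switches
    blank_max_on_log_scale: bool = True
    rare_reference: str = "grand_mean_nonzero"
    welch: bool = False
    one_sided: bool = True
    dunnett_draws: int = 100_000
    treatment_only_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.blank_multiplier <= 0:
            raise ValidationError("blank_multiplier must be > 0")
        if not 0 < self.background_subnetwork_fraction <= 1:
            raise ValidationError("background_subnetwork_fraction must be in (0, 1]")
        if self.transient_max_samples < 0:
            raise ValidationError("transient_max_samples must be >= 0")
        if self.transient_intensity_threshold <= 0:
            raise ValidationError("transient_intensity_threshold must be > 0")
        if self.n_trees <= 0 or self.n_importance_reps <= 0:
            raise ValidationError("n_trees and n_importance_reps must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.rare_reference not in (
            "grand_mean_nonzero",
            "grand_mean_all",
            "mean_of_feature_max",
        ):
            raise ValidationError(f"unknown rare_reference {self.rare_reference!r}")
        if not 0 < self.treatment_only_fraction <= 1:
            raise ValidationError("treatment_only_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from a YAML (or flat ``key=value``) file.

        Keyword overrides win over file values, mirroring CLI-flag
        precedence.
        """
        raw = Path(path).read_text()
        data = yaml.safe_load(raw)
        if isinstance(data, str):  # flat key=value lines
            data = {}
            for line in raw.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = yaml.safe_load(val.strip())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} did not parse to a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# validation


def validate_tables(
    matrix: pd.DataFrame,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    mz_range: tuple[float, float] | None = DEFAULT_MZ_RANGE,
) -> None:
    """Check the structural invariants tying the three tables together.

    Raises :class:`ValidationError` on any violation; m/z values outside
    the acquisition window only warn (boundary features occur in real
    exports).
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids: {dupes}")
    if matrix.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in intensity matrix")
    if features.index.has_duplicates:
        dupes = features.index[features.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in feature table: {dupes}")
    if samples.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    if set(matrix.index) != set(features.index):
        raise ValidationError("intensity matrix and feature table index mismatch")
    if set(matrix.columns) != set(samples.index):
        raise ValidationError("intensity matrix columns and sample metadata mismatch")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("intensity matrix contains non-finite values")
    if (values < 0).any():
        raise ValidationError("intensity matrix contains negative values")
    bad_roles = set(samples["role"]) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
    if features["subnetwork_id"].isna().any():
        raise ValidationError("features with missing subnetwork_id after read")
    if mz_range is not None and len(features):
        lo, hi = mz_range
        outside = features["mz"].dropna()
        outside = outside[(outside < lo) | (outside > hi)]
        if len(outside):
            warnings.warn(
                f"{len(outside)} features have m/z outside the acquisition "
                f"window [{lo}, {hi}]",
                stacklevel=2,
            )


def require_roles(samples: pd.DataFrame, *roles: str) -> None:
    for role in roles:
        if not (samples["role"] == role).any():
            raise ValidationError(f"no samples with role {role!r}")


# ---------------------------------------------------------------------------
# readers


def _resolve_alias(columns: Sequence[str], aliases: Iterable[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias.lower() in lowered:
            return lowered[alias.lower()]
    return None


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata CSV (``sample_id, role, group_label, replicate``)."""
    meta = pd.read_csv(path, dtype={"sample_id": str})
    missing = {"sample_id", "role"} - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if "group_label" not in meta.columns:
        meta["group_label"] = ""
    if "replicate" not in meta.columns:
        meta["replicate"] = 1
    meta["group_label"] = meta["group_label"].fillna("").astype(str)
    meta["role"] = meta["role"].astype(str).str.strip().str.lower()
    meta = meta.set_index("sample_id")[SAMPLE_COLUMNS]
    bad = set(meta["role"]) - set(ROLES)
    if bad:
        raise ValidationError(f"unknown sample roles in metadata: {sorted(bad)}")
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    return meta


def read_feature_table(
    path: str | Path,
    metadata_path: str | Path,
    *,
    long_format: bool = False,
    rt_minutes: bool = False,
    aliases: Mapping[str, Sequence[str]] | None = None,
    mz_range: tuple[float, float] | None = DEFAULT_MZ_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a feature quantification table plus its sample metadata.

    Returns ``(matrix, features, samples)``: the intensity matrix
    (features x samples), the per-feature table (``mz``, ``rt`` in
    seconds, ``subnetwork_id``) and the sample table.  Missing intensity
    cells become 0 (non-detection); features lacking a subnetwork id are
    assigned singleton subnetworks ``S:<feature_id>`` with a warning.

    ``long_format=True`` expects tidy rows
    ``feature_id, mz, rt, subnetwork_id, sample_id, intensity`` instead of
    one column per sample.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k: tuple(v) for k, v in aliases.items()})
    samples = read_sample_metadata(metadata_path)

    raw = pd.read_csv(path)
    resolved = {
        key: _resolve_alias(raw.columns, names) for key, names in alias_map.items()
    }
    if resolved["feature_id"] is None:
        raise ValidationError(f"no feature id column found in {path}")

    if long_format:
        needed = {"sample_id", "intensity"}
        if not needed <= set(raw.columns):
            raise ValidationError(
                "long-format table requires 'sample_id' and 'intensity' columns"
            )
        wide = raw.pivot_table(
            index=resolved["feature_id"],
            columns="sample_id",
            values="intensity",
            aggfunc="sum",
        )
        attr_cols = [resolved[k] for k in ("mz", "rt", "subnetwork_id") if resolved[k]]
        attrs = raw.drop_duplicates(resolved["feature_id"]).set_index(
            resolved["feature_id"]
        )[attr_cols]
        raw = attrs.join(wide).reset_index()

    feature_ids = raw[resolved["feature_id"]].astype(str)
    if feature_ids.duplicated().any():
        dupes = feature_ids[feature_ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dupes}")

    attr_columns = {resolved[k] for k in resolved if resolved[k] is not None}
    sample_cols: list[str] = []
    for col in raw.columns:
        if col in attr_columns:
            continue
        stripped = _PEAK_AREA_SUFFIX.sub("", col).strip()
        if stripped in samples.index or col in samples.index:
            sample_cols.append(col)
        elif _PEAK_AREA_SUFFIX.search(col):
            raise ValidationError(
                f"sample column {col!r} ({stripped!r}) absent from metadata"
            )
        else:
            warnings.warn(f"ignoring unrecognized column {col!r}", stacklevel=2)

    matrix = raw[sample_cols].copy()
    matrix.columns = [
        _PEAK_AREA_SUFFIX.sub("", c).strip()
        if _PEAK_AREA_SUFFIX.sub("", c).strip() in samples.index
        else c
        for c in sample_cols
    ]
    matrix.index = pd.Index(feature_ids, name="feature_id")
    matrix.columns.name = "sample_id"
    matrix = matrix.apply(pd.to_numeric, errors="raise").fillna(0.0).astype(float)
    if (matrix.to_numpy() < 0).any():
        raise ValidationError(f"negative intensities in {path}")

    missing_samples = set(samples.index) - set(matrix.columns)
    if missing_samples:
        raise ValidationError(
            f"metadata samples absent from feature table: {sorted(missing_samples)}"
        )

    features = pd.DataFrame(index=matrix.index)
    features["mz"] = (
        pd.to_numeric(raw[resolved["mz"]], errors="coerce").to_numpy()
        if resolved["mz"]
        else np.nan
    )
    rt = (
        pd.to_numeric(raw[resolved["rt"]], errors="coerce").to_numpy()
        if resolved["rt"]
        else np.full(len(raw), np.nan)
    )
    features["rt"] = rt * 60.0 if rt_minutes else rt
    if resolved["subnetwork_id"]:
        sub = raw[resolved["subnetwork_id"]].astype("string")
        sub = sub.where(~sub.isin(["-1", ""]), other=pd.NA)  # GNPS self-loop marker
    else:
        sub = pd.Series(pd.NA, index=raw.index, dtype="string")
    n_missing = int(sub.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} features lack a subnetwork id; assigned singleton "
            "subnetworks",
            stacklevel=2,
        )
    sub = sub.fillna("S:" + feature_ids)
    features["subnetwork_id"] = sub.astype(str).to_numpy()

    matrix = matrix[[c for c in samples.index if c in matrix.columns]]
    validate_tables(matrix, features, samples, mz_range=mz_range)
    return matrix, features, samples


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read subnetwork consensus annotations (superclass/class/subclass)."""
    ann = pd.read_csv(path, dtype=str)
    if "subnetwork_id" not in ann.columns:
        raise ValidationError("annotation table requires a 'subnetwork_id' column")
    ann = ann.set_index("subnetwork_id")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = pd.NA
    if ann.index.has_duplicates:
        raise ValidationError("multiple annotation rows for one subnetwork")
    ann["source"] = ann["source"].fillna("none")
    bad = set(ann["source"]) - set(ANNOTATION_SOURCES)
    if bad:
        raise ValidationError(f"unknown annotation sources: {sorted(bad)}")
    return ann[ANNOTATION_COLUMNS]


# ---------------------------------------------------------------------------
# writers


def write_feature_table(
    matrix: pd.DataFrame,
    features: pd.DataFrame,
    path: str | Path,
    *,
    float_format: str = "%.12g",
) -> None:
    """Write the wide-dialect feature table consumed by :func:`read_feature_table`."""
    out = pd.DataFrame(
        {
            "row ID": matrix.index,
            "row m/z": features.loc[matrix.index, "mz"].to_numpy(),
            "row retention time": features.loc[matrix.index, "rt"].to_numpy(),
            "subnetwork": features.loc[matrix.index, "subnetwork_id"].to_numpy(),
        }
    )
    for col in matrix.columns:
        out[f"{col}.mzXML Peak area"] = matrix[col].to_numpy()
    out.to_csv(path, index=False, float_format=float_format)


def write_sample_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, index=False
    )


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.reset_index().to_csv(path, index=False)


def write_enrichment_table(
    results: pd.DataFrame,
    features: pd.DataFrame,
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    annotations: pd.DataFrame | None,
    path: str | Path,
) -> pd.DataFrame:
    """Write the curated per-feature table of enriched subnetworks.

    One row per member feature of every subnetwork whose enrichment
    ``direction`` is not ``"none"``, with feature identity (m/z, RT),
    per-role mean XIC intensity, the subnetwork's screening and testing
    statistics and any consensus ontology annotation.  Rows are ordered by
    (subnetwork_id, feature_id) so repeated writes are byte-identical.
    """
    unknown = set(results.index) - set(features["subnetwork_id"])
    # subnetworks may legitimately have been reduced to no features only if
    # results were computed on a different table -- that is an error
    if unknown and len(results):
        raise ValidationError(f"results reference unknown subnetworks: {sorted(unknown)}")

    enriched = results[results["direction"] != "none"]
    rows = []
    role_means = {}
    for role in (ROLE_CONTROL, ROLE_TREATMENT):
        cols = samples.index[samples["role"] == role]
        cols = [c for c in cols if c in matrix.columns]
        role_means[role] = (
            matrix[cols].mean(axis=1) if cols else pd.Series(np.nan, index=matrix.index)
        )
    for subnetwork_id in sorted(enriched.index.astype(str)):
        res = enriched.loc[subnetwork_id]
        members = features.index[features["subnetwork_id"] == subnetwork_id]
        for fid in sorted(members.astype(str)):
            row = {
                "feature_id": fid,
                "subnetwork_id": subnetwork_id,
                "mz": features.at[fid, "mz"],
                "rt": features.at[fid, "rt"],
                "mean_xic_control": role_means[ROLE_CONTROL].get(fid, np.nan),
                "mean_xic_treatment": role_means[ROLE_TREATMENT].get(fid, np.nan),
                "mda": res["mda"],
                "q_fdr": res["q_fdr"],
                "direction": res["direction"],
                "treatment_only": bool(res.get("treatment_only", False)),
            }
            if annotations is not None and subnetwork_id in annotations.index:
                ann = annotations.loc[subnetwork_id]
                row.update(
                    superclass=ann["superclass"],
                    **{"class": ann["class"]},
                    subclass=ann["subclass"],
                    annotation_source=ann["source"],
                )
            else:
                row.update(
                    superclass=pd.NA,
                    **{"class": pd.NA},
                    subclass=pd.NA,
                    annotation_source="none",
                )
            rows.append(row)
    columns = [
        "feature_id",
        "subnetwork_id",
        "mz",
        "rt",
        "mean_xic_control",
        "mean_xic_treatment",
        "mda",
        "q_fdr",
        "direction",
        "treatment_only",
        "superclass",
        "class",
        "subclass",
        "annotation_source",
    ]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(path, index=False, float_format="%.12g")
    return table


def export_network_edges(
    features: pd.DataFrame,
    edges: Iterable[tuple[str, str, float]],
    results: pd.DataFrame | None,
    sif_path: str | Path,
    node_path: str | Path,
    matrix: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
) -> int:
    """Export a molecular network for external rendering.

    Writes a SIF-style edge file (``source<TAB>score<TAB>target``) and a
    node-attribute CSV carrying each feature's subnetwork, enrichment
    direction and, when the intensity matrix is supplied, the fraction of
    its total XIC intensity observed in each sample role (the per-node
    "pie chart" fractions).  Edges touching unknown features are dropped
    with a warning.  Returns the number of edges written.
    """
    known = set(features.index.astype(str))
    n_written = 0
    with open(sif_path, "w") as fh:
        for source, target, score in edges:
            if str(source) not in known or str(target) not in known:
                warnings.warn(
                    f"dropping edge {source!r}--{target!r}: unknown feature",
                    stacklevel=2,
                )
                continue
            fh.write(f"{source}\t{score:.6g}\t{target}\n")
            n_written += 1

    nodes = pd.DataFrame(index=features.index.astype(str))
    nodes["subnetwork_id"] = features["subnetwork_id"].to_numpy()
    if results is not None and "direction" in results:
        direction = features["subnetwork_id"].map(results["direction"])
        nodes["direction"] = direction.fillna("none").to_numpy()
    else:
        nodes["direction"] = "none"
    if matrix is not None and samples is not None:
        totals = matrix.sum(axis=1)
        for role in ROLES:
            cols = [c for c in samples.index[samples["role"] == role] if c in matrix]
            frac = matrix[cols].sum(axis=1) / totals.replace(0, np.nan) if cols else 0.0
            nodes[f"intensity_fraction_{role}"] = np.asarray(frac, dtype=float)
    nodes.sort_index().reset_index(names="feature_id").to_csv(
        node_path, index=False, float_format="%.12g"
    )
    return n_written


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def dump_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
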