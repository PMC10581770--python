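"""Coral larval settlement bioassay statistics.

Settlement counts (larvae attached out of larvae added per well) are
relativized to proportions and variance-stabilized with the angular
(arcsine-square-root) transformation before a two-way factorial ANOVA and
Dunnett many-to-one comparisons against the seawater control.  For the
fractionation design each fraction x concentration treatment is compared
against *two* controls -- the unfractionated seawater control and its own
resin (column methanol) control -- and is called settlement-inducing only
when both FDR-corrected Dunnett comparisons are significant.

Dunnett p-values come from the max-t statistic of the multivariate-t null
with the design's correlation structure, evaluated by seeded Monte-Carlo
integration; the single-treatment family reduces analytically to the
one-sided two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .core_model import PipelineConfig, ValidationError

__all__ = [
    "SettlementTestResult",
    "angular_transform",
    "read_settlement_table",
    "two_way_anova",
    "dunnett_many_to_one",
    "single_control_assessment",
    "dual_control_assessment",
]

SETTLEMENT_COLUMNS = [
    "well_id",
    "coral_species",
    "factor_a",
    "factor_b",
    "control_role",
    "larvae_added",
    "larvae_settled",
    "day",
]
CONTROL_ROLES = ("none", "seawater_control", "resin_control")


@dataclass
class SettlementTestResult:
    """ANOVA table plus per-treatment many-to-one comparisons."""

    anova: pd.DataFrame
    comparisons: pd.DataFrame
    family_description: str = ""


def angular_transform(settled, added):
    """arcsin(sqrt(settled/added)) in radians; range [0, pi/2].

    Vectorized; raises on counts outside ``0 <= settled <= added``.
    """
    settled_arr = np.asarray(settled, dtype=float)
    added_arr = np.asarray(added, dtype=float)
    if (added_arr <= 0).any():
        raise ValidationError("larvae_added must be positive")
    if (settled_arr < 0).any() or (settled_arr > added_arr).any():
        raise ValidationError("larvae_settled must satisfy 0 <= settled <= added")
    out = np.arcsin(np.sqrt(settled_arr / added_arr))
    if np.isscalar(settled) and np.isscalar(added):
        return float(out)
    return out


def read_settlement_table(path) -> pd.DataFrame:
    """Read a per-well settlement CSV and validate counts."""
    table = pd.read_csv(path)
    missing = set(SETTLEMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"settlement table missing columns: {sorted(missing)}")
    bad = set(table["control_role"]) - set(CONTROL_ROLES)
    if bad:
        raise ValidationError(f"unknown control roles: {sorted(bad)}")
    if (table["larvae_settled"] > table["larvae_added"]).any():
        raise ValidationError("larvae_settled exceeds larvae_added")
    return table


def _day_slice(table: pd.DataFrame, day: int | None) -> pd.DataFrame:
    if day is None:
        day = int(table["day"].max())  # cumulative endpoint: last scoring day
    sliced = table[table["day"] == day].copy()
    if sliced.empty:
        raise ValidationError(f"no observations for day {day}")
    sliced["response"] = angular_transform(
        sliced["larvae_settled"].to_numpy(), sliced["larvae_added"].to_numpy()
    )
    return sliced


def two_way_anova(table: pd.DataFrame, day: int | None = None) -> pd.DataFrame:
    """Type-II two-way factorial ANOVA on angular-transformed settlement.

    Factors are ``factor_a`` and ``factor_b``; a factor with a single
    observed level is dropped from the model with a warning.  Zero-variance
    responses yield F = 0, p = 1 for every term.
    """
    data = _day_slice(table, day)
    terms = []
    for factor in ("factor_a", "factor_b"):
        if data[factor].nunique() > 1:
            terms.append(f"C({factor})")
        else:
            warnings.warn(f"{factor} has a single level; dropped from the model",
                          stacklevel=2)
    if not terms:
        raise ValidationError("no factor with more than one level")
    formula = "response ~ " + " + ".join(terms)
    if len(terms) == 2:
        formula += " + " + ":".join(terms)
    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on 0 residual SS
        anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        columns={"sum_sq": "SS", "F": "F", "PR(>F)": "p"}
    )
    if np.allclose(data["response"].var(ddof=0), 0.0):
        anova.loc[anova.index != "Residual", "F"] = 0.0
        anova.loc[anova.index != "Residual", "p"] = 1.0
    return anova


def _pooled_sd(groups: list[np.ndarray]) -> tuple[float, int]:
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = sum(len(g) - 1 for g in groups)
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    return float(np.sqrt(ss / df)), df


def dunnett_many_to_one(
    treatment_groups: list[np.ndarray],
    control_group: np.ndarray,
    cfg: PipelineConfig | None = None,
    *,
    alternative: str | None = None,
) -> np.ndarray:
    """Dunnett many-to-one comparison p-values against a shared control.

    The joint null of the k treatment-vs-control t statistics is
    multivariate t with correlation
    ``rho_ij = sqrt(n_i n_j / ((n_i + n0)(n_j + n0)))`` and the pooled
    residual degrees of freedom; the p-value for treatment i is
    ``P(max_j T_j >= t_i)`` (one-sided "greater", the default) evaluated by
    Monte-Carlo with ``cfg.dunnett_draws`` seeded draws.  With a single
    treatment group the p-value is the exact one-sided (or two-sided)
    two-sample pooled t-test p.
    """
    cfg = cfg or PipelineConfig()
    if alternative is None:
        alternative = "greater" if cfg.one_sided else "two-sided"
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    groups = [np.asarray(g, dtype=float) for g in treatment_groups]
    control = np.asarray(control_group, dtype=float)
    if any(len(g) < 2 for g in groups) or len(control) < 2:
        raise ValidationError("need >= 2 observations per group")
    k = len(groups)
    if k == 0:
        return np.array([])

    s, df = _pooled_sd(groups + [control])
    n0 = len(control)
    t_obs = np.array(
        [
            (g.mean() - control.mean()) / (s * np.sqrt(1 / len(g) + 1 / n0))
            if s > 0
            else (np.inf if g.mean() > control.mean() else (0.0 if g.mean() == control.mean() else -np.inf))
            for g in groups
        ]
    )

    if k == 1:
        if not np.isfinite(t_obs[0]):
            p = 0.0 if t_obs[0] > 0 else 1.0
        else:
            p = float(stats.t.sf(t_obs[0], df))
        if alternative == "two-sided":
            p = float(2 * stats.t.sf(abs(t_obs[0]), df)) if np.isfinite(t_obs[0]) else 0.0
        return np.array([min(p, 1.0)])

    n = np.array([len(g) for g in groups], dtype=float)
    lam = np.sqrt(n / (n + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0xD0]))
    draws = int(cfg.dunnett_draws)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((draws, k)) @ chol.T
    scale = np.sqrt(rng.chisquare(df, size=draws) / df)
    t_null = z / scale[:, None]
    if alternative == "greater":
        max_stat = t_null.max(axis=1)
        p = np.array(
            [float((max_stat >= t).mean()) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
             for t in t_obs]
        )
    else:
        max_stat = np.abs(t_null).max(axis=1)
        p = np.array(
            [float((max_stat >= abs(t)).mean()) if np.isfinite(t) else 0.0
             for t in t_obs]
        )
    return p


def _group_values(data: pd.DataFrame, mask) -> np.ndarray:
    return data.loc[mask, "response"].to_numpy(dtype=float)


def single_control_assessment(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    day: int | None = None,
) -> SettlementTestResult:
    """ANOVA plus Dunnett comparisons of every treatment vs the seawater control.

    Treatments are the distinct ``(factor_a, factor_b)`` combinations with
    ``control_role == "none"``; the family is BH-FDR corrected jointly.
    """
    cfg = cfg or PipelineConfig()
    data = _day_slice(table, day)
    ctrl = _group_values(data, data["control_role"] == "seawater_control")
    if len(ctrl) < 2:
        raise ValidationError("need >= 2 seawater control wells")
    treatments = (
        data.loc[data["control_role"] == "none", ["factor_a", "factor_b"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    labels, groups = [], []
    for fa, fb in treatments:
        vals = _group_values(
            data,
            (data["factor_a"] == fa)
            & (data["factor_b"] == fb)
            & (data["control_role"] == "none"),
        )
        if len(vals) >= 2:
            labels.append((fa, fb))
            groups.append(vals)
    if not groups:
        raise ValidationError("no treatment group with >= 2 wells")
    p_raw = dunnett_many_to_one(groups, ctrl, cfg)
    _, q, _, _ = multipletests(p_raw, alpha=cfg.alpha, method="fdr_bh")
    comparisons = pd.DataFrame(
        {
            "factor_a": [l[0] for l in labels],
            "factor_b": [l[1] for l in labels],
            "control": "seawater_control",
            "estimate": [g.mean() - ctrl.mean() for g in groups],
            "p_raw": p_raw,
            "p_fdr": q,
            "significant": q < cfg.alpha,
        }
    )
    anova = two_way_anova(table, day)
    return SettlementTestResult(
        anova=anova,
        comparisons=comparisons,
        family_description="Dunnett vs seawater control; BH-FDR across all "
        "treatments within this table (one coral species x metabolite type)",
    )


def dual_control_assessment(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    day: int | None = None,
) -> SettlementTestResult:
    """Fractionation-design test against both seawater and resin controls.

    Each ``factor_a`` (resin) x ``factor_b`` (concentration) treatment is
    Dunnett-compared (a) within the family of all treatments against the
    unfractionated seawater control and (b) within its resin's family
    against that resin's column control.  Both p-value sets are BH-FDR
    corrected within their family; a treatment is significant only when
    both corrected p-values fall below ``alpha``.  Treatments whose resin
    control is missing are reported as not evaluable.
    """
    cfg = cfg or PipelineConfig()
    data = _day_slice(table, day)
    sea = _group_values(data, data["control_role"] == "seawater_control")
    if len(sea) < 2:
        raise ValidationError("need >= 2 seawater control wells")

    treat = data[data["control_role"] == "none"]
    combos = treat[["factor_a", "factor_b"]].drop_duplicates()
    labels = [tuple(r) for r in combos.itertuples(index=False)]
    groups = {
        (fa, fb): _group_values(
            treat, (treat["factor_a"] == fa) & (treat["factor_b"] == fb)
        )
        for fa, fb in labels
    }
    labels = [l for l in labels if len(groups[l]) >= 2]
    if not labels:
        raise ValidationError("no treatment group with >= 2 wells")

    # family 1: all treatments vs the seawater control
    p_sea = dunnett_many_to_one([groups[l] for l in labels], sea, cfg)
    _, q_sea, _, _ = multipletests(p_sea, alpha=cfg.alpha, method="fdr_bh")
    q_sea_map = dict(zip(labels, q_sea))
    p_sea_map = dict(zip(labels, p_sea))

    # family 2: per resin, its treatments vs its own column control;
    # BH across all resin-side comparisons pooled
    p_resin_map: dict = {}
    evaluable: dict = {}
    resin_labels, resin_ps = [], []
    for resin in sorted({fa for fa, _ in labels}):
        resin_ctrl = _group_values(
            data,
            (data["control_role"] == "resin_control") & (data["factor_a"] == resin),
        )
        members = [l for l in labels if l[0] == resin]
        if len(resin_ctrl) < 2:
            for l in members:
                evaluable[l] = False
            warnings.warn(
                f"no resin control for {resin!r}; its treatments are not evaluable",
                stacklevel=2,
            )
            continue
        ps = dunnett_many_to_one([groups[l] for l in members], resin_ctrl, cfg)
        for l, p in zip(members, ps):
            evaluable[l] = True
            resin_labels.append(l)
            resin_ps.append(p)
    if resin_ps:
        _, q_resin, _, _ = multipletests(resin_ps, alpha=cfg.alpha, method="fdr_bh")
        for l, q in zip(resin_labels, q_resin):
            p_resin_map[l] = q
    raw_resin_map = dict(zip(resin_labels, resin_ps))

    rows = []
    for l in labels:
        ok = evaluable.get(l, False)
        q_r = p_resin_map.get(l, np.nan)
        rows.append(
            {
                "factor_a": l[0],
                "factor_b": l[1],
                "p_seawater_raw": p_sea_map[l],
                "p_seawater_fdr": q_sea_map[l],
                "p_resin_raw": raw_resin_map.get(l, np.nan),
                "p_resin_fdr": q_r,
                "evaluable": ok,
                "significant": bool(
                    ok and q_sea_map[l] < cfg.alpha and q_r < cfg.alpha
                ),
            }
        )
    comparisons = pd.DataFrame(rows)
    anova = two_way_anova(table, day)
    return SettlementTestResult(
        anova=anova,
        comparisons=comparisons,
        family_description="dual Dunnett: BH-FDR within the seawater-control "
        "family (all treatments) and within the pooled resin-control family; "
        "significant requires both",
    )
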