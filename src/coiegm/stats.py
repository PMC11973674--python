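"""Group-level inference on the post-ablation time course.

The repeated-measures structure (several lesions per animal) is handled
with a linear mixed-effects model: the (normalized) segment value is
modeled as ``value ~ time + group + time:group`` with a random intercept
per animal, fitted by restricted maximum likelihood.  Time is treated as
continuous seconds because the scientific question is a difference in
recovery *slopes* over the 30 s - 3 min window.  Significance of the
``time`` and ``time x group`` fixed effects is assessed with 1-df Wald
chi-square tests (equivalent to the ANOVA on these terms when the group
factor has two levels).

Per-timepoint two-group comparisons use a Student t test when both
groups pass Shapiro-Wilk normality and a median-centered Levene
equality-of-variance check at alpha = 0.05, and a Mann-Whitney U test
otherwise; the branch taken is reported.  P-values are reported raw,
without multiple-testing correction across timepoints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sstats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .features import FeatureSeries

__all__ = [
    "LMEFit",
    "TwoGroupTest",
    "fit_lme",
    "per_timepoint_test",
    "recovery_slope",
    "simulate_long_table",
]

REQUIRED_COLUMNS = ("lesion_id", "animal_id", "group", "t_rel_s")


@dataclass
class LMEFit:
    """Fixed-effect estimates and Wald ANOVA p-values of one LME fit."""

    fixed_effects: dict[str, float]
    std_errors: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float
    anova_pvalues: dict[str, float]
    n_obs: int
    groups: tuple[str, str]
    n_animals: int
    converged: bool
    singular: bool
    note: str = ""


def fit_lme(
    table: pd.DataFrame,
    t_from_s: float = 30.0,
    t_to_s: float = 180.0,
    value_col: str = "normalized",
    reml: bool = True,
) -> LMEFit:
    """Fit ``value ~ time * group`` with a per-animal random intercept.

    ``table`` is a long-format frame with columns ``lesion_id``,
    ``animal_id``, ``group`` (exactly two levels), ``t_rel_s`` and the
    value column; rows outside [t_from_s, t_to_s] or with missing values
    are dropped.  A singular or non-converged fit is returned with its
    diagnostic flags set, never silently discarded.
    """
    missing = [c for c in (*REQUIRED_COLUMNS, value_col) if c not in table.columns]
    if missing:
        raise ValueError(f"long table missing columns {missing}")
    df = table.loc[
        (table["t_rel_s"] >= t_from_s)
        & (table["t_rel_s"] <= t_to_s)
        & table[value_col].notna()
    ].copy()
    if "valid" in df.columns:
        df = df[df["valid"]]
    groups = tuple(sorted(df["group"].astype(str).unique()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in [{t_from_s}, {t_to_s}] s, got {groups}")
    n_animals = df["animal_id"].nunique()
    if n_animals < 2:
        raise ValueError("need at least 2 animals for a random intercept")
    if df["t_rel_s"].nunique() < 2:
        raise ValueError("need at least 2 timepoints in the analysis interval")

    df["group"] = df["group"].astype(str)
    formula = f"{value_col} ~ t_rel_s * C(group)"
    singular = False
    note = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["animal_id"])
        result = model.fit(reml=reml)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            singular = True
            note = str(w.message)

    params = result.params
    interaction = [k for k in params.index if k.startswith("t_rel_s:")]
    if not interaction:
        raise RuntimeError("interaction term missing from the fitted model")
    inter_key = interaction[0]
    re_var = float(np.asarray(result.cov_re)[0, 0])
    if re_var < 1e-12:
        singular = True
        note = note or "random-intercept variance estimated at the boundary (~0)"

    fixed = {k: float(params[k]) for k in params.index if k != "Group Var"}
    return LMEFit(
        fixed_effects=fixed,
        std_errors={k: float(result.bse[k]) for k in fixed},
        pvalues={k: float(result.pvalues[k]) for k in fixed},
        random_intercept_var=re_var,
        anova_pvalues={
            "time": float(result.pvalues["t_rel_s"]),
            "time_by_group": float(result.pvalues[inter_key]),
        },
        n_obs=int(len(df)),
        groups=groups,
        n_animals=int(n_animals),
        converged=bool(result.converged),
        singular=singular,
        note=note,
    )


@dataclass
class TwoGroupTest:
    """Outcome of the normality/variance-gated two-group comparison."""

    test_name: str
    statistic: float
    pvalue: float
    normal: tuple[bool, bool]
    equal_variance: bool | None


def per_timepoint_test(values_g1, values_g2, alpha: float = 0.05) -> TwoGroupTest:
    """t test when both groups look normal with equal variance, otherwise
    Mann-Whitney.  Requires at least 3 values per group."""
    a = np.asarray(values_g1, dtype=float)
    b = np.asarray(values_g2, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")

    def _looks_normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False
        return sstats.shapiro(v).pvalue > alpha

    na, nb = _looks_normal(a), _looks_normal(b)
    equal_var: bool | None = None
    if na and nb:
        equal_var = bool(sstats.levene(a, b, center="median").pvalue > alpha)
        if equal_var:
            t, p = sstats.ttest_ind(a, b, equal_var=True)
            return TwoGroupTest("t", float(t), float(p), (na, nb), equal_var)
    u, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
    return TwoGroupTest("mann-whitney", float(u), float(p), (na, nb), equal_var)


def recovery_slope(
    series,
    t_from_s: float = 30.0,
    t_to_s: float = 180.0,
    use: str = "normalized",
) -> float:
    """OLS slope (per second) of the series over [t_from_s, t_to_s].

    ``series`` is a FeatureSeries (using its ``normalized`` values by
    default, ``use="values"`` for absolute mV) or a ``(times, values)``
    pair.  Only valid, finite points inside the interval contribute;
    excluded segments are simply absent, never interpolated.
    """
    if isinstance(series, FeatureSeries):
        t = series.times_rel_s
        v = series.normalized if use == "normalized" else series.values_mV
        if v is None:
            raise ValueError("series has no normalized values; normalize first")
        mask = series.valid_mask
    else:
        t, v = series
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        mask = np.ones_like(t, dtype=bool)
    sel = mask & np.isfinite(v) & (t >= t_from_s) & (t <= t_to_s)
    if sel.sum() < 2 or np.unique(t[sel]).size < 2:
        raise ValueError("need at least 2 valid points in the slope interval")
    return float(np.polyfit(t[sel], v[sel], 1)[0])


def simulate_long_table(
    n_per_group: tuple[int, int] = (8, 8),
    slopes: tuple[float, float] = (0.0, 0.0),
    intercepts: tuple[float, float] = (1.0, 1.0),
    t_grid: np.ndarray | None = None,
    n_animals: int = 5,
    animal_sd: float = 0.1,
    resid_sd: float = 0.1,
    group_names: tuple[str, str] = ("A", "B"),
    seed: int = 0,
) -> pd.DataFrame:
    """Lightweight long-table generator for calibration and power studies.

    Each lesion contributes one value per grid time:
    ``intercept_g + animal_effect + slope_g * t + noise`` with a normal
    per-animal intercept (sd ``animal_sd``) shared by all lesions of an
    animal, matching the structure :func:`fit_lme` assumes.  Lesions are
    assigned to animals round-robin.
    """
    rng = np.random.default_rng(seed)
    if t_grid is None:
        t_grid = np.arange(35.0, 176.0, 10.0)
    animal_eff = rng.normal(0.0, animal_sd, n_animals)
    rows = []
    lesion = 0
    for g, (n_g, slope, icpt) in enumerate(zip(n_per_group, slopes, intercepts)):
        for _ in range(n_g):
            animal = lesion % n_animals
            noise = rng.normal(0.0, resid_sd, len(t_grid))
            for t, e in zip(t_grid, noise):
                rows.append(
                    {
                        "lesion_id": f"lesion-{lesion:03d}",
                        "animal_id": f"animal-{animal}",
                        "group": group_names[g],
                        "t_rel_s": float(t),
                        "normalized": icpt + animal_eff[animal] + slope * t + e,
                    }
                )
            lesion += 1
    return pd.DataFrame(rows)
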