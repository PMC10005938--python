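"""Cohort-description statistics for the demographics tables.

Continuous variables are screened for normality (Shapiro-Wilk at
alpha = 0.05) to choose the summary style (mean +/- SD vs median [IQR])
and the test; non-normal continuous variables use Kruskal-Wallis and
categorical variables use chi-square — with Yates continuity correction
on 2x2 tables only, Pearson's statistic otherwise.  Pairwise subgroup
contrasts are reported with raw (unadjusted) p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DemographicsError(ValueError):
    pass


@dataclass
class GroupComparisonResult:
    variable: str
    groups: tuple[str, ...]
    test: str                      # "KW" or "chi2"
    statistic: float
    df: int
    p: float
    summaries: dict[str, str] = field(default_factory=dict)


def chi_square(table, variable: str = "", groups: tuple[str, ...] = ()) -> GroupComparisonResult:
    """Chi-square test of independence on a contingency table.

    2x2 tables get the Yates continuity correction; larger tables use
    the plain Pearson statistic.  Rows/columns are category levels.
    """
    arr = np.asarray(table, float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DemographicsError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise DemographicsError("counts must be non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DemographicsError("zero marginal in contingency table")
    correction = arr.shape == (2, 2)
    res = stats.chi2_contingency(arr, correction=correction)
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return GroupComparisonResult(
        variable=variable, groups=groups, test="chi2",
        statistic=float(res.statistic), df=df, p=float(res.pvalue),
    )


def kruskal_wallis(groups_values: dict[str, np.ndarray],
                   variable: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis H with tie correction, chi-square approximation."""
    names = tuple(groups_values)
    samples = [np.asarray(v, float) for v in groups_values.values()]
    if len(samples) < 2:
        raise DemographicsError("Kruskal-Wallis needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise DemographicsError("empty group in Kruskal-Wallis")
    if len(np.unique(np.concatenate(samples))) < 2:
        raise DemographicsError("all values identical")
    h, p = stats.kruskal(*samples)
    summaries = {
        n: f"{np.median(s):.2f} [{np.percentile(s, 25):.2f}, {np.percentile(s, 75):.2f}]"
        for n, s in zip(names, samples)
    }
    return GroupComparisonResult(
        variable=variable, groups=names, test="KW", statistic=float(h),
        df=len(samples) - 1, p=float(p), summaries=summaries,
    )


def normality_screen(values, alpha: float = 0.05) -> str:
    """Shapiro-Wilk screen; returns "normal" or "non-normal"."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise DemographicsError("normality screen needs at least 3 values")
    if np.ptp(v) == 0:
        warnings.warn("constant sample: treated as non-normal", stacklevel=2)
        return "non-normal"
    _, p = stats.shapiro(v)
    return "normal" if p > alpha else "non-normal"


CONTINUOUS_VARS = ("age", "panss_neg", "panss_pos", "age_onset", "duration", "cpz")
CATEGORICAL_VARS = ("sex", "handedness", "ap_user", "lithium_user", "ad_user", "ae_user")


def _counts(series_by_group: dict[str, pd.Series]) -> np.ndarray | None:
    levels = sorted(set().union(*[set(s.dropna().unique()) for s in series_by_group.values()]))
    if len(levels) < 2:
        return None
    table = np.array([
        [(s == lev).sum() for s in series_by_group.values()] for lev in levels
    ])
    return table[:, table.sum(axis=0) > 0]


def build_demographics_table(participants: pd.DataFrame,
                             grouping: str = "diagnosis",
                             pairwise: bool = True) -> pd.DataFrame:
    """One test per variable across groups, plus pairwise subgroup contrasts.

    ``grouping`` is "diagnosis" (CTR vs EOP) or "subgroup" (CTR, EOS,
    AFP, OTP).  Clinical variables are compared across case subgroups
    only (controls carry no clinical data).  Failures on individual
    variables are warned about and skipped.
    """
    if grouping not in ("diagnosis", "subgroup"):
        raise DemographicsError(f"unknown grouping {grouping!r}")
    col = grouping
    levels = [g for g in (("CTR", "EOP") if grouping == "diagnosis"
                          else ("CTR", "EOS", "AFP", "OTP"))
              if (participants[col] == g).any()]
    rows = []

    def groups_for(var: str) -> list[str]:
        if var in ("age", "sex", "handedness"):
            return levels
        return [g for g in levels if g != "CTR" and g != "EOP"] or (
            ["EOP"] if grouping == "diagnosis" else []
        )

    def run(var: str, use_levels: list[str], label: str) -> None:
        try:
            sub = {g: participants.loc[participants[col] == g, var]
                   for g in use_levels}
            if var in CONTINUOUS_VARS:
                samples = {g: s.dropna().to_numpy(float) for g, s in sub.items()}
                samples = {g: s for g, s in samples.items() if s.size > 0}
                if len(samples) < 2:
                    return
                res = kruskal_wallis(samples, variable=var)
            else:
                table = _counts(sub)
                if table is None or table.shape[1] < 2:
                    return
                res = chi_square(table, variable=var, groups=tuple(sub))
            rows.append({
                "variable": var, "comparison": label, "test": res.test,
                "statistic": res.statistic, "df": res.df, "p": res.p,
            })
        except DemographicsError as exc:
            warnings.warn(f"{var} ({label}): {exc}", stacklevel=2)

    for var in CONTINUOUS_VARS + CATEGORICAL_VARS:
        use = groups_for(var)
        if grouping == "diagnosis" and var not in ("age", "sex", "handedness"):
            continue  # clinical vars are case-only; no two-group contrast
        if len(use) >= 2:
            run(var, use, "overall")
        if pairwise and grouping == "subgroup":
            sub_levels = [g for g in use if g != "CTR"]
            for i, a in enumerate(sub_levels):
                for b in sub_levels[i + 1:]:
                    run(var, [a, b], f"{a} vs {b}")
    return pd.DataFrame(rows)
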