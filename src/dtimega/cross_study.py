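"""Comparing effect-size profiles between two case-control studies.

Two complementary procedures for a pair of per-tract Cohen's d tables
(e.g., an adolescent cohort vs a published adult reference):

* a per-tract z-test on the difference of effect sizes,

      Diff    = M_B - M_A
      SE_Diff = sqrt(V_MA + V_MB)
      Z_Diff  = Diff / SE_Diff
      p       = 2 * [1 - Phi(|Z_Diff|)],

  where M_A, M_B are the two studies' d values and V_MA, V_MB their
  squared standard errors;

* the Pearson correlation of the two d profiles across tracts, with a
  t-based two-sided p at n - 2 degrees of freedom.

The comparator study's values are user-supplied (CSV with columns
``roi, d, se``); tract matching is by canonical abbreviation and
order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ComparisonError(ValueError):
    pass


@dataclass
class ZComparison:
    tract: str
    m_a: float
    m_b: float
    v_ma: float
    v_mb: float
    diff: float
    se_diff: float
    z: float
    p: float


@dataclass
class ProfileCorrelation:
    n: int
    r: float
    t: float
    df: int
    p: float


def z_difference(m_a: float, se_a: float, m_b: float, se_b: float,
                 tract: str = "") -> ZComparison:
    """Two-tailed z-test for the difference between two effect sizes."""
    if se_a <= 0 or se_b <= 0:
        raise ComparisonError("standard errors must be > 0")
    v_ma, v_mb = se_a**2, se_b**2
    diff = m_b - m_a
    se_diff = float(np.sqrt(v_ma + v_mb))
    z = diff / se_diff
    # 2*[1 - Phi(|z|)] via the survival function; floored at the
    # smallest positive float so p stays in (0, 1] for extreme z
    p = float(max(2.0 * stats.norm.sf(abs(z)), 5e-324))
    return ZComparison(tract=tract, m_a=m_a, m_b=m_b, v_ma=v_ma, v_mb=v_mb,
                       diff=diff, se_diff=se_diff, z=float(z), p=p)


def profile_correlation(d_a, d_b) -> ProfileCorrelation:
    """Pearson correlation of two matched effect-size vectors."""
    d_a = np.asarray(d_a, float)
    d_b = np.asarray(d_b, float)
    if d_a.shape != d_b.shape:
        raise ComparisonError("effect-size vectors differ in length")
    n = d_a.size
    if n < 3:
        raise ComparisonError("need at least 3 matched tracts")
    if np.std(d_a) == 0 or np.std(d_b) == 0:
        raise ComparisonError("zero variance in an effect-size vector")
    r = float(np.corrcoef(d_a, d_b)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        r = float(np.clip(r, -1.0, 1.0))
        return ProfileCorrelation(n=n, r=r, t=np.inf if r > 0 else -np.inf,
                                  df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ProfileCorrelation(n=n, r=r, t=float(t), df=df, p=p)


def compare_profiles(study_a: pd.DataFrame, study_b: pd.DataFrame,
                     tracts: list[str] | None = None) -> tuple[pd.DataFrame, ProfileCorrelation]:
    """Match two per-tract effect tables and run both procedures.

    Each table needs columns ``roi``, ``d``, ``se``.  Tracts are matched
    by label regardless of row order; ``tracts`` optionally restricts
    the comparison to a subset.  Returns the per-tract z-test table and
    the profile correlation over the matched set.
    """
    for name, tab in (("A", study_a), ("B", study_b)):
        missing = {"roi", "d", "se"} - set(tab.columns)
        if missing:
            raise ComparisonError(f"study {name}: missing columns {sorted(missing)}")
    merged = study_a.merge(study_b, on="roi", suffixes=("_a", "_b"))
    if tracts is not None:
        merged = merged[merged["roi"].isin(tracts)]
    if merged.empty:
        raise ComparisonError("no matching tracts between the two studies")
    rows = []
    for _, row in merged.iterrows():
        zc = z_difference(row["d_a"], row["se_a"], row["d_b"], row["se_b"],
                          tract=row["roi"])
        rows.append({
            "roi": zc.tract, "d_a": zc.m_a, "d_b": zc.m_b,
            "diff": zc.diff, "se_diff": zc.se_diff, "z": zc.z, "p": zc.p,
        })
    corr = profile_correlation(merged["d_a"].to_numpy(), merged["d_b"].to_numpy())
    return pd.DataFrame(rows), corr
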