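"""Random-effects meta-analysis of per-site effect sizes.

Complements the mega-analysis (pooled subject-level fits): each
sufficiently large site is fitted separately and the per-site Cohen's d
values are pooled by inverse-variance weighting.  Between-site variance
tau^2 uses the DerSimonian-Laird moment estimator

    tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w)),

with Q the fixed-effect heterogeneity statistic and w = 1/v the
fixed-effect weights; I^2 = max(0, (Q - (k - 1)) / Q).  Random-effects
weights are 1/(v + tau^2) and the 95% CI uses normal quantiles.  A
leave-one-out series flags sites whose omission flips significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effect_models import DesignSpec, fit_roi_model, _merge_tables
from .rois import N_ROI_TESTS, ROI_OUTCOMES


class MetaError(ValueError):
    pass


@dataclass
class MetaEstimate:
    k: int
    d_sites: np.ndarray
    v_sites: np.ndarray
    site_ids: list[str]
    fixed_d: float
    Q: float
    tau2: float
    I2: float
    pooled_d: float
    pooled_se: float
    ci_low: float
    ci_high: float
    p: float
    roi: str = ""
    metric: str = ""
    excluded_sites: dict[str, str] = field(default_factory=dict)


def meta_pool(d: np.ndarray, v: np.ndarray, site_ids: list[str] | None = None,
              method: str = "dl") -> MetaEstimate:
    """Pool per-site (d, v) pairs; v are squared standard errors.

    ``method`` is "dl" (DerSimonian-Laird, default) or "reml"
    (iterative restricted maximum likelihood).
    """
    d = np.asarray(d, float)
    v = np.asarray(v, float)
    if d.size == 0:
        raise MetaError("empty effect list")
    if d.shape != v.shape:
        raise MetaError("d and v must have equal length")
    if (v <= 0).any():
        raise MetaError("all variances must be > 0")
    site_ids = site_ids or [f"site{i}" for i in range(d.size)]
    k = d.size
    w = 1.0 / v
    fixed = float((w * d).sum() / w.sum())
    Q = float((w * (d - fixed) ** 2).sum())
    if k == 1:
        tau2, I2 = 0.0, 0.0
    elif method == "dl":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom)
        I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    elif method == "reml":
        tau2 = _reml_tau2(d, v)
        I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    else:
        raise MetaError(f"unknown method {method!r}")
    wr = 1.0 / (v + tau2)
    pooled = float((wr * d).sum() / wr.sum())
    se = float(np.sqrt(1.0 / wr.sum()))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(0.975)
    return MetaEstimate(
        k=k, d_sites=d, v_sites=v, site_ids=list(site_ids), fixed_d=fixed,
        Q=Q, tau2=float(tau2), I2=float(I2), pooled_d=pooled, pooled_se=se,
        ci_low=pooled - zq * se, ci_high=pooled + zq * se, p=p,
    )


def _reml_tau2(d: np.ndarray, v: np.ndarray, tol: float = 1e-8,
               max_iter: int = 200) -> float:
    tau2 = max(0.0, np.var(d, ddof=1) - v.mean())
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = (w * d).sum() / w.sum()
        num = (w**2 * ((d - mu) ** 2 - v)).sum() + (w**2 / w.sum()).sum() * tau2
        new = max(0.0, num / (w**2).sum())
        if abs(new - tau2) < tol:
            return float(new)
        tau2 = new
    return float(tau2)


def site_filter(participants: pd.DataFrame, min_per_group: int = 10,
                case_level: str = "EOP") -> list[str]:
    """Sites with at least ``min_per_group`` cases and controls."""
    group_col = "diagnosis" if case_level == "EOP" else "subgroup"
    out = []
    for site, grp in participants.groupby("site_id"):
        n_case = int((grp[group_col] == case_level).sum())
        n_ctrl = int((grp["diagnosis"] == "CTR").sum())
        if n_case >= min_per_group and n_ctrl >= min_per_group:
            out.append(site)
    return sorted(out)


def site_effects(measures: pd.DataFrame, participants: pd.DataFrame,
                 roi: str, metric: str, min_per_group: int = 10,
                 case_level: str = "EOP") -> pd.DataFrame:
    """Per-site covariate-adjusted Cohen's d for one (roi, metric).

    Sites failing the minimum-size rule are excluded and listed with a
    reason; each included site is fitted with the full covariate set.
    """
    included = site_filter(participants, min_per_group, case_level)
    rows = []
    design = DesignSpec(group="diagnosis" if case_level == "EOP" else "subgroup")
    data_all = _merge_tables(measures, participants, roi, metric)
    for site, grp in data_all.groupby("site_id"):
        if site not in included:
            rows.append({"site_id": site, "included": False, "d": np.nan,
                         "v": np.nan,
                         "reason": f"fewer than {min_per_group} per group"})
            continue
        res = fit_roi_model(grp, roi, metric, design, case_level)
        rows.append({"site_id": site, "included": True, "d": res["d"],
                     "v": res["d_se"] ** 2, "reason": ""})
    return pd.DataFrame(rows)


def leave_one_out(d: np.ndarray, v: np.ndarray, site_ids: list[str],
                  alpha: float = 0.05 / N_ROI_TESTS,
                  method: str = "dl") -> pd.DataFrame:
    """k re-poolings, each omitting one site.

    A site is flagged influential when dropping it flips the pooled
    estimate's significance at ``alpha`` relative to the full pooling.
    """
    d = np.asarray(d, float)
    v = np.asarray(v, float)
    if d.size < 2:
        raise MetaError("leave-one-out requires at least two sites")
    full = meta_pool(d, v, site_ids, method)
    full_sig = full.p <= alpha
    rows = []
    for i in range(d.size):
        mask = np.ones(d.size, bool)
        mask[i] = False
        sub = meta_pool(d[mask], v[mask],
                        [s for j, s in enumerate(site_ids) if j != i], method)
        rows.append({
            "omitted_site": site_ids[i], "pooled_d": sub.pooled_d,
            "pooled_se": sub.pooled_se, "tau2": sub.tau2, "I2": sub.I2,
            "p": sub.p, "influential": bool((sub.p <= alpha) != full_sig),
        })
    return pd.DataFrame(rows)


def run_meta_battery(measures: pd.DataFrame, participants: pd.DataFrame,
                     alpha: float = 0.05, min_per_group: int = 10,
                     method: str = "dl") -> pd.DataFrame:
    """Pooled random-effects d per (roi, metric) across eligible sites."""
    metrics = sorted(measures["metric"].unique())
    alpha_per_test = alpha / N_ROI_TESTS
    rows = []
    for metric in metrics:
        for roi in ROI_OUTCOMES:
            try:
                se_tab = site_effects(measures, participants, roi, metric,
                                      min_per_group)
            except Exception as exc:  # propagate per-cell, continue others
                warnings.warn(f"meta {roi}/{metric}: {exc}", stacklevel=2)
                continue
            inc = se_tab[se_tab["included"]]
            if inc.empty:
                warnings.warn(
                    f"meta {roi}/{metric}: no site meets the size rule; skipped",
                    stacklevel=2,
                )
                continue
            est = meta_pool(inc["d"].to_numpy(), inc["v"].to_numpy(),
                            inc["site_id"].tolist(), method)
            rows.append({
                "roi": roi, "metric": metric, "k": est.k,
                "pooled_d": est.pooled_d, "pooled_se": est.pooled_se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "Q": est.Q, "tau2": est.tau2, "I2": est.I2, "p": est.p,
                "significant": bool(est.p <= alpha_per_test),
                "excluded_sites": ";".join(
                    se_tab.loc[~se_tab["included"], "site_id"]
                ),
            })
    return pd.DataFrame(rows)
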