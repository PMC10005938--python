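"""Covariate-adjusted case-control regression battery with Cohen's d.

Every analysis is an ordinary least-squares fit per (ROI, metric) with
the regional DTI value as outcome.  The main battery covaries for
centered age, age^2, sex, age-by-sex and age^2-by-sex; sex-stratified
models use age and age^2 only; the age-at-onset clinical model adjusts
for sex only (age and onset are strongly collinear in an adolescent
cohort).  Group contrasts are oriented control-minus-case: the group
regressor is 1 for controls and 0 for the case group, so lower FA in
cases prints as positive d.

Cohen's d is derived from the contrast t-statistic,

    d  = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df)),
    SE(d) = sqrt((n1 + n2) / (n1 * n2) + d^2 / (2 (n1 + n2))),

with df the residual degrees of freedom; as df -> n1 + n2 this reduces
to the classical two-sample d.  Significance uses a Bonferroni
threshold of alpha divided by the number of regional outcomes tested
per metric (0.05 / 25 = 0.002 at the defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rois import (
    AVERAGE,
    CORE,
    N_ROI_TESTS,
    PERIPHERY,
    ROI_OUTCOMES,
    SKELETON_SUMMARIES,
    V_CORE,
    V_PERIPHERY,
    V_TOTAL,
)

FULL_COVARIATES = ("age", "age2", "sex", "age_x_sex", "age2_x_sex")
RESULT_COLUMNS = [
    "roi", "metric", "contrast", "coef", "t", "df", "n1", "n2",
    "d", "d_se", "p", "significant",
]


class ModelError(RuntimeError):
    pass


@dataclass
class DesignSpec:
    """Declarative description of one regression design."""

    group: str = "diagnosis"            # "diagnosis", "subgroup" or a clinical var
    covariates: tuple[str, ...] = FULL_COVARIATES
    stratum: dict[str, str] | None = None   # e.g. {"sex": "M"}
    center: bool = True
    interaction: str | None = None      # "sex_x_dx" or "age_x_dx"
    adjust_summary: str | None = None   # "average", "core" or "periphery"


def cohens_d_from_t(t: float, n1: int, n2: int, df: float) -> tuple[float, float]:
    """Cohen's d and its SE from a regression t-statistic."""
    d = t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df))
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return float(d), float(se)


def t_from_cohens_d(d: float, n1: int, n2: int, df: float) -> float:
    """Inverse of :func:`cohens_d_from_t`."""
    return float(d * np.sqrt(n1 * n2) * np.sqrt(df) / (n1 + n2))


def _covariate_columns(part: pd.DataFrame, covariates: tuple[str, ...],
                       center: bool) -> tuple[np.ndarray, list[str]]:
    """Continuous covariates are mean-centered (within the analysis
    sample) when ``center`` is set; age^2 is the square of centered age."""
    age = part["age"].to_numpy(float)
    age_c = age - age.mean() if center else age
    sex = (part["sex"] == "F").to_numpy(float)
    available = {
        "age": age_c,
        "age2": age_c**2,
        "sex": sex,
        "age_x_sex": age_c * sex,
        "age2_x_sex": age_c**2 * sex,
    }
    cols, names = [], []
    for c in covariates:
        if c not in available:
            raise ModelError(f"unknown covariate {c!r}")
        cols.append(available[c])
        names.append(c)
    x = np.column_stack(cols) if cols else np.empty((len(part), 0))
    return x, names


def _ols_t(y: np.ndarray, x: np.ndarray, term: int) -> tuple[float, float, float, float]:
    """OLS fit; returns (coef, t, df, p) for column ``term`` of ``x``."""
    n, p = x.shape
    df = n - p
    if df < 5:
        raise ModelError(f"insufficient residual df ({df})")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # identify offending columns for the error message
        keep, bad = [], []
        for j in range(p):
            trial = x[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(j)
        raise ModelError(f"rank-deficient design; collinear column indices {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    s2 = resid @ resid / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(s2 * xtx_inv[term, term])
    coef = beta[term]
    t = coef / se
    p_val = 2.0 * stats.t.sf(abs(t), df)
    return float(coef), float(t), float(df), float(p_val)


def _merge_tables(measures: pd.DataFrame, participants: pd.DataFrame,
                  roi: str, metric: str) -> pd.DataFrame:
    vals = measures[(measures["roi"] == roi) & (measures["metric"] == metric)]
    merged = participants.merge(
        vals[["subject_id", "value"]], on="subject_id", how="inner"
    )
    return merged.dropna(subset=["value"])


def fit_roi_model(data: pd.DataFrame, roi: str, metric: str,
                  design: DesignSpec, case_level: str = "EOP",
                  alpha_per_test: float = 0.05 / N_ROI_TESTS) -> dict:
    """Fit one design for one (roi, metric); returns a result row.

    ``data`` must hold participant columns plus a ``value`` column.
    For group designs the contrast is control-minus-case.
    """
    part = data
    if design.stratum:
        for col, level in design.stratum.items():
            part = part[part[col] == level]
        if len(part) == 0:
            raise ModelError(f"empty stratum {design.stratum}")
    group_col = "diagnosis" if design.group == "diagnosis" else "subgroup"
    if design.group in ("diagnosis", "subgroup"):
        part = part[(part[group_col] == case_level) | (part[group_col] == "CTR")]
    n1 = int((part[group_col] == case_level).sum())
    n2 = int((part[group_col] == "CTR").sum())
    if min(n1, n2) < 3:
        raise ModelError(
            f"{roi}/{metric}: contrast {case_level} has group sizes {n1}/{n2}"
        )
    ctrl = (part[group_col] == "CTR").to_numpy(float)
    x_cov, names = _covariate_columns(part, design.covariates, design.center)
    cols = [np.ones(len(part)), ctrl]
    col_names = ["intercept", "ctrl"]
    if design.interaction == "sex_x_dx":
        cols.append(ctrl * (part["sex"] == "F").to_numpy(float))
        col_names.append("ctrl_x_sex")
    elif design.interaction == "age_x_dx":
        age = part["age"].to_numpy(float)
        age_c = age - age.mean() if design.center else age
        cols.append(ctrl * age_c)
        col_names.append("ctrl_x_age")
    if design.adjust_summary:
        cols.append(part["_summary"].to_numpy(float))
        col_names.append(f"adjust_{design.adjust_summary}")
    x = np.column_stack(cols + [x_cov]) if x_cov.size else np.column_stack(cols)
    term = col_names.index("ctrl") if design.interaction is None else (
        col_names.index("ctrl_x_sex") if design.interaction == "sex_x_dx"
        else col_names.index("ctrl_x_age")
    )
    y = part["value"].to_numpy(float)
    if len(y) < x.shape[1] + 5:
        raise ModelError(f"{roi}/{metric}: outcome present for too few subjects")
    coef, t, df, p = _ols_t(y, x, term)
    d, d_se = cohens_d_from_t(t, n1, n2, df)
    label = (f"CTR-{case_level}" if design.interaction is None
             else f"{design.interaction}:{case_level}")
    return {
        "roi": roi, "metric": metric, "contrast": label, "coef": coef,
        "t": t, "df": df, "n1": n1, "n2": n2, "d": d, "d_se": d_se, "p": p,
        "significant": bool(p <= alpha_per_test),
    }


def _battery(measures: pd.DataFrame, participants: pd.DataFrame,
             design: DesignSpec, case_levels: tuple[str, ...],
             alpha: float, outcomes: tuple[str, ...] = ROI_OUTCOMES,
             summary_by_metric: pd.DataFrame | None = None) -> pd.DataFrame:
    metrics = sorted(measures["metric"].unique())
    alpha_per_test = alpha / len(outcomes)
    rows, failures = [], []
    for metric in metrics:
        for roi in outcomes:
            data = _merge_tables(measures, participants, roi, metric)
            if data.empty:
                continue
            if design.adjust_summary is not None:
                summ = summary_by_metric[summary_by_metric["metric"] == metric]
                data = data.merge(
                    summ[["subject_id", "_summary"]], on="subject_id", how="inner"
                )
            for level in case_levels:
                try:
                    rows.append(
                        fit_roi_model(data, roi, metric, design, level,
                                      alpha_per_test)
                    )
                except ModelError as exc:
                    failures.append(f"{roi}/{metric}/{level}: {exc}")
    if failures:
        warnings.warn(
            f"{len(failures)} model(s) skipped: " + "; ".join(failures[:5]),
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_case_control_battery(measures: pd.DataFrame, participants: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """CTR vs EOP across the 25 regional outcomes per metric."""
    return _battery(measures, participants, DesignSpec(), ("EOP",), alpha)


def run_subgroup_battery(measures: pd.DataFrame, participants: pd.DataFrame,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Each diagnostic subgroup (EOS/AFP/OTP) vs CTR, full covariates."""
    present = [g for g in ("EOS", "AFP", "OTP")
               if (participants["subgroup"] == g).sum() >= 3]
    skipped = set(("EOS", "AFP", "OTP")) - set(present)
    if skipped:
        warnings.warn(f"subgroups skipped (n < 3): {sorted(skipped)}", stacklevel=2)
    design = DesignSpec(group="subgroup")
    return _battery(measures, participants, design, tuple(present), alpha)


def run_interaction_models(measures: pd.DataFrame, participants: pd.DataFrame,
                           which: str, alpha: float = 0.05,
                           group: str = "diagnosis") -> pd.DataFrame:
    """Sex-by-diagnosis or age-by-diagnosis interaction battery.

    The base covariates are retained; the reported term is the
    interaction of the control indicator with sex (F=1) or centered age.
    """
    if which not in ("sex_x_dx", "age_x_dx"):
        raise ModelError(f"unknown interaction {which!r}")
    design = DesignSpec(group=group, interaction=which)
    levels = ("EOP",) if group == "diagnosis" else ("EOS", "AFP", "OTP")
    return _battery(measures, participants, design, levels, alpha)


def run_stratified_battery(measures: pd.DataFrame, participants: pd.DataFrame,
                           stratum: str, alpha: float = 0.05) -> pd.DataFrame:
    """Single-sex case-control battery, covaried for age and age^2 only."""
    if stratum not in ("F", "M"):
        raise ModelError(f"stratum must be 'F' or 'M', got {stratum!r}")
    if (participants["sex"] == stratum).sum() == 0:
        raise ModelError(f"empty stratum sex={stratum}")
    design = DesignSpec(covariates=("age", "age2"), stratum={"sex": stratum})
    return _battery(measures, participants, design, ("EOP",), alpha)


def run_global_adjusted_battery(measures: pd.DataFrame, participants: pd.DataFrame,
                                adjust: str, alpha: float = 0.05) -> pd.DataFrame:
    """Case-control battery additionally covaried for a skeleton summary.

    ``adjust`` is one of "average", "core", "periphery".  The chosen
    summary is excluded from the outcome list.
    """
    label = {"average": AVERAGE, "core": CORE, "periphery": PERIPHERY}.get(adjust)
    if label is None:
        raise ModelError(f"adjust must be average/core/periphery, got {adjust!r}")
    summ = measures[measures["roi"] == label][["subject_id", "metric", "value"]]
    if summ.empty:
        raise ModelError(f"summary measure {label!r} absent from input")
    summ = summ.rename(columns={"value": "_summary"})
    outcomes = tuple(r for r in ROI_OUTCOMES if r != label)
    design = DesignSpec(adjust_summary=adjust)
    return _battery(measures, participants, design, ("EOP",), alpha,
                    outcomes=outcomes, summary_by_metric=summ)


def derive_periphery(average, core, metric: str | None = None):
    """Periphery summary from the skeleton voxel-count identity.

    periphery = (V_total * average - V_core * core) / V_periphery, so
    that average * V_total == core * V_core + periphery * V_periphery
    exactly.  Raises for non-positive results on diffusivity metrics.
    """
    average = np.asarray(average, float)
    core = np.asarray(core, float)
    periphery = (V_TOTAL * average - V_CORE * core) / V_PERIPHERY
    if metric in ("MD", "RD", "AD") and np.any(periphery <= 0):
        raise ModelError(f"derived periphery non-positive for {metric}")
    if periphery.ndim == 0:
        return float(periphery)
    return periphery


CLINICAL_CONTINUOUS = ("duration", "age_onset", "panss_neg", "panss_pos", "cpz")
CLINICAL_BINARY = ("ap_user", "lithium_user", "ad_user", "ae_user")


def run_clinical_associations(measures: pd.DataFrame, participants: pd.DataFrame,
                              alpha: float = 0.05,
                              min_n: int = 20) -> pd.DataFrame:
    """Clinical-covariate associations within cases only.

    Continuous variables (illness duration, PANSS sub-scores, CPZ dose)
    enter as slopes with the full covariate set; age at onset is
    adjusted for sex only.  Medication flags are user-vs-non-user
    contrasts (user = 1, reported as non-user-minus-user so that lower
    values in users print as positive d).  Bonferroni is applied within
    each variable across the regional outcomes.
    """
    cases = participants[participants["diagnosis"] == "EOP"]
    metrics = sorted(measures["metric"].unique())
    alpha_per_test = alpha / N_ROI_TESTS
    rows, skipped = [], []
    for var in CLINICAL_CONTINUOUS + CLINICAL_BINARY:
        avail = cases.dropna(subset=[var])
        if len(avail) < min_n:
            skipped.append(var)
            continue
        covs = ("sex",) if var == "age_onset" else FULL_COVARIATES
        for metric in metrics:
            for roi in ROI_OUTCOMES:
                data = _merge_tables(measures, avail, roi, metric)
                if len(data) < min_n:
                    continue
                x_cov, _ = _covariate_columns(data, covs, center=True)
                if var in CLINICAL_BINARY:
                    nonuser = (data[var] == 0).to_numpy(float)
                    x = np.column_stack([np.ones(len(data)), nonuser, x_cov])
                    n1 = int((data[var] == 1).sum())
                    n2 = int((data[var] == 0).sum())
                    if min(n1, n2) < 3:
                        continue
                    try:
                        coef, t, df, p = _ols_t(data["value"].to_numpy(float), x, 1)
                    except ModelError:
                        continue
                    d, d_se = cohens_d_from_t(t, n1, n2, df)
                    label = f"{var}:nonuser-user"
                else:
                    v = data[var].to_numpy(float)
                    v_c = v - v.mean()
                    x = np.column_stack([np.ones(len(data)), v_c, x_cov])
                    n1 = n2 = len(data)
                    try:
                        coef, t, df, p = _ols_t(data["value"].to_numpy(float), x, 1)
                    except ModelError:
                        continue
                    d, d_se = np.nan, np.nan
                    label = f"{var}:slope"
                rows.append({
                    "roi": roi, "metric": metric, "contrast": label,
                    "coef": coef, "t": t, "df": df, "n1": n1, "n2": n2,
                    "d": d, "d_se": d_se, "p": p,
                    "significant": bool(p <= alpha_per_test),
                })
    if skipped:
        warnings.warn(
            f"clinical variables skipped (fewer than {min_n} non-missing): {skipped}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
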