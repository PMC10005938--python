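"""Parametric empirical-Bayes ComBat harmonization of ROI measures.

Removes site/scanner location-and-scale effects from multi-site ROI
data while preserving the modelled biological covariates (age, sex,
diagnostic subgroup).  The model per feature g (an ROI within a metric)
and site i is

    y_ijg = alpha_g + x_ij' beta_g + gamma_ig + delta_ig * eps_ijg,

with eps ~ N(0, sigma_g^2).  Sites share information through empirical-
Bayes priors: gamma_ig ~ N(gamma_bar_i, tau_i^2) and delta_ig^2 ~
inverse-gamma(lambda_i, theta_i), with hyperparameters estimated by the
method of moments across features within each site.  Conditional
posterior means gamma*_ig, delta*^2_ig are iterated to convergence and
used to adjust the standardized data:

    y_adj = sigma_g * (z_ijg - gamma*_ig) / delta*_ig + alpha_g + x_ij' beta_g.

Each metric is fitted independently, using only the sites that provide
it, so a cohort in which one site contributes FA only harmonizes
without touching that site's (absent) diffusivity records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_COVARIATES = ("age", "sex", "subgroup")


class HarmonizationError(RuntimeError):
    pass


def _covariate_matrix(participants: pd.DataFrame,
                      covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Biological design columns (no intercept). sex F=1/M=0; subgroup
    one-hot with CTR as reference."""
    cols, names = [], []
    for cov in covariates:
        if cov == "age":
            cols.append(participants["age"].to_numpy(float))
            names.append("age")
        elif cov == "sex":
            cols.append((participants["sex"] == "F").to_numpy(float))
            names.append("sexF")
        elif cov == "subgroup":
            for level in ("EOS", "AFP", "OTP"):
                cols.append((participants["subgroup"] == level).to_numpy(float))
                names.append(f"subgroup[{level}]")
        elif cov == "diagnosis":
            cols.append((participants["diagnosis"] == "EOP").to_numpy(float))
            names.append("diagnosisEOP")
        else:
            raise HarmonizationError(f"unknown covariate {cov!r}")
    if not cols:
        return np.empty((len(participants), 0)), []
    return np.column_stack(cols), names


@dataclass
class MetricFit:
    """Fitted ComBat parameters for one DTI metric."""

    metric: str
    features: list[str]                 # ROI labels, fixed order
    sites: list[str]
    n_per_site: np.ndarray              # (S,)
    covariate_names: list[str]
    grand_mean: np.ndarray              # (G,) alpha per feature
    beta: np.ndarray                    # (p, G) covariate coefficients
    sigma2: np.ndarray                  # (G,) pooled residual variance
    gamma_hat: np.ndarray               # (S, G) raw site locations
    delta2_hat: np.ndarray              # (S, G) raw site scales
    gamma_star: np.ndarray              # (S, G) EB posterior locations
    delta2_star: np.ndarray             # (S, G) EB posterior scales
    gamma_bar: np.ndarray               # (S,) prior mean per site
    tau2: np.ndarray                    # (S,) prior variance per site
    lambda_: np.ndarray                 # (S,) inverse-gamma shape
    theta: np.ndarray                   # (S,) inverse-gamma scale
    n_iter: int = 0
    converged: bool = False
    # per-subject standardization pieces, so apply() needs no covariates
    subject_ids: list[str] = field(default_factory=list)
    stand_mean: np.ndarray | None = None  # (n, G) alpha + x'beta per subject
    site_of_subject: list[str] = field(default_factory=list)


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2.0 * s2 + m * m) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _fit_metric(y: np.ndarray, site_idx: np.ndarray, x_cov: np.ndarray,
                metric: str, features: list[str], sites: list[str],
                covariate_names: list[str], subject_ids: list[str],
                tol: float, max_iter: int, eb: bool = True) -> MetricFit:
    n, n_feat = y.shape
    n_sites = len(sites)
    if n_sites < 2:
        raise HarmonizationError(
            f"{metric}: harmonization undefined for one batch"
        )
    counts = np.bincount(site_idx, minlength=n_sites).astype(float)
    if (counts < 3).any():
        small = [sites[i] for i in np.where(counts < 3)[0]]
        raise HarmonizationError(
            f"{metric}: sites {small} have fewer than 3 subjects"
        )

    # least squares with all site indicators plus covariates; the grand
    # mean is the size-weighted average of the site intercepts, which
    # enforces the sum-to-zero constraint on gamma_hat.
    batch = np.zeros((n, n_sites))
    batch[np.arange(n), site_idx] = 1.0
    design = np.hstack([batch, x_cov])
    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_means = b_hat[:n_sites]                      # (S, G)
    grand_mean = (counts / n) @ site_means            # (G,)
    beta = b_hat[n_sites:]                            # (p, G)

    resid = y - design @ b_hat
    sigma2 = (resid**2).mean(axis=0)                  # (G,)
    if (sigma2 <= 0).any():
        bad = [features[g] for g in np.where(sigma2 <= 0)[0]]
        raise HarmonizationError(f"{metric}: zero residual variance in {bad}")

    stand_mean = grand_mean[None, :] + x_cov @ beta   # (n, G)
    z = (y - stand_mean) / np.sqrt(sigma2)[None, :]

    gamma_hat = site_means - grand_mean[None, :]
    gamma_hat = gamma_hat / np.sqrt(sigma2)[None, :]
    delta2_hat = np.vstack([
        z[site_idx == i].var(axis=0, ddof=1) for i in range(n_sites)
    ])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    lambda_ = np.array([_aprior(delta2_hat[i]) for i in range(n_sites)])
    theta = np.array([_bprior(delta2_hat[i]) for i in range(n_sites)])

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter, converged = 0, False
    if not eb:
        # plain location/scale adjustment: posterior = raw estimates
        converged = True
        return MetricFit(
            metric=metric, features=features, sites=sites, n_per_site=counts,
            covariate_names=covariate_names, grand_mean=grand_mean, beta=beta,
            sigma2=sigma2, gamma_hat=gamma_hat, delta2_hat=delta2_hat,
            gamma_star=gamma_star, delta2_star=delta2_star,
            gamma_bar=gamma_bar, tau2=tau2, lambda_=lambda_, theta=theta,
            n_iter=0, converged=True, subject_ids=subject_ids,
            stand_mean=stand_mean,
            site_of_subject=[sites[i] for i in site_idx],
        )
    for n_iter in range(1, max_iter + 1):
        g_old, d_old = gamma_star.copy(), delta2_star.copy()
        gamma_star = (
            counts[:, None] * tau2[:, None] * gamma_hat
            + delta2_star * gamma_bar[:, None]
        ) / (counts[:, None] * tau2[:, None] + delta2_star)
        sum2 = np.vstack([
            ((z[site_idx == i] - gamma_star[i][None, :]) ** 2).sum(axis=0)
            for i in range(n_sites)
        ])
        delta2_star = (0.5 * sum2 + theta[:, None]) / (
            counts[:, None] / 2.0 + lambda_[:, None] - 1.0
        )
        change = max(
            np.abs(gamma_star - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(delta2_star - d_old).max() / np.abs(d_old).max(),
        )
        if change <= tol:
            converged = True
            break
    if not converged:
        raise HarmonizationError(
            f"{metric}: EB iterations did not converge in {max_iter} steps "
            f"(last relative change {change:.3g})"
        )
    if (delta2_star <= 0).any():
        raise HarmonizationError(f"{metric}: non-positive posterior scale")

    return MetricFit(
        metric=metric, features=features, sites=sites, n_per_site=counts,
        covariate_names=covariate_names, grand_mean=grand_mean, beta=beta,
        sigma2=sigma2, gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta2_star=delta2_star, gamma_bar=gamma_bar,
        tau2=tau2, lambda_=lambda_, theta=theta, n_iter=n_iter,
        converged=converged, subject_ids=subject_ids, stand_mean=stand_mean,
        site_of_subject=[sites[i] for i in site_idx],
    )


@dataclass
class CombatFit:
    """ComBat fits for every metric present in the training data."""

    metric_fits: dict[str, MetricFit]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    tol: float = 1e-4
    max_iter: int = 1000

    def to_json(self, path: str | Path) -> None:
        def pack(mf: MetricFit) -> dict:
            d = {
                "metric": mf.metric, "features": mf.features, "sites": mf.sites,
                "covariate_names": mf.covariate_names, "n_iter": mf.n_iter,
                "converged": mf.converged, "subject_ids": mf.subject_ids,
                "site_of_subject": mf.site_of_subject,
            }
            for name in ("n_per_site", "grand_mean", "beta", "sigma2",
                         "gamma_hat", "delta2_hat", "gamma_star", "delta2_star",
                         "gamma_bar", "tau2", "lambda_", "theta", "stand_mean"):
                d[name] = np.asarray(getattr(mf, name)).tolist()
            return d

        payload = {
            "covariates": list(self.covariates), "tol": self.tol,
            "max_iter": self.max_iter,
            "metrics": {m: pack(mf) for m, mf in self.metric_fits.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombatFit":
        payload = json.loads(Path(path).read_text())
        fits = {}
        for m, d in payload["metrics"].items():
            arrays = {
                name: np.asarray(d[name])
                for name in ("n_per_site", "grand_mean", "beta", "sigma2",
                             "gamma_hat", "delta2_hat", "gamma_star",
                             "delta2_star", "gamma_bar", "tau2", "lambda_",
                             "theta", "stand_mean")
            }
            fits[m] = MetricFit(
                metric=d["metric"], features=d["features"], sites=d["sites"],
                covariate_names=d["covariate_names"], n_iter=d["n_iter"],
                converged=d["converged"], subject_ids=d["subject_ids"],
                site_of_subject=d["site_of_subject"], **arrays,
            )
        return cls(metric_fits=fits, covariates=tuple(payload["covariates"]),
                   tol=payload["tol"], max_iter=payload["max_iter"])


def _pivot(measures: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = measures[measures["metric"] == metric]
    wide = sub.pivot(index="subject_id", columns="roi", values="value")
    return wide.dropna(axis=0, how="any")


def fit_combat(measures: pd.DataFrame, participants: pd.DataFrame,
               covariates: tuple[str, ...] = DEFAULT_COVARIATES,
               tol: float = 1e-4, max_iter: int = 1000,
               eb: bool = True) -> CombatFit:
    """Fit ComBat per metric on a long ROI-measure table.

    ``covariates`` name the biological terms to preserve (default age,
    sex and 4-level diagnostic subgroup).  Requires at least two sites
    with at least three subjects each per metric.  ``eb=False`` skips
    the empirical-Bayes shrinkage and adjusts with the raw per-site
    location/scale estimates (exact removal, no pooling across ROIs).
    """
    part = participants.set_index("subject_id")
    fits: dict[str, MetricFit] = {}
    for metric in measures["metric"].unique():
        wide = _pivot(measures, metric)
        subs = wide.index.tolist()
        p = part.loc[subs]
        sites = sorted(p["site_id"].unique())
        site_idx = p["site_id"].map({s: i for i, s in enumerate(sites)}).to_numpy()
        x_cov, names = _covariate_matrix(p.reset_index(), covariates)
        fits[metric] = _fit_metric(
            wide.to_numpy(float), site_idx, x_cov, metric,
            wide.columns.tolist(), sites, names, subs, tol, max_iter, eb,
        )
    return CombatFit(metric_fits=fits, covariates=covariates, tol=tol,
                     max_iter=max_iter)


def apply_combat(fit: CombatFit, measures: pd.DataFrame) -> pd.DataFrame:
    """Adjust a long ROI-measure table with a fitted ComBat model.

    Subjects must have been present at fit time (their standardization
    means are stored in the fit); unseen subjects or sites raise.
    Output schema and row order match the input.
    """
    out_frames = []
    for metric in measures["metric"].unique():
        if metric not in fit.metric_fits:
            raise HarmonizationError(f"no fit available for metric {metric!r}")
        mf = fit.metric_fits[metric]
        wide = _pivot(measures, metric)
        unseen = set(wide.index) - set(mf.subject_ids)
        if unseen:
            raise HarmonizationError(
                f"{metric}: subjects not present at fit time: {sorted(unseen)[:5]}"
            )
        order = {s: i for i, s in enumerate(mf.subject_ids)}
        rows = [order[s] for s in wide.index]
        feats = mf.features
        y = wide[feats].to_numpy(float)
        stand_mean = mf.stand_mean[rows]
        site_idx = np.array(
            [mf.sites.index(mf.site_of_subject[r]) for r in rows]
        )
        sigma = np.sqrt(mf.sigma2)[None, :]
        z = (y - stand_mean) / sigma
        adj = (
            sigma * (z - mf.gamma_star[site_idx]) / np.sqrt(mf.delta2_star[site_idx])
            + stand_mean
        )
        wide_adj = pd.DataFrame(adj, index=wide.index, columns=feats)
        long = (
            wide_adj.reset_index()
            .melt(id_vars="subject_id", var_name="roi", value_name="value")
        )
        long.insert(1, "metric", metric)
        out_frames.append(long)
    out = pd.concat(out_frames, ignore_index=True)
    key = measures[["subject_id", "metric", "roi"]].copy()
    merged = key.merge(out, on=["subject_id", "metric", "roi"], how="left")
    result = measures.copy()
    result["value"] = merged["value"].to_numpy()
    return result


def site_effect_eta2(measures: pd.DataFrame, participants: pd.DataFrame,
                     covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Site-effect variance fraction per (roi, metric).

    eta^2 is the between-site share of variance in covariate-adjusted
    residuals (one-way decomposition), a scalar measure of how much
    scanner signal remains.
    """
    part = participants.set_index("subject_id")
    rows = []
    for metric in measures["metric"].unique():
        wide = _pivot(measures, metric)
        p = part.loc[wide.index]
        x_cov, _ = _covariate_matrix(p.reset_index(), covariates)
        x = np.hstack([np.ones((len(wide), 1)), x_cov])
        y = wide.to_numpy(float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        site = p["site_id"].to_numpy()
        ss_total = (resid**2).sum(axis=0)
        ss_between = np.zeros(resid.shape[1])
        for s in np.unique(site):
            r = resid[site == s]
            ss_between += len(r) * r.mean(axis=0) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            eta2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
        for j, roi in enumerate(wide.columns):
            rows.append({"roi": roi, "metric": metric, "eta2": float(eta2[j])})
    return pd.DataFrame(rows)


def _covariate_betas(measures: pd.DataFrame, participants: pd.DataFrame,
                     covariates: tuple[str, ...]) -> pd.DataFrame:
    part = participants.set_index("subject_id")
    rows = []
    for metric in measures["metric"].unique():
        wide = _pivot(measures, metric)
        p = part.loc[wide.index]
        x_cov, names = _covariate_matrix(p.reset_index(), covariates)
        x = np.hstack([np.ones((len(wide), 1)), x_cov])
        y = wide.to_numpy(float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        dof = len(wide) - x.shape[1]
        resid = y - x @ beta
        s2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(x.T @ x)
        for k, name in enumerate(["intercept"] + names):
            for j, roi in enumerate(wide.columns):
                rows.append({
                    "roi": roi, "metric": metric, "term": name,
                    "beta": float(beta[k, j]),
                    "se": float(np.sqrt(s2[j] * xtx_inv[k, k])),
                })
    return pd.DataFrame(rows)


def harmonization_report(pre: pd.DataFrame, post: pd.DataFrame,
                         participants: pd.DataFrame,
                         covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric before/after summary: site-effect eta^2 and covariate drift.

    One row per (roi, metric) with pre/post eta^2 and, for each
    biological covariate, the absolute coefficient drift and its
    pre-fit standard error.
    """
    if set(pre["subject_id"]) != set(post["subject_id"]):
        raise HarmonizationError("report: pre and post tables cover different subjects")
    e_pre = site_effect_eta2(pre, participants, covariates).rename(
        columns={"eta2": "eta2_pre"}
    )
    e_post = site_effect_eta2(post, participants, covariates).rename(
        columns={"eta2": "eta2_post"}
    )
    report = e_pre.merge(e_post, on=["roi", "metric"])
    b_pre = _covariate_betas(pre, participants, covariates)
    b_post = _covariate_betas(post, participants, covariates)
    drift = b_pre.merge(b_post, on=["roi", "metric", "term"],
                        suffixes=("_pre", "_post"))
    drift = drift[drift["term"] != "intercept"].copy()
    drift["beta_drift"] = (drift["beta_pre"] - drift["beta_post"]).abs()
    wide_drift = drift.pivot(index=["roi", "metric"], columns="term",
                             values="beta_drift")
    wide_drift.columns = [f"drift[{c}]" for c in wide_drift.columns]
    wide_se = drift.pivot(index=["roi", "metric"], columns="term",
                          values="se_pre")
    wide_se.columns = [f"se_pre[{c}]" for c in wide_se.columns]
    report = report.merge(wide_drift.reset_index(), on=["roi", "metric"])
    report = report.merge(wide_se.reset_index(), on=["roi", "metric"])
    return report
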