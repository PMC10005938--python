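"""Synthetic multi-site adolescent case-control cohort generator.

Emulates the statistical structure of a nine-site diffusion-MRI
case-control study of early-onset psychosis (EOP): 321 cases split into
early-onset schizophrenia (EOS), affective psychosis (AFP) and other
psychosis (OTP) subgroups versus 265 healthy controls (CTR), aged 12-18,
with subgroup-specific sex imbalance, site-specific additive and
multiplicative scanner effects, developmental age/age^2/sex trajectories
in each DTI metric, subgroup-specific standardized case-control
differences, one site contributing FA only, and clinical covariates for
cases (PANSS sub-scores, chlorpromazine equivalents, illness duration,
age at onset, medication flags).

Values are generated directly at the ROI level; there is no image
domain.  For each subject and metric the generator writes 24 tract ROIs,
a core and a periphery skeleton summary, and the full-skeleton average
derived exactly from the voxel-count identity

    Average * V_total = Core * V_core + Periphery * V_periphery.

All randomness flows from ``CohortConfig.seed`` through a single
``numpy.random.Generator``; identical configs produce identical tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .rois import (
    AVERAGE,
    CORE,
    METRICS,
    PERIPHERY,
    ROI_OUTCOMES,
    TRACTS,
    V_CORE,
    V_PERIPHERY,
    V_TOTAL,
)

SUBGROUPS = ("CTR", "EOS", "AFP", "OTP")
CASE_SUBGROUPS = ("EOS", "AFP", "OTP")


class ConfigError(ValueError):
    """A cohort configuration violates an invariant; names the field."""


@dataclass
class SiteSpec:
    """Per-site sample sizes and scanner effects.

    ``additive_shift`` and ``scale_factor`` are per-metric scanner
    location and scale effects applied uniformly across ROIs (shift in
    the metric's units; scale multiplies the residual noise).
    """

    site_id: str
    n_cases: int
    n_controls: int
    additive_shift: dict[str, float] = field(default_factory=dict)
    scale_factor: dict[str, float] = field(default_factory=dict)
    metrics_available: tuple[str, ...] = METRICS
    field_strength: str = "3T"

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError(f"site {self.site_id}: negative sample size")
        if not self.metrics_available:
            raise ConfigError(f"site {self.site_id}: metrics_available empty")
        if "FA" not in self.metrics_available:
            raise ConfigError(f"site {self.site_id}: FA must be available")
        for m, s in self.scale_factor.items():
            if s <= 0:
                raise ConfigError(
                    f"site {self.site_id}: scale_factor[{m}] must be > 0"
                )


@dataclass
class ClinicalModel:
    """Distributions for case-only clinical covariates.

    Durations and doses are log-normal (parameterized by median and a
    log-scale sigma); PANSS sub-scores are shifted log-normals; onset is
    derived as age minus duration so the chronology is always coherent.
    Medication-use probabilities are per subgroup.
    """

    duration_median: dict[str, float] = field(
        default_factory=lambda: {"EOS": 1.00, "AFP": 0.21, "OTP": 0.62}
    )
    duration_sigma: float = 0.9
    panss_neg_median: dict[str, float] = field(
        default_factory=lambda: {"EOS": 18.0, "AFP": 14.0, "OTP": 15.0}
    )
    panss_pos_median: dict[str, float] = field(
        default_factory=lambda: {"EOS": 21.0, "AFP": 19.0, "OTP": 16.0}
    )
    panss_sigma: float = 0.35
    panss_floor: float = 7.0
    cpz_median: dict[str, float] = field(
        default_factory=lambda: {"EOS": 200.0, "AFP": 183.3, "OTP": 166.7}
    )
    cpz_sigma: float = 0.6
    med_prob: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ap_user": {"EOS": 0.90, "AFP": 0.90, "OTP": 0.88},
            "lithium_user": {"EOS": 0.018, "AFP": 0.33, "OTP": 0.0},
            "ad_user": {"EOS": 0.14, "AFP": 0.48, "OTP": 0.16},
            "ae_user": {"EOS": 0.065, "AFP": 0.042, "OTP": 0.0},
        }
    )
    panss_missing_sites: tuple[str, ...] = ()
    cpz_missing_rate: float = 0.12


def _default_effect_matrix() -> dict[str, dict[str, dict[str, float]]]:
    """Standardized case shifts (control-SD units) per subgroup/metric/ROI.

    Negative FA shifts encode lower anisotropy in cases; positive
    diffusivity shifts encode higher diffusivity.  The EOS subgroup
    carries most of the signal, AFP a mild global component, OTP none,
    mirroring the subgroup structure the pipeline is designed to detect.
    "Periphery" entries propagate a global skeleton-wide component.
    """
    eos_fa = {
        "SLF": -0.58, "PCR": -0.52, "SFO": -0.50, "CC": -0.46, "GCC": -0.44,
        "IC": -0.42, "PTR": -0.42, "RLIC": -0.40, "BCC": -0.40, "SCC": -0.38,
        "ALIC": -0.36, "CR": -0.36, "FXST": -0.34, "ACR": -0.26, "SCR": -0.26,
        "CGC": -0.24, "EC": -0.22, "SS": -0.22, "FX": -0.20, "CGH": -0.16,
        "IFO": -0.20, "UNC": -0.18, "PLIC": -0.20, "CST": -0.12,
        PERIPHERY: -0.30,
    }
    eos_rd = {
        "CC": 0.42, "CGC": 0.40, "FX": 0.44, "PCR": 0.46, "PTR": 0.40,
        "RLIC": 0.38, "SLF": 0.46, "SS": 0.38, "UNC": 0.30, "BCC": 0.30,
        "SCC": 0.30, "CR": 0.28, "GCC": 0.28, PERIPHERY: 0.28,
    }
    afp_fa = {t: -0.12 for t in TRACTS}
    afp_fa[PERIPHERY] = -0.10
    afp_rd = {t: 0.18 for t in TRACTS}
    afp_rd[PERIPHERY] = 0.20
    return {
        "EOS": {
            "FA": eos_fa,
            "RD": eos_rd,
            "MD": {"FX": 0.50, "UNC": 0.40},
            "AD": {"FX": 0.46},
        },
        "AFP": {"FA": afp_fa, "RD": afp_rd, "MD": {}, "AD": {}},
        "OTP": {"FA": {}, "RD": {}, "MD": {}, "AD": {}},
    }


@dataclass
class CohortConfig:
    """Everything the generator needs, including its seed.

    ``effect_matrix[subgroup][metric][roi]`` holds the standardized case
    shift in control-SD units (multiplied by ``noise_sd[metric]`` on
    generation).  ``age_coefficients[metric]`` are (linear, quadratic)
    slopes on centered age; ``sex_offset[metric]`` is added for females
    (coding F=1, M=0).
    """

    sites: list[SiteSpec]
    subgroup_sizes: dict[str, int] = field(
        default_factory=lambda: {"CTR": 265, "EOS": 180, "AFP": 95, "OTP": 46}
    )
    age_range: tuple[float, float] = (12.0, 18.0)
    age_mean: float = 16.3
    age_sd: float = 1.4
    sex_prob_by_group: dict[str, float] = field(
        default_factory=lambda: {
            "CTR": 153 / 265, "EOS": 70 / 180, "AFP": 54 / 95, "OTP": 25 / 46,
        }
    )
    roi_names: tuple[str, ...] = ROI_OUTCOMES + (CORE, PERIPHERY)
    metric_names: tuple[str, ...] = METRICS
    effect_matrix: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=_default_effect_matrix
    )
    # developmental trajectories (per year of centered age)
    age_coefficients: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "FA": (0.004, -0.0006),
            "MD": (-0.006, 0.0008),
            "RD": (-0.007, 0.0009),
            "AD": (-0.003, 0.0004),
        }
    )
    sex_offset: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.004, "MD": -0.004, "RD": -0.005, "AD": -0.002}
    )
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.46, "MD": 0.82, "RD": 0.62, "AD": 1.22}
    )
    baseline_spread: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.06, "MD": 0.05, "RD": 0.05, "AD": 0.07}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.025, "MD": 0.035, "RD": 0.040, "AD": 0.050}
    )
    latent_rho: float = 0.5  # shared within-subject factor across ROIs
    handedness_probs: tuple[float, float, float] = (0.90, 0.095, 0.005)
    handedness_missing_rate: float = 0.35
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    seed: int = 0

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if not self.sites:
            raise ConfigError("sites: at least one site required")
        for s in self.sites:
            s.validate()
        n_cases = sum(s.n_cases for s in self.sites)
        n_controls = sum(s.n_controls for s in self.sites)
        case_total = sum(self.subgroup_sizes.get(g, 0) for g in CASE_SUBGROUPS)
        if case_total != n_cases:
            raise ConfigError(
                "subgroup_sizes: case subgroup sizes sum to "
                f"{case_total}, sites provide {n_cases} cases"
            )
        if self.subgroup_sizes.get("CTR", 0) != n_controls:
            raise ConfigError(
                "subgroup_sizes: CTR count "
                f"{self.subgroup_sizes.get('CTR', 0)} != site controls {n_controls}"
            )
        for g, p in self.sex_prob_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"sex_prob_by_group[{g}]: {p} not in [0,1]")
        lo, hi = self.age_range
        if not (12.0 <= lo < hi <= 18.0):
            raise ConfigError(f"age_range: {self.age_range} outside [12, 18]")
        for m in self.metric_names:
            if self.noise_sd.get(m, 0.0) <= 0:
                raise ConfigError(f"noise_sd[{m}]: must be > 0")
        expected = set(ROI_OUTCOMES) | {CORE, PERIPHERY}
        if set(self.roi_names) != expected:
            raise ConfigError(
                "roi_names: must contain exactly the 25 regional outcomes "
                "plus the Core and Periphery summaries"
            )
        if not 0.0 <= self.latent_rho < 1.0:
            raise ConfigError(f"latent_rho: {self.latent_rho} not in [0,1)")


def default_study_config(seed: int = 0) -> CohortConfig:
    """Nine-site configuration matching the published sample structure.

    321 cases (180 EOS / 95 AFP / 46 OTP) and 265 controls across nine
    sites of unequal size; four sites have fewer than 10 participants in
    one diagnostic group (and so drop out of the meta-analysis under the
    default inclusion rule); exactly one site contributes FA only, so
    diffusivity metrics cover 505 of the 586 participants.  Site scanner
    effects are drawn once here, from N(0, (0.6*noise_sd)^2) for shifts
    and log-normal(0, 0.15) for scales, and stored explicitly on each
    ``SiteSpec`` so harmonization tests have ground truth.
    """
    # (site_id, n_cases, n_controls, FA-only?, field strength)
    layout = [
        ("S1", 70, 50, False, "3T"),
        ("S2", 65, 48, False, "3T"),
        ("S3", 56, 44, False, "1.5T"),
        ("S4", 50, 40, False, "3T"),
        ("S5", 45, 36, True, "1.5T"),   # FA only: 81 participants
        ("S6", 12, 9, False, "3T"),
        ("S7", 9, 15, False, "1.5T"),
        ("S8", 8, 12, False, "3T"),
        ("S9", 6, 11, False, "1.5T"),
    ]
    noise_sd = {"FA": 0.025, "MD": 0.035, "RD": 0.040, "AD": 0.050}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x517E]))
    sites = []
    for site_id, n_ca, n_co, fa_only, fs in layout:
        metrics = ("FA",) if fa_only else METRICS
        shift = {m: float(rng.normal(0.0, 0.6 * noise_sd[m])) for m in METRICS}
        scale = {m: float(np.exp(rng.normal(0.0, 0.15))) for m in METRICS}
        sites.append(
            SiteSpec(
                site_id=site_id,
                n_cases=n_ca,
                n_controls=n_co,
                additive_shift=shift,
                scale_factor=scale,
                metrics_available=metrics,
                field_strength=fs,
            )
        )
    cm = ClinicalModel(panss_missing_sites=("S8", "S9"))
    return CohortConfig(sites=sites, clinical_model=cm, seed=seed)


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _exact_count_flags(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """n binary flags with exactly round(n*p) ones, in random order."""
    k = int(round(n * p))
    flags = np.zeros(n, dtype=int)
    flags[:k] = 1
    rng.shuffle(flags)
    return flags


def _generate_participants(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    cm = config.clinical_model
    lo, hi = config.age_range

    # subgroup labels for cases, shuffled then partitioned across sites
    case_labels = np.concatenate(
        [np.repeat(g, config.subgroup_sizes.get(g, 0)) for g in CASE_SUBGROUPS]
    )
    rng.shuffle(case_labels)

    rows: list[dict] = []
    cursor = 0
    for site in config.sites:
        labels = list(case_labels[cursor: cursor + site.n_cases])
        cursor += site.n_cases
        labels += ["CTR"] * site.n_controls
        for g in labels:
            rows.append({"site_id": site.site_id, "subgroup": g})
    df = pd.DataFrame(rows)
    df["diagnosis"] = np.where(df["subgroup"] == "CTR", "CTR", "EOP")
    df["subject_id"] = [f"sub-{i:04d}" for i in range(len(df))]

    # sex: exact female counts within each subgroup
    df["sex"] = ""
    for g in SUBGROUPS:
        idx = df.index[df["subgroup"] == g]
        flags = _exact_count_flags(rng, len(idx), config.sex_prob_by_group[g])
        df.loc[idx, "sex"] = np.where(flags == 1, "F", "M")

    df["age"] = np.round(
        _truncnorm(rng, config.age_mean, config.age_sd, lo, hi, len(df)), 2
    )

    hand = rng.choice(["R", "L", "A"], size=len(df), p=config.handedness_probs)
    miss = rng.random(len(df)) < config.handedness_missing_rate
    df["handedness"] = np.where(miss, "", hand)

    # clinical covariates: cases only, controls stay missing
    clin_cols = [
        "panss_neg", "panss_pos", "age_onset", "duration", "cpz",
        "ap_user", "lithium_user", "ad_user", "ae_user",
    ]
    for c in clin_cols:
        df[c] = np.nan

    is_case = df["diagnosis"] == "EOP"
    for g in CASE_SUBGROUPS:
        idx = df.index[df["subgroup"] == g]
        n = len(idx)
        if n == 0:
            continue
        dur = np.exp(rng.normal(math.log(cm.duration_median[g]), cm.duration_sigma, n))
        dur = np.minimum(dur, df.loc[idx, "age"].to_numpy() - 7.0)  # onset >= 7 y
        dur = np.round(np.maximum(dur, 0.02), 2)
        df.loc[idx, "duration"] = dur
        df.loc[idx, "age_onset"] = np.round(df.loc[idx, "age"].to_numpy() - dur, 2)
        for score, med in (("panss_neg", cm.panss_neg_median), ("panss_pos", cm.panss_pos_median)):
            base = np.exp(rng.normal(math.log(med[g] - cm.panss_floor), cm.panss_sigma, n))
            df.loc[idx, score] = np.round(cm.panss_floor + base, 0)
        df.loc[idx, "cpz"] = np.round(
            np.exp(rng.normal(math.log(cm.cpz_median[g]), cm.cpz_sigma, n)), 1
        )
        for flag, probs in cm.med_prob.items():
            df.loc[idx, flag] = (rng.random(n) < probs.get(g, 0.0)).astype(float)

    # site-level PANSS non-acquisition and sporadic CPZ missingness
    panss_miss = is_case & df["site_id"].isin(cm.panss_missing_sites)
    df.loc[panss_miss, ["panss_neg", "panss_pos"]] = np.nan
    cpz_miss = is_case & (rng.random(len(df)) < cm.cpz_missing_rate)
    df.loc[cpz_miss, "cpz"] = np.nan

    return df[
        ["subject_id", "site_id", "diagnosis", "subgroup", "sex", "age", "handedness"]
        + clin_cols
    ]


def _generate_measures(
    config: CohortConfig, participants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """ROI-measure long table for every subject/metric/ROI.

    value = baseline(ROI) + beta1*age_c + beta2*age_c^2 + beta_s*female
            + effect(subgroup, ROI) * noise_sd
            + site_shift + site_scale * noise_sd * (shared latent + ROI noise)
    """
    site_map = {s.site_id: s for s in config.sites}
    gen_rois = list(TRACTS) + [PERIPHERY]  # Core/Average derived afterwards
    frames = []
    age_c = participants["age"].to_numpy() - participants["age"].mean()
    female = (participants["sex"] == "F").to_numpy().astype(float)
    rho = config.latent_rho

    for metric in config.metric_names:
        sd = config.noise_sd[metric]
        b1, b2 = config.age_coefficients[metric]
        bs = config.sex_offset[metric]
        baselines = rng.normal(
            config.baseline_mean[metric], config.baseline_spread[metric], len(gen_rois)
        )
        if metric == "FA":
            baselines = np.clip(baselines, 0.15, 0.85)
        else:
            baselines = np.maximum(baselines, 0.2)

        has_metric = participants["site_id"].map(
            lambda s: metric in site_map[s].metrics_available
        ).to_numpy()
        sub = participants[has_metric].reset_index(drop=True)
        n = len(sub)
        if n == 0:
            continue
        agec = age_c[has_metric]
        fem = female[has_metric]
        shift = sub["site_id"].map(
            lambda s: site_map[s].additive_shift.get(metric, 0.0)
        ).to_numpy()
        scale = sub["site_id"].map(
            lambda s: site_map[s].scale_factor.get(metric, 1.0)
        ).to_numpy()

        eff = np.zeros((n, len(gen_rois)))
        for j, roi in enumerate(gen_rois):
            for g in CASE_SUBGROUPS:
                e = config.effect_matrix.get(g, {}).get(metric, {}).get(roi, 0.0)
                if e:
                    eff[sub["subgroup"].to_numpy() == g, j] += e * sd

        mean = (
            baselines[None, :]
            + (b1 * agec + b2 * agec**2 + bs * fem + shift)[:, None]
            + eff
        )
        latent = rng.normal(0.0, 1.0, n)
        eps = rng.normal(0.0, 1.0, (n, len(gen_rois)))
        noise = math.sqrt(rho) * latent[:, None] + math.sqrt(1.0 - rho) * eps
        values = mean + scale[:, None] * sd * noise

        # diffusivities must stay positive; FA inside (0,1): resample offenders
        lo_ok = 0.0
        for attempt in range(10):
            if metric == "FA":
                bad = (values <= 0.02) | (values >= 0.98)
            else:
                bad = values <= lo_ok
            if not bad.any():
                break
            warnings.warn(
                f"{metric}: resampling {int(bad.sum())} out-of-range draws",
                stacklevel=2,
            )
            redraw = rng.normal(0.0, 1.0, int(bad.sum()))
            scale_mat = np.broadcast_to(scale[:, None], values.shape)
            values[bad] = mean[bad] + scale_mat[bad] * sd * redraw
        else:
            raise RuntimeError(f"{metric}: values out of range after 10 resamples")

        wide = pd.DataFrame(values, columns=gen_rois)
        wide[CORE] = wide[list(TRACTS)].mean(axis=1)  # voxel-weighted-mean proxy
        wide[AVERAGE] = (V_CORE * wide[CORE] + V_PERIPHERY * wide[PERIPHERY]) / V_TOTAL
        wide.insert(0, "subject_id", sub["subject_id"].to_numpy())
        long = wide.melt(id_vars="subject_id", var_name="roi", value_name="value")
        long.insert(1, "metric", metric)
        frames.append(long)

    out = pd.concat(frames, ignore_index=True)
    order = {r: i for i, r in enumerate((AVERAGE,) + TRACTS + (CORE, PERIPHERY))}
    out["_roi_order"] = out["roi"].map(order)
    out = (
        out.sort_values(["metric", "_roi_order", "subject_id"], kind="stable")
        .drop(columns="_roi_order")
        .reset_index(drop=True)
    )
    return out


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (participants, roi_measures) tables for a configuration.

    Deterministic given ``config.seed``.  Returns the participant table
    (one row per subject) and the long-format ROI-measure table (one row
    per subject x metric x ROI, including Core/Periphery summaries and
    the exactly-consistent skeleton Average).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0110]))
    participants = _generate_participants(config, rng)
    measures = _generate_measures(config, participants, rng)
    return participants, measures


def true_effects_sidecar(config: CohortConfig) -> dict:
    """JSON-serializable record of injected ground truth for audits."""
    return {
        "seed": int(config.seed),
        "effect_matrix": config.effect_matrix,
        "sites": [
            {
                "site_id": s.site_id,
                "n_cases": s.n_cases,
                "n_controls": s.n_controls,
                "additive_shift": s.additive_shift,
                "scale_factor": s.scale_factor,
                "metrics_available": list(s.metrics_available),
                "field_strength": s.field_strength,
            }
            for s in config.sites
        ],
        "noise_sd": config.noise_sd,
        "latent_rho": config.latent_rho,
    }


def with_injected_effect(
    config: CohortConfig, roi: str, metric: str, d: float,
    subgroups: tuple[str, ...] = CASE_SUBGROUPS,
) -> CohortConfig:
    """Copy of ``config`` with a single uniform case-control effect.

    ``d`` is the standardized control-minus-case difference, so a
    positive ``d`` lowers the case mean by ``d`` control SDs (the
    orientation in which FA deficits in cases print as positive d).
    All other effects are cleared.
    """
    eff = {g: {m: {} for m in METRICS} for g in CASE_SUBGROUPS}
    for g in subgroups:
        eff[g][metric] = {roi: -d}
    return replace(config, effect_matrix=eff)
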