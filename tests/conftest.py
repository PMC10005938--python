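import numpy as np
import pandas as pd
import pytest

from dtimega import (
    CohortConfig,
    SiteSpec,
    apply_combat,
    default_study_config,
    fit_combat,
    generate_cohort,
)
from dtimega.synthetic_cohort import _default_effect_matrix


def make_config(site_layout, subgroup_sizes, seed=0, effect_matrix=None,
                shifts=None, scales=None, **kwargs) -> CohortConfig:
    """Small custom cohort configuration for fast unit tests.

    ``site_layout`` is a list of (site_id, n_cases, n_controls,
    metrics_available) tuples; ``shifts``/``scales`` map site_id to
    per-metric dicts.
    """
    sites = []
    for site_id, n_ca, n_co, metrics in site_layout:
        sites.append(SiteSpec(
            site_id=site_id, n_cases=n_ca, n_controls=n_co,
            additive_shift=(shifts or {}).get(site_id, {}),
            scale_factor=(scales or {}).get(site_id, {}),
            metrics_available=metrics,
        ))
    eff = effect_matrix if effect_matrix is not None else {
        g: {m: {} for m in ("FA", "MD", "RD", "AD")} for g in ("EOS", "AFP", "OTP")
    }
    return CohortConfig(sites=sites, subgroup_sizes=subgroup_sizes,
                        effect_matrix=eff, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Two mid-sized sites, ~100 subjects, no injected effects."""
    cfg = make_config(
        [("A", 30, 25, ("FA", "MD", "RD", "AD")),
         ("B", 25, 20, ("FA", "MD", "RD", "AD"))],
        {"CTR": 45, "EOS": 30, "AFP": 15, "OTP": 10},
        seed=42,
    )
    participants, measures = generate_cohort(cfg)
    return cfg, participants, measures


@pytest.fixture(scope="session")
def study_cohort():
    """Default nine-site cohort with the standard injected effects."""
    cfg = default_study_config(seed=11)
    participants, measures = generate_cohort(cfg)
    return cfg, participants, measures


@pytest.fixture(scope="session")
def study_cohort_harmonized(study_cohort):
    cfg, participants, measures = study_cohort
    fit = fit_combat(measures, participants)
    adjusted = apply_combat(fit, measures)
    return cfg, participants, adjusted, fit
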