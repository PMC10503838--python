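"""Shared fixtures: small regimens, synthetic studies and fitted models.

Everything is generated programmatically and seeded, so the suite needs no
data files and is fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from photogam import (
    GroupParams,
    ModelSpec,
    SimConfig,
    SmoothTerm,
    aggregate_group_mean,
    build_design,
    build_repeat_regimen,
    fit_gam,
    group_series_frame,
    simulate_traces,
)


@pytest.fixture(scope="session")
def small_regimen():
    """Compact dark-light repeat regimen: 5-min acclim + 2x(4+2 min) + 4-min dark."""
    return build_repeat_regimen(
        acclim_min=5, n_cycles=2, dark_min=4, light_min=2, final_dark_min=4
    )


@pytest.fixture(scope="session")
def small_study(small_regimen):
    """A seeded 3-assay study with the default genotype mechanism."""
    cfg = SimConfig(
        regimen=small_regimen, n_assays=3, n_fish_per_group=6, seed=20240
    )
    traces, truth = simulate_traces(cfg)
    return cfg, traces, truth


@pytest.fixture(scope="session")
def small_series(small_study, small_regimen):
    cfg, traces, _ = small_study
    series = aggregate_group_mean(
        traces, ["geno"], stride_s=5, start_s=small_regimen.analysis_start_s
    )
    return group_series_frame(series)


@pytest.fixture(scope="session")
def small_fit(small_series):
    spec = ModelSpec(
        parametric_factors=["geno"],
        smooth_terms=[SmoothTerm(var="time_s", k=20, by="geno")],
        random_effect="assay_id",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_gam(build_design(spec, small_series))


@pytest.fixture(scope="session")
def toy_fit():
    """Tiny two-genotype fit with known structure for EMM/contrast checks."""
    rng = np.random.default_rng(7)
    rows = []
    for aid, aeff in zip(["a1", "a2", "a3"], [0.4, -0.1, -0.3]):
        for g, off in [("WT", 0.0), ("HM", -1.5)]:
            t = np.arange(60, dtype=float)
            y = 5 + off + np.sin(t / 9) + aeff + rng.normal(0, 0.4, 60)
            rows.append(
                pd.DataFrame(
                    {"assay_id": aid, "geno": g, "time_s": t, "rsums": y}
                )
            )
    df = pd.concat(rows, ignore_index=True)
    spec = ModelSpec(
        parametric_factors=["geno"],
        smooth_terms=[SmoothTerm(var="time_s", k=10, by="geno")],
        random_effect="assay_id",
    )
    return fit_gam(build_design(spec, df))
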