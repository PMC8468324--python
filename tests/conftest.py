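"""Shared fixtures: generated cohorts reused across test modules."""

from __future__ import annotations

import dataclasses

import pytest

import bodywage as bw
from bodywage import models as md
from bodywage.synthetic import GENDERS


def clean_config(n: int = 20_000, seed: int = 0) -> bw.GeneratorConfig:
    """Alias for the package's recovery configuration."""
    return bw.recovery_demo_config(n=n, seed=seed)


SHORT_SPEC = md.ModelSpec(
    dependent="ln_income",
    regressors=("bmi", *md.DEMOGRAPHICS, *md.SOCIOECONOMIC),
    factors=("edu",),
)


@pytest.fixture(scope="session")
def paperlike_sample():
    """Raw table + ground truth at moderate n (paper-like defaults)."""
    cfg = bw.default_paperlike_config(n=12_000, seed=42)
    df, truth = bw.generate_population(cfg)
    return df, truth


@pytest.fixture(scope="session")
def paperlike_cohort(paperlike_sample):
    """Prepared analysis cohort for the paper-like sample."""
    df, truth = paperlike_sample
    cohort, log, thresholds = bw.prepare_cohort(df)
    return cohort, log, thresholds, truth
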