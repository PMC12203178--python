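"""Shared fixtures: phantoms, echo series and cohort tables are generated
programmatically (session-scoped where expensive, so reconstruction-heavy
tests share one run)."""

import numpy as np
import pytest

from nigraq import (
    build_phantom,
    default_design,
    reconstruct_qsm,
    simulate_cohort,
    simulate_echoes,
)


@pytest.fixture(scope="session")
def phantom64():
    return build_phantom(shape=(64, 64, 64), seed=1)


@pytest.fixture(scope="session")
def echoes64(phantom64):
    return simulate_echoes(phantom64, noise_sd=0.0)


@pytest.fixture(scope="session")
def recon64(phantom64, echoes64):
    chi, inter = reconstruct_qsm(
        echoes64, phantom64.brain_mask, keep_intermediates=True
    )
    return chi, inter


@pytest.fixture(scope="session")
def phantom48():
    return build_phantom(shape=(48, 48, 48), seed=2)


@pytest.fixture(scope="session")
def cohort_pv():
    """Default paper-derived design restricted to the posteroventral SN."""
    design = default_design(seed=11, rois=["posteroventral"])
    table, truth = simulate_cohort(design)
    return table, truth, design


def null_design(seed=0, sd=0.030):
    """Matched-null cohort design: identical group means, no slopes."""
    design = default_design(seed=seed, rois=["posteroventral"])
    for m in design.measures:
        for g in list(m.mean):
            m.mean[g] = 0.103 if m.modality == "qsm_ppm" else 26.0
            m.sd[g] = sd if m.modality == "qsm_ppm" else 3.4
        m.slope = {}
    design.beta_sex_male = {"qsm_ppm": 0.0, "r2s_hz": 0.0}
    return design
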