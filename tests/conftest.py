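"""Shared builders for the test suite.

Everything is generated programmatically; the only on-disk fixtures are
the small reference tables packaged with the library.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scavtrace import AsvTable, CohortConfig, DecompositionConfig, RunConfig, run_pipeline


def make_table(
    counts,
    sample_ids=None,
    asv_ids=None,
    sample_type="chicken_tissue",
    days=None,
    sites=None,
    is_control=None,
):
    """Build an AsvTable from a plain count matrix with minimal metadata."""
    counts = np.asarray(counts, dtype=np.int64)
    n, m = counts.shape
    sample_ids = sample_ids or [f"s{i:02d}" for i in range(n)]
    asv_ids = asv_ids or [f"asv{j:02d}" for j in range(m)]
    types = [sample_type] * n if isinstance(sample_type, str) else list(sample_type)
    meta = pd.DataFrame(
        {
            "sample_type": types,
            "site": sites or ["site1"] * n,
            "day": days or [None] * n,
            "is_control": is_control or [False] * n,
        },
        index=sample_ids,
    )
    return AsvTable(pd.DataFrame(counts, index=sample_ids, columns=asv_ids), meta)


def random_table(rng, n_samples=12, n_asvs=20, sparsity=0.6, **kwargs):
    counts = rng.integers(1, 40, size=(n_samples, n_asvs))
    counts[rng.random((n_samples, n_asvs)) < sparsity] = 0
    counts[:, 0] = np.maximum(counts[:, 0], 1)  # no empty samples
    return make_table(counts, **kwargs)


# -- small, noise-free pipeline run shared across recovery tests ----------

SMALL_DECOMP = dict(
    n_fresh_only=3, n_decayed_only=8, n_spanning=0, n_sporadic=0, detection_prob=1.0
)
SMALL_COHORT = dict(
    n_rats=24,
    n_feces=12,
    frac_consumed=10 / 24,
    frac_not_consumed=6 / 24,
    frac_scavenger=0.5,
    n_planted_per_scavenger=2,
    n_resident_pool=50,
    resident_richness=18.0,
    n_confounders=3,
)


@pytest.fixture(scope="session")
def noise_free_run():
    """One end-to-end run on constructively clean synthetic data."""
    cfg = RunConfig(
        seed=42,
        decomposition=DecompositionConfig(seed=101, **SMALL_DECOMP),
        cohort=CohortConfig(seed=202, **SMALL_COHORT),
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def ambiguous_run():
    """A run whose cohort includes evidence-ambiguous rats carrying plants."""
    cfg = RunConfig(
        seed=7,
        decomposition=DecompositionConfig(seed=301, **SMALL_DECOMP),
        cohort=CohortConfig(
            seed=302,
            n_rats=30,
            n_feces=15,
            frac_consumed=10 / 30,
            frac_not_consumed=8 / 30,
            frac_scavenger=0.5,
            n_planted_per_scavenger=2,
            n_resident_pool=50,
            resident_richness=18.0,
            n_confounders=3,
        ),
    )
    return run_pipeline(cfg)
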