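"""Shared fixtures: small synthetic datasets and a text-counts stand-in."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import labiofreq as lf


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset with a clear negative subsistence effect."""
    cfg = lf.GeneratorConfig(
        n_lineages=30, regions=8, doculects_per_lineage="geometric:5",
        beta_hg=-0.8, seed=42)
    return lf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    profiles, _ = lf.profile_doculects(small_dataset.doculects)
    return lf.join_metadata(lf.profiles_frame(profiles), small_dataset.metadata,
                            taxonomy="large")


@pytest.fixture(scope="session")
def jipa_like_counts() -> pd.DataFrame:
    """Synthetic per-text consonant-count table with the lineage-level
    presence tallies of the published text survey: 72 texts, 7 HG lineages
    none of which uses labiodentals, 30 non-HG lineages of which 18 do.

    The per-text counts themselves are invented (synthetic stand-in); only
    the lineage-level presence/absence pattern is meaningful.
    """
    rows = []
    for i in range(7):
        rows.append({"text_id": f"hg_t{i}", "lineage": f"hgL{i:02d}",
                     "subsistence": "HG", "n_consonants": 500,
                     "n_labiodental": 0, "n_wi_labiodental": 0})
    # 65 non-HG texts over 30 lineages, round-robin; lineages 0-17 positive
    for j in range(65):
        lin = j % 30
        positive = lin < 18 and j < 30  # first text of each positive lineage
        rows.append({
            "text_id": f"non_t{j}", "lineage": f"nonL{lin:02d}",
            "subsistence": "nonHG", "n_consonants": 500,
            "n_labiodental": 10 if positive else 0,
            "n_wi_labiodental": 4 if positive else 0,
        })
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
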