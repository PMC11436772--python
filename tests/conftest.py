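"""Shared fixtures: in-memory variant tables and small simulation runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from loadfit.load_metrics import VariantTable


def make_table(genotypes, impacts, samples=None, positions=None, genes=None):
    """Build a VariantTable from a (n_sites, n_samples) genotype list/array.

    ``impacts`` is one category string per site; positions default to
    100, 200, ...; genes default to g1, g2, ...
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if positions is None:
        positions = [100 * (i + 1) for i in range(n_sites)]
    if genes is None:
        genes = [f"g{i + 1}" for i in range(n_sites)]
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n_sites,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
        "impact": impacts,
        "gene": genes,
    })
    return VariantTable(sites=sites, genotypes=g, samples=list(samples))


@pytest.fixture
def toy_table():
    """5 individuals x 6 sites covering all impact classes."""
    return make_table(
        genotypes=[
            [2, 1, 0, 0, 1],   # LOF
            [1, 0, 0, 2, 0],   # LOF
            [1, 1, 2, 0, 0],   # MISSENSE
            [0, 2, 1, 1, 1],   # SYNONYMOUS
            [1, 1, 1, 1, 1],   # SYNONYMOUS, everyone het
            [0, 1, 0, 0, 2],   # OTHER (noncoding)
        ],
        impacts=["LOF", "LOF", "MISSENSE", "SYNONYMOUS", "SYNONYMOUS", "OTHER"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """One moderate default-scenario run shared across tests."""
    from loadfit.synthetic_data import default_config, simulate_population

    cfg = default_config(
        seed=42, n_founders=30, n_generations=12, carrying_capacity=80,
        immigration_generation=9,
        standing_sites=(30, 200, 400, 800), panel_size=30, n_dens=15,
    )
    return simulate_population(cfg)
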