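"""Shared fixtures: small synthetic studies and hand-built datasets."""

import numpy as np
import pandas as pd
import pytest

from pathprs import harmonize
from pathprs.ldpanel import clump
from pathprs.simulate import SimulationConfig, simulate_study
from pathprs.sumstats import SummaryDataset


def make_dataset(rows, trait_label="trait", cohort_n=10_000):
    """Build a SummaryDataset from a list of row dicts (defaults filled in)."""
    defaults = {
        "chrom": "1",
        "effect_allele": "A",
        "other_allele": "G",
        "beta": 0.1,
        "se": 0.05,
        "pvalue": 0.5,
        "eaf": 0.3,
        "n": cohort_n,
    }
    full = []
    for i, r in enumerate(rows):
        d = {"snp_id": f"rs{i + 1}", "pos": 1000 * (i + 1), **defaults, **r}
        full.append(d)
    order = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pvalue", "eaf", "n"]
    df = (
        pd.DataFrame(full)[order]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SummaryDataset(df, trait_label=trait_label, cohort_n=cohort_n)


def random_aligned_frame(rng, n=50):
    """Random aligned score-table rows (w >= 0, positive SEs)."""
    from pathprs.sumstats import AlignedScoreTable

    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "w": np.abs(rng.normal(0.1, 0.05, n)) + 1e-3,
            "b": rng.normal(0, 0.02, n),
            "s": rng.uniform(0.01, 0.05, n),
            "p_disc": rng.uniform(0, 1, n),
            "p_targ": rng.uniform(0, 1, n),
            "eaf": rng.uniform(0.05, 0.95, n),
        }
    )
    return AlignedScoreTable(df, target_n=13_000)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_snps=2_000,
        n_blocks=40,
        within_block_rho=0.6,
        panel_n=250,
        n_genes=100,
        set_size=10,
        n_targ=(8_000, 6_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_aligned(small_bundle):
    return harmonize(small_bundle.discovery, small_bundle.targets[0])


@pytest.fixture(scope="session")
def small_clump(small_aligned, small_bundle):
    return clump(small_aligned, small_bundle.panel)
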