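import numpy as np
import pandas as pd
import pytest

import epicohort as ec


@pytest.fixture(scope="session")
def small_config() -> ec.SyntheticConfig:
    """A reduced design for fast per-module tests (same structure as the
    default study conditions, fewer genes)."""
    return ec.SyntheticConfig(
        genes_per_archetype={**{a: 40 for a in ec.synthetic.ARCHETYPES},
                             "background": 200},
        seed=123)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> ec.SyntheticBundle:
    return ec.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    """Shared downstream products of the small bundle (computed once)."""
    b = small_bundle
    filtered = ec.filter_low_counts(b.counts)
    factors = ec.tmm_factors(filtered)
    norm = ec.normalize(filtered, factors)
    cpm = ec.expression.tmm_cpm(filtered, factors)
    contrasts = ec.plan_contrasts(b.metadata)
    de = ec.expression.run_all_contrasts(filtered, b.metadata, contrasts,
                                         factors)
    signal_tables = {
        key: ec.assign_peaks_to_genes(df, b.gene_models, mark=key[0])
        for key, df in b.peaks.items()}
    marks = ec.profiles.mark_signal_wide(signal_tables)
    return {"bundle": b, "filtered": filtered, "factors": factors,
            "norm": norm, "cpm": cpm, "contrasts": contrasts, "de": de,
            "marks": marks}


def random_genes(rng: np.random.Generator, n: int,
                 chrom_choices=("chr1", "chr2")) -> pd.DataFrame:
    starts = rng.integers(5_000, 500_000, size=n)
    lengths = rng.integers(500, 20_000, size=n)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": rng.choice(chrom_choices, size=n),
        "start": starts,
        "end": starts + lengths,
        "strand": rng.choice(["+", "-"], size=n),
    })


def random_peaks(rng: np.random.Generator, n: int,
                 chrom_choices=("chr1", "chr2")) -> pd.DataFrame:
    starts = rng.integers(0, 520_000, size=n)
    widths = rng.integers(100, 5_000, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chrom_choices, size=n),
        "start": starts,
        "end": starts + widths,
        "name": [f"p{i}" for i in range(n)],
        "score": 0,
        "strand": ".",
        "signalValue": rng.uniform(0.1, 50.0, size=n).round(3),
        "pValue": rng.uniform(1, 10, size=n),
        "qValue": rng.uniform(0.5, 10.0, size=n),
        "peak": -1,
    })
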