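import numpy as np
import pandas as pd
import pytest

from renalmr.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_variants():
    """Three-variant metadata frame for scan tests."""
    return pd.DataFrame({
        "variant_id": ["1:100:A:G", "1:200:T:C", "1:300:A:C"],
        "chrom": "1",
        "pos": [100, 200, 300],
        "effect_allele": ["A", "T", "A"],
        "other_allele": ["G", "C", "C"],
    })


def make_variants(m, chrom="1", start=1000, spacing=1000):
    pos = start + spacing * np.arange(m)
    return pd.DataFrame({
        "variant_id": [f"{chrom}:{p}:A:G" for p in pos],
        "chrom": chrom,
        "pos": pos,
        "effect_allele": "A",
        "other_allele": "G",
    })


@pytest.fixture
def base_config():
    return SimulationConfig(n_individuals=2000, n_variants_region=20, seed=7)
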