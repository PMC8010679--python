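import numpy as np
import pandas as pd
import pytest

from retroatlas import synthetic_data as sd


@pytest.fixture(scope="session")
def small_count_sim():
    """A 600-gene, 16-sample planted count matrix shared across tests."""
    spec = sd.CountSimSpec(
        n_genes=600,
        samples=tuple(f"S{i + 1:02d}" for i in range(16)),
        seed=42,
    )
    counts, truth = sd.simulate_count_matrix(spec)
    return spec, counts, truth


@pytest.fixture(scope="session")
def small_ltr_library():
    """A 30-element simulated genome with known insertion ages."""
    spec = sd.EvolutionSpec(seed=7)
    return sd.simulate_ltr_library(
        30, 120, sd.two_class_ages(0.5, 5e5, 3e6), spec,
        complete_fraction=0.8, internal_length=80, spacer_length=50)


@pytest.fixture
def toy_counts():
    """Hand-written 4-gene, 2-sample (2 replicates) count table."""
    return pd.DataFrame(
        {
            "A.1": [10, 100, 0, 7],
            "A.2": [12, 90, 0, 6],
            "B.1": [9, 110, 0, 0],
            "B.2": [11, 95, 0, 1],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


def brute_force_fisher(a: int, b: int, c: int, d: int) -> float:
    """Exact-arithmetic two-sided Fisher p (minimum-likelihood method).

    Enumerates every table with the observed margins; point probabilities
    are compared as exact integers (common denominator C(n, c1)), so the
    oracle shares no code path or floating-point pmf with the
    implementation under test.
    """
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    # numerator comparison with the same 1e-7 relative slack, in exact ints
    total = sum(v for v in nums.values() if v * 10**7 <= obs * (10**7 + 1))
    return total / comb(n, c1)
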