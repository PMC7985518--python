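"""Shared fixtures and independent oracle implementations.

The oracles deliberately use naive explicit loops / set logic so they
stay independent of the vectorized implementation paths they check.
"""

import math

import numpy as np
import pytest

from tfcascade.genomic_core import reverse_complement
from tfcascade.pipeline import config_for_bundle, run_pipeline
from tfcascade.synthetic_data import SimulationConfig, simulate_bundle

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_trap_affinity(energy_matrix, sequence: str) -> float:
    """Per-window loop implementation of the TRAP occupancy sum."""
    s = sequence.upper()
    m = energy_matrix.width
    en = energy_matrix.energies
    ln_r0 = energy_matrix.ln_r0
    total = 0.0
    for i in range(len(s) - m + 1):
        window = s[i : i + m]
        if any(b not in "ACGT" for b in window):
            continue
        for w in (window, reverse_complement(window)):
            e = sum(en["ACGT".index(b), j] for j, b in enumerate(w))
            x = math.exp(ln_r0 - e)
            total += x / (1.0 + x)
    return total


def brute_force_overlaps(a, b):
    """All-pairs O(n*m) overlap check with half-open semantics."""
    pairs = set()
    for i, iv_a in enumerate(a):
        for j, iv_b in enumerate(b):
            if (
                iv_a.chrom == iv_b.chrom
                and iv_a.start < iv_b.end
                and iv_b.start < iv_a.end
            ):
                pairs.add((i, j))
    return pairs


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# Simulated bundles (session-scoped: the expensive ones are shared)
# ---------------------------------------------------------------------------

SMALL_SIM = dict(
    seed=7,
    n_chromosomes=2,
    chrom_length=1_800_000,
    n_genes=60,
    n_tfs=4,
)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic bundle: 300 genes, noise-free."""
    config = SimulationConfig(seed=1)
    return simulate_bundle(config, tmp_path_factory.mktemp("default_bundle"))


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """Full pipeline result on the default bundle."""
    config = config_for_bundle(
        default_bundle, tmp_path_factory.mktemp("default_run")
    )
    return default_bundle, run_pipeline(config)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 60-gene bundle for fast pipeline-level tests."""
    config = SimulationConfig(**SMALL_SIM)
    return simulate_bundle(config, tmp_path_factory.mktemp("small_bundle"))


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    config = config_for_bundle(small_bundle, tmp_path_factory.mktemp("small_run"))
    return small_bundle, run_pipeline(config)
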