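"""Shared fixtures: small random weighted graphs and a compact synthetic cohort."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `import oracles` work

from tbiconn import CohortSpec, generate_cohort


def random_weighted_graph(rng: np.random.Generator, n: int | None = None, density: float = 0.6) -> np.ndarray:
    """Symmetric nonnegative weight matrix with zero diagonal; may be disconnected."""
    if n is None:
        n = int(rng.integers(3, 9))
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, k=1)
    return w + w.T


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Compact study conditions for structural tests: 30 nodes, groups 4/3/3."""
    return CohortSpec(
        n_nodes=30,
        group_sizes={"control": 4, "mTBI": 3, "msTBI": 3},
        n_control_cognition=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)
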