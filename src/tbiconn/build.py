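"""Construction of analysis-ready weighted networks from streamline-count matrices.

Raw tractography output is a square, (near-)symmetric matrix of streamline
counts between parcellation regions. The construction pipeline is:
symmetrize (average with the transpose), zero the diagonal, threshold out
low-count edges that are treated as tractography noise, and normalize by the
subject's total fiber count so that subjects with globally different
streamline yields become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: severity groups, ordered from least to most severe
GROUPS = ("control", "mTBI", "msTBI")

#: default noise threshold in raw streamline units
DEFAULT_MIN_STREAMLINES = 10


class DegenerateNetworkError(ValueError):
    """All edges were removed (e.g. every count fell below the noise threshold)."""


class AsymmetryError(ValueError):
    """Input matrix is asymmetric beyond the allowed tolerance."""


def _validate_counts(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"streamline matrix must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("streamline matrix contains non-finite entries")
    if np.any(m < 0):
        raise ValueError("streamline matrix contains negative entries")
    return m


@dataclass
class WeightedNetwork:
    """Thresholded, diagonal-zeroed, total-fiber-normalized adjacency.

    Attributes
    ----------
    weights
        Symmetric n x n nonnegative weights; upper triangle sums to 1.
    node_labels
        Region names aligned to the rows/columns.
    total_fibers
        Sum of upper-triangle streamline counts before normalization.
        Multiplying ``weights`` by this recovers the thresholded counts.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    total_fibers: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.node_labels:
            self.node_labels = [f"node_{i:03d}" for i in range(self.n_nodes)]
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def raw_counts(self) -> np.ndarray:
        """Thresholded streamline counts (weights un-normalized)."""
        return self.weights * self.total_fibers


def symmetrize(matrix: np.ndarray, asymmetry_tol: float = 1e-6) -> np.ndarray:
    """Average a matrix with its transpose; reject gross asymmetry.

    Tractography pipelines emit symmetric matrices up to floating point, so
    any relative asymmetry beyond ``asymmetry_tol`` indicates corrupted input
    rather than numerical noise.
    """
    m = _validate_counts(matrix)
    scale = np.abs(m).max()
    if scale > 0:
        rel = np.abs(m - m.T).max() / scale
        if rel > asymmetry_tol:
            raise AsymmetryError(
                f"relative asymmetry {rel:.3g} exceeds tolerance {asymmetry_tol:.3g}"
            )
    return (m + m.T) / 2.0


def zero_diagonal(matrix: np.ndarray) -> np.ndarray:
    """Remove self-connections: set the main diagonal to zero."""
    m = _validate_counts(matrix).copy()
    np.fill_diagonal(m, 0.0)
    return m


def apply_noise_threshold(
    matrix: np.ndarray, min_streamlines: float = DEFAULT_MIN_STREAMLINES
) -> np.ndarray:
    """Zero out connections supported by fewer than ``min_streamlines`` streamlines.

    Entries >= the threshold pass through unchanged (10 streamlines survive a
    threshold of 10; 9 do not).
    """
    m = _validate_counts(matrix).copy()
    m[m < min_streamlines] = 0.0
    return m


def normalize_total_fibers(
    matrix: np.ndarray, node_labels: Sequence[str] | None = None
) -> WeightedNetwork:
    """Divide by the total fiber count (sum over the upper triangle).

    Each anatomical connection is counted once, so after normalization the
    upper-triangle weights sum to 1 and the network is a connection-probability
    style weighting comparable across subjects.
    """
    m = _validate_counts(matrix)
    total = float(np.triu(m, k=1).sum())
    if total <= 0:
        raise DegenerateNetworkError("network has no surviving edges; cannot normalize")
    return WeightedNetwork(
        weights=m / total,
        node_labels=list(node_labels) if node_labels is not None else [],
        total_fibers=total,
    )


def build_network(
    matrix: np.ndarray,
    min_streamlines: float = DEFAULT_MIN_STREAMLINES,
    node_labels: Sequence[str] | None = None,
    asymmetry_tol: float = 1e-6,
) -> WeightedNetwork:
    """Full construction: symmetrize -> zero diagonal -> threshold -> normalize."""
    m = symmetrize(matrix, asymmetry_tol=asymmetry_tol)
    m = zero_diagonal(m)
    m = apply_noise_threshold(m, min_streamlines=min_streamlines)
    return normalize_total_fibers(m, node_labels=node_labels)


def classify_severity(gcs: int) -> str:
    """Map a Glasgow Coma Scale score to a TBI severity group.

    GCS 14-15 is classified mild (mTBI); GCS 3-13 moderate-severe (msTBI).
    """
    gcs = int(gcs)
    if not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be in [3, 15], got {gcs}")
    return "mTBI" if gcs >= 14 else "msTBI"


def change_score(pre: float | None, post: float | None) -> float | None:
    """Cognitive change score: post-injury minus pre-injury.

    Returns None (an explicitly missing result, never zero) if either score
    is missing.
    """
    if pre is None or post is None:
        return None
    pre = float(pre)
    post = float(post)
    if not (np.isfinite(pre) and np.isfinite(post)):
        return None
    return post - pre


@dataclass
class SubjectRecord:
    """Subject-level metadata: group membership, injury and cognitive scores."""

    id: str
    group: str
    gcs: int | None = None
    age: float | None = None
    time_since_injury: float | None = None
    rpm_pre: float | None = None
    rpm_post: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.gcs is not None and self.group != "control":
            expected = classify_severity(self.gcs)
            if expected != self.group:
                raise ValueError(
                    f"GCS {self.gcs} implies group {expected!r}, not {self.group!r}"
                )

    @property
    def rpm_change(self) -> float | None:
        return change_score(self.rpm_pre, self.rpm_post)
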