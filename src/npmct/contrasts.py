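"""Genetic contrast matrices for three ordered genotype groups.

The Marcus-type matrix targets the three classical modes of inheritance —
dominant (carriers {aA, AA} vs aa), additive (AA vs aa) and recessive
(AA vs non-carriers {aa, aA}) — with pooled groups weighted by their sample
sizes. The Tukey-type all-pairs matrix is sensitive to any heterogeneity
among the three groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContrastSpec", "marcus_matrix", "all_pairs_matrix", "apply_contrasts"]

MARCUS_LABELS = ("dominant", "additive", "recessive")
ALL_PAIRS_LABELS = ("2-1", "3-1", "3-2")


@dataclass(frozen=True)
class ContrastSpec:
    """A labeled set of contrast rows over the three genotype-group effects."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    weights: tuple[int, ...] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), 3):
            raise ValueError("contrast matrix shape must match labels x 3 groups")
        if not np.allclose(m.sum(axis=1), 0.0, atol=1e-12):
            raise ValueError("every contrast row must sum to 0")
        if np.any(np.all(m == 0, axis=1)):
            raise ValueError("all-zero contrast row")
        object.__setattr__(self, "matrix", m)


def marcus_matrix(n1: int, n2: int, n3: int) -> ContrastSpec:
    """Marcus-type dominant/additive/recessive contrasts.

    Pooled groups enter with sample-size weights; positive contrast values
    mean higher trait values with more risk-allele copies. With equal group
    sizes this reduces to the balanced form
    ``[(-1, 1/2, 1/2), (-1, 0, 1), (-1/2, -1/2, 1)]``.
    """
    if min(n1, n2, n3) < 1:
        raise ValueError("all group sizes must be >= 1")
    m = np.array(
        [
            [-1.0, n2 / (n2 + n3), n3 / (n2 + n3)],
            [-1.0, 0.0, 1.0],
            [-n1 / (n1 + n2), -n2 / (n1 + n2), 1.0],
        ]
    )
    return ContrastSpec(m, MARCUS_LABELS, (n1, n2, n3))


def all_pairs_matrix() -> ContrastSpec:
    """Tukey-type all-pairwise comparisons among the three groups."""
    m = np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0], [0.0, -1.0, 1.0]])
    return ContrastSpec(m, ALL_PAIRS_LABELS)


def apply_contrasts(spec: ContrastSpec, p_hat) -> np.ndarray:
    """Contrast effects ``delta_q = c_q' p_hat``; each lies in [-1, 1]."""
    p = np.asarray(p_hat, dtype=float)
    if p.shape != (spec.matrix.shape[1],):
        raise ValueError(
            f"effect vector of length {p.size} does not match contrast width {spec.matrix.shape[1]}"
        )
    return spec.matrix @ p
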