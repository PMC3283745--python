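"""Rank-based estimation of relative effects for three ordered genotype groups.

The quantities here are the building blocks of the nonparametric multiple
contrast tests: normalized (mid) empirical distribution functions, pairwise
placements, two-sample relative effects ``w_ij = P(X_i < X_j) + 0.5 P(X_i = X_j)``,
pseudo-ranks, the unweighted relative effects ``p_i = int G dF_i`` against the
unweighted mean distribution ``G = (F_1 + F_2 + F_3)/3``, and the covariance
matrix of ``sqrt(N) (p_hat - p)`` obtained from the asymptotic influence
decomposition of the effect estimator.

All empirical distribution functions use the mid (normalized) convention
``F(x) = (#{X < x} + 0.5 #{X = x}) / n``, so ties — including ordered
categorical scores and detection-limit data encoded as a shared constant —
need no special casing, and every statistic is invariant under strictly
increasing transformations of the trait values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GroupedSample",
    "EffectEstimate",
    "midranks",
    "pairwise_placements",
    "pairwise_effect",
    "pseudo_ranks",
    "estimate_effects",
    "estimate_covariance",
    "relative_effects",
]


def _as_finite_vector(values, name: str = "values") -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d vector")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must contain only finite values")
    return x


@dataclass(frozen=True)
class GroupedSample:
    """Trait values split into the three genotype groups.

    Groups are ordered by risk-allele copy number: group 1 carries 0 copies
    (aa), group 2 one copy (aA), group 3 two copies (AA). Ties are permitted;
    ordered-categorical and detection-limit phenotypes are represented as
    tied real values.
    """

    groups: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.groups) != 3:
            raise ValueError("exactly 3 genotype groups are required")
        clean = tuple(_as_finite_vector(g, f"group {i + 1}") for i, g in enumerate(self.groups))
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_arrays(cls, values, genotypes) -> "GroupedSample":
        """Build from a flat trait vector and 0/1/2 risk-allele counts."""
        values = _as_finite_vector(values, "trait values")
        genotypes = np.asarray(genotypes)
        if genotypes.shape != values.shape:
            raise ValueError("values and genotypes must have the same length")
        return cls(tuple(values[genotypes == g] for g in (0, 1, 2)))

    @property
    def n(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups])

    @property
    def N(self) -> int:
        return int(self.n.sum())

    def require_variance_estimable(self) -> None:
        if np.any(self.n < 2):
            raise ValueError(
                f"variance not estimable: every genotype group needs n >= 2, got n = {tuple(self.n)}"
            )

    def transform(self, func) -> "GroupedSample":
        return GroupedSample(tuple(func(g) for g in self.groups))


@dataclass
class EffectEstimate:
    """Unweighted relative effects and the covariance of their estimator.

    ``p_hat`` sums to 3/2 by construction (each effect is measured against the
    unweighted mean distribution). ``V_hat`` estimates the covariance of
    ``sqrt(N) (p_hat - p)``; ``group_contrib`` holds the per-genotype-group
    summands of ``V_hat`` (needed for Satterthwaite degrees of freedom).
    """

    p_hat: np.ndarray
    w_hat: np.ndarray
    pseudo_ranks: np.ndarray
    n: np.ndarray
    N: int
    V_hat: np.ndarray | None = None
    group_contrib: list[np.ndarray] | None = field(default=None)


def midranks(values) -> np.ndarray:
    """Mid-ranks: tied values receive the average of the ranks they span."""
    x = _as_finite_vector(values)
    return rankdata(x, method="average")


def _edf_at(sample_sorted: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Mid empirical distribution function of ``sample`` evaluated at ``x``."""
    lo = np.searchsorted(sample_sorted, x, side="left")
    hi = np.searchsorted(sample_sorted, x, side="right")
    return (lo + hi) / (2.0 * sample_sorted.size)


def pairwise_placements(sample_i, sample_j) -> np.ndarray:
    """Placements ``F_j(X_ik)`` of the observations of group i within group j.

    Equals ``(rank of X_ik in the pooled sample i+j  -  rank within i) / n_j``
    with mid-ranks throughout; every value lies in [0, 1].
    """
    xi = _as_finite_vector(sample_i, "sample_i")
    xj = _as_finite_vector(sample_j, "sample_j")
    return _edf_at(np.sort(xj), xi)


def pairwise_effect(sample_i, sample_j) -> float:
    """Two-sample relative effect ``w_ij = P(X_i < X_j) + 0.5 P(X_i = X_j)``.

    Estimated by the mean placement of sample j within sample i; satisfies
    ``w_ij + w_ji = 1`` and equals the Mann-Whitney U statistic (ties counted
    half) divided by ``n_i * n_j``.
    """
    xi = _as_finite_vector(sample_i, "sample_i")
    xj = _as_finite_vector(sample_j, "sample_j")
    return float(np.mean(_edf_at(np.sort(xi), xj)))


def _placement_table(gs: GroupedSample) -> list[list[np.ndarray]]:
    """F[j][g] = EDF of group j evaluated at the observations of group g."""
    sorted_groups = [np.sort(g) for g in gs.groups]
    return [[_edf_at(sorted_groups[j], gs.groups[g]) for g in range(3)] for j in range(3)]


def pseudo_ranks(grouped: GroupedSample) -> np.ndarray:
    """Pseudo-ranks ``1/2 + N * G(X_ik)`` with ``G`` the unweighted mean EDF.

    In balanced designs (n1 = n2 = n3) these coincide exactly with the global
    mid-ranks of the pooled sample, and are computed as such so the identity
    holds to the last bit. Returned in group order, observations in input
    order within each group.
    """
    n = grouped.n
    if n[0] == n[1] == n[2]:
        return midranks(np.concatenate(grouped.groups))
    F = _placement_table(grouped)
    N = grouped.N
    out = [0.5 + N * (F[0][g] + F[1][g] + F[2][g]) / 3.0 for g in range(3)]
    return np.concatenate(out)


def estimate_effects(grouped: GroupedSample) -> EffectEstimate:
    """Unweighted relative effects ``p_i`` and the pairwise effect matrix.

    ``p_i = (mean pseudo-rank of group i - 1/2) / N``, equivalently
    ``(1/3) (1/2 + sum_{j != i} w_ji)``; the three effects sum to 3/2.
    """
    F = _placement_table(grouped)
    N = grouped.N
    # w[i, j] = mean placement of group j inside group i = P(X_i < X_j) + ties/2
    w = np.array([[float(np.mean(F[i][j])) for j in range(3)] for i in range(3)])
    psr = pseudo_ranks(grouped)
    splits = np.cumsum(grouped.n)[:-1]
    p_hat = np.array([float(np.mean(r)) for r in np.split(psr, splits)])
    p_hat = (p_hat - 0.5) / N
    return EffectEstimate(p_hat=p_hat, w_hat=w, pseudo_ranks=psr, n=grouped.n, N=N)


def estimate_covariance(grouped: GroupedSample, effects: EffectEstimate) -> EffectEstimate:
    """Covariance of ``sqrt(N)(p_hat - p)`` via the influence decomposition.

    Writing ``p_hat_m - p_m ~ sum_g (1/n_g) sum_k u^{(m)}_{gk}`` with
    influence terms

    * own group:    ``u^{(m)}_{mk} = (1/3) sum_{j != m} (F_j(X_mk) - w_jm)``
    * other groups: ``u^{(m)}_{gk} = -(1/3) (F_m(X_gk) - w_mg)``

    the estimator is ``V_hat[m, m'] = N sum_g [n_g (n_g - 1)]^{-1}
    sum_k u^{(m)}_{gk} u^{(m')}_{gk}``; each group summand is a scaled Gram
    matrix, hence V_hat is symmetric positive semidefinite. Requires every
    group to contribute within-group variance (n_g >= 2).
    """
    grouped.require_variance_estimable()
    F = _placement_table(grouped)
    w = effects.w_hat
    n, N = grouped.n, grouped.N
    # u[m][g]: influence of group-g observations on p_hat[m] (without 1/n_g)
    u = [[None] * 3 for _ in range(3)]
    for m in range(3):
        own = np.zeros(n[m])
        for j in range(3):
            if j != m:
                # w[j, m] = mean of F_j over group m's observations
                own += F[j][m] - w[j, m]
        u[m][m] = own / 3.0
        for g in range(3):
            if g != m:
                u[m][g] = -(F[m][g] - w[m, g]) / 3.0
    contrib = []
    for g in range(3):
        U = np.vstack([u[m][g] for m in range(3)])  # 3 x n_g
        contrib.append(N / (n[g] * (n[g] - 1.0)) * (U @ U.T))
    effects.group_contrib = contrib
    effects.V_hat = np.sum(contrib, axis=0)
    return effects


def relative_effects(grouped: GroupedSample) -> EffectEstimate:
    """Effects plus covariance in one call (the usual entry point)."""
    return estimate_covariance(grouped, estimate_effects(grouped))
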