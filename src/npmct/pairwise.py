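"""Pairwise-rankings variant of the genetic multiple contrast test.

Instead of contrasts of effects measured against the common mean
distribution, the dominant/additive/recessive effects are expressed directly
as linear combinations of two-sample relative effects ``w_ij`` estimated from
pairwise ranks only:

* dominant:  ``pi_dom = (n1 w_13 + n2 w_23) / (n1 + n2)`` — group 3 (AA)
  against the pooled non-AA sample;
* additive:  ``pi_add = w_13``;
* recessive: ``pi_rec = (n2 w_12 + n3 w_13) / (n2 + n3)`` — the pooled
  carrier sample against group 1 (aa).

The null value of every effect is 1/2. Pairwise effects may be intransitive
(cyclic stochastic dominance), which the global-ranking version cannot
exhibit; a transitivity check is attached to every result and the
global-ranking test remains the recommended default.
"""

from __future__ import annotations

import numpy as np

from .contrasts import MARCUS_LABELS
from .mctp import (
    _DEFAULT_QMC_SEED,
    DEGENERATE_VAR,
    MctpResult,
    equicoordinate_quantile,
    mvt_box_prob,
)
from .ranks import GroupedSample, _placement_table

__all__ = ["pairwise_genetic_effects", "pairwise_mctp_test", "transitivity_check", "PairwiseEffects"]

from dataclasses import dataclass


@dataclass
class PairwiseEffects:
    """Two-sample effect matrix and the three pairwise genetic effects.

    ``w[i, j]`` estimates ``P(X_i < X_j) + 0.5 P(X_i = X_j)`` (so
    ``w[i, j] + w[j, i] = 1``); ``pi`` holds the (dominant, additive,
    recessive) effects with null value 1/2. ``V_hat`` is the covariance of
    ``sqrt(N) (pi_hat - pi)`` from the pairwise influence decomposition and
    ``group_contrib`` its per-group summands.
    """

    w: np.ndarray
    pi: np.ndarray
    V_hat: np.ndarray
    group_contrib: list[np.ndarray]
    n: np.ndarray
    N: int


def _pair_weights(n: np.ndarray) -> list[list[tuple[int, int, float]]]:
    """Each effect as [(i, j, a)] meaning ``sum a * w_ij`` (i < j pairs)."""
    n1, n2, n3 = (float(x) for x in n)
    return [
        [(0, 2, n1 / (n1 + n2)), (1, 2, n2 / (n1 + n2))],  # dominant
        [(0, 2, 1.0)],  # additive
        [(0, 1, n2 / (n2 + n3)), (0, 2, n3 / (n2 + n3))],  # recessive
    ]


def pairwise_genetic_effects(grouped: GroupedSample) -> PairwiseEffects:
    """Estimate the pairwise genetic effects and their covariance.

    ``w_ij`` is the mean placement of group j within group i. The influence
    of an observation on ``w_ij`` is ``(F_i(X_jk) - w_ij)/n_j`` through its
    own sample j and ``-(F_j(X_ik) - w_ji)/n_i`` through sample i; effects
    combine these linearly, and the covariance estimator aggregates the
    per-group Gram matrices exactly as in the global-ranking version.
    """
    grouped.require_variance_estimable()
    F = _placement_table(grouped)
    n, N = grouped.n, grouped.N
    w = np.array([[float(np.mean(F[i][j])) for j in range(3)] for i in range(3)])
    weights = _pair_weights(n)
    pi = np.array([sum(a * w[i, j] for i, j, a in terms) for terms in weights])
    # u[q][g]: influence of group-g observations on pi[q] (without 1/n_g)
    u = [[np.zeros(n[g]) for g in range(3)] for q in range(3)]
    for q, terms in enumerate(weights):
        for i, j, a in terms:
            u[q][j] = u[q][j] + a * (F[i][j] - w[i, j])
            u[q][i] = u[q][i] - a * (F[j][i] - w[j, i])
    contrib = []
    for g in range(3):
        U = np.vstack([u[q][g] for q in range(3)])
        contrib.append(N / (n[g] * (n[g] - 1.0)) * (U @ U.T))
    V = np.sum(contrib, axis=0)
    return PairwiseEffects(w=w, pi=pi, V_hat=V, group_contrib=contrib, n=n, N=N)


def transitivity_check(w) -> tuple[bool, str]:
    """Flag cyclic pairwise dominance among the three groups.

    The configuration is intransitive when the centered effects
    ``w_12 - 1/2``, ``w_23 - 1/2`` and ``w_31 - 1/2`` all share a strict
    sign (1 beats 2 beats 3 beats 1, or the reverse cycle).
    """
    w = np.asarray(w, dtype=float)
    cycle = np.array([w[0, 1], w[1, 2], 1.0 - w[0, 2]]) - 0.5
    if np.all(cycle > 0) or np.all(cycle < 0):
        return True, (
            "intransitive pairwise effects: cyclic stochastic dominance "
            f"(w12={w[0, 1]:.3f}, w23={w[1, 2]:.3f}, w31={1 - w[0, 2]:.3f}); "
            "the global-ranking test is recommended"
        )
    return False, "pairwise effects are transitive"


def pairwise_mctp_test(
    grouped: GroupedSample,
    alpha: float = 0.05,
    approx: str = "t",
    interval: str = "fisher",
    *,
    qmc_seed: int = _DEFAULT_QMC_SEED,
    maxpts: int | None = None,
) -> MctpResult:
    """Max-T test of the three pairwise genetic effects against 1/2.

    Same inferential machinery as the global-ranking test, applied to
    ``pi - 1/2``. Fisher intervals operate on the (-1, 1) rescaling
    ``2 pi - 1`` and are mapped back, so reported bounds stay inside (0, 1).
    """
    eff = pairwise_genetic_effects(grouped)
    n, N = eff.n, eff.N
    delta = eff.pi - 0.5
    var = np.diag(eff.V_hat).copy()
    degen = var < DEGENERATE_VAR
    se = np.where(degen, 0.0, np.sqrt(np.where(degen, 1.0, var) / N))
    scale = np.where(degen, 1.0, np.sqrt(np.where(degen, 1.0, var)))
    R = eff.V_hat / np.outer(scale, scale)
    R[degen, :] = 0.0
    R[:, degen] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    if approx == "t":
        dfs = []
        for q in range(3):
            lam = np.maximum([c[q, q] for c in eff.group_contrib], 0.0)
            tot = float(np.sum(lam))
            if tot < DEGENERATE_VAR:
                continue
            denom = float(np.sum(lam**2 / (n - 1.0)))
            dfs.append(np.inf if denom == 0 else tot**2 / denom)
        df = float(max(2.0, min(dfs))) if dfs else np.inf
    elif approx == "normal":
        df = np.inf
    else:
        raise ValueError(f"unknown approximation {approx!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        if interval == "fisher":
            # statistics and intervals on the atanh(2 pi - 1) scale
            x = np.clip(2.0 * delta, -1 + 1e-12, 1 - 1e-12)
            se_x = 2.0 * se
            T = np.where(degen, 0.0, np.arctanh(x) * (1.0 - x**2) / np.where(degen, 1.0, se_x))
        elif interval == "plain":
            T = np.where(degen, 0.0, delta / np.where(degen, 1.0, se))
        else:
            raise ValueError(f"unknown interval method {interval!r}")
    z = equicoordinate_quantile(R, df, alpha, qmc_seed=qmc_seed, maxpts=maxpts)
    if interval == "fisher":
        x = np.clip(2.0 * delta, -1 + 1e-12, 1 - 1e-12)
        half = z * 2.0 * se / (1.0 - x**2)
        lower = 0.5 * (1.0 + np.tanh(np.arctanh(x) - half))
        upper = 0.5 * (1.0 + np.tanh(np.arctanh(x) + half))
    else:
        lower, upper = eff.pi - z * se, eff.pi + z * se
    # degenerate effects get the uninformative maximal interval (cf. mctp)
    lower = np.where(degen, 0.0, lower)
    upper = np.where(degen, 1.0, upper)
    p = np.ones(3)
    for q in range(3):
        if not degen[q] and abs(T[q]) > 0:
            p[q] = 1.0 - mvt_box_prob(float(abs(T[q])), R, df, qmc_seed=qmc_seed, maxpts=maxpts)
    flagged, note = transitivity_check(eff.w)
    return MctpResult(
        labels=MARCUS_LABELS,
        estimate=eff.pi,
        se=se,
        statistic=np.asarray(T),
        lower=lower,
        upper=upper,
        p_adjusted=p,
        degenerate=degen,
        correlation=R,
        df=float(df),
        quantile=z,
        alpha=alpha,
        approx=approx,
        interval=interval,
        null_value=0.5,
        ranking="pairwise",
        intransitive=flagged,
        n=tuple(int(x) for x in n),
    )
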