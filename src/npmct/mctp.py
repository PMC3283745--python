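"""Max-T multiple contrast tests for relative genetic effects.

Given the three unweighted relative effects and the covariance of their
estimator, each contrast ``delta_q = c_q' p`` is studentized and the vector of
statistics is referred to a central multivariate t distribution with the
estimated correlation matrix (multivariate normal for large samples). The
equicoordinate quantile of that distribution yields simultaneous confidence
intervals, and adjusted p-values are defined through the distribution of the
maximum statistic, so interval decisions and p-value decisions can never
contradict each other.

Two interval/test scales are offered:

* ``plain``  — statistics ``T_q = delta_q / se_q`` and intervals
  ``delta_q +/- z se_q`` (not range preserving: bounds may leave [-1, 1]);
* ``fisher`` — the delta method on the Fisher z scale: statistics
  ``atanh(delta_q) / (se_q / (1 - delta_q^2))`` with intervals mapped back
  through tanh, always inside (-1, 1).

Multivariate t/normal box probabilities are evaluated by randomized
quasi-Monte-Carlo integration with a fixed, configurable seed so that
p-values and quantiles are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import ContrastSpec, all_pairs_matrix, apply_contrasts, marcus_matrix
from .ranks import EffectEstimate, GroupedSample, relative_effects

__all__ = [
    "MctpResult",
    "studentize",
    "satterthwaite_df",
    "equicoordinate_quantile",
    "mvt_box_prob",
    "simultaneous_ci",
    "mctp_test",
]

#: contrast variance (on the sqrt(N) scale) below which a contrast carries no
#: evidence: totally tied data yield statistic 0, p-value 1, degenerate CI.
DEGENERATE_VAR = 1e-12

_DEFAULT_QMC_SEED = 20120221  # fixed for reproducible p-values/quantiles


@dataclass
class MctpResult:
    """Result of a multiple contrast test over the three genetic models.

    Per-contrast arrays are aligned with ``labels``. ``estimate`` holds the
    contrast effects (null value ``null_value``; 0 for contrasts of relative
    effects, 1/2 for the pairwise-ranking effects), ``lower``/``upper`` the
    simultaneous confidence bounds, ``p_adjusted`` the compatible adjusted
    p-values. The global max test rejects iff any adjusted p-value falls
    below ``alpha``, equivalently iff any interval excludes ``null_value``.
    """

    labels: tuple[str, ...]
    estimate: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    p_adjusted: np.ndarray
    degenerate: np.ndarray
    correlation: np.ndarray
    df: float
    quantile: float
    alpha: float
    approx: str
    interval: str
    null_value: float = 0.0
    ranking: str = "global"
    intransitive: bool | None = None
    n: tuple[int, ...] | None = None

    @property
    def p_global(self) -> float:
        return float(np.min(self.p_adjusted))

    @property
    def global_reject(self) -> bool:
        return self.p_global < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.labels),
                "estimate": self.estimate,
                "se": self.se,
                "statistic": self.statistic,
                "lower": self.lower,
                "upper": self.upper,
                "p_adjusted": self.p_adjusted,
                "degenerate": self.degenerate,
            }
        )


def _check_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("invalid correlation matrix")
    if np.min(np.linalg.eigvalsh(R)) < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    return R


def mvt_box_prob(
    b: float,
    R: np.ndarray,
    df: float | None,
    *,
    two_sided: bool = True,
    qmc_seed: int = _DEFAULT_QMC_SEED,
    maxpts: int | None = None,
) -> float:
    """``P(max_q |T_q| <= b)`` (or ``max_q T_q`` one-sided) under mvt(df, R).

    ``df=None`` or ``inf`` selects the multivariate normal. Deterministic for
    a fixed ``qmc_seed``.
    """
    R = _check_correlation(R)
    if b <= 0:
        return 0.0
    q = R.shape[0]
    upper = np.full(q, float(b))
    lower = -upper if two_sided else np.full(q, -np.inf)
    if df is None or np.isinf(df):
        p = stats.multivariate_normal.cdf(
            upper, mean=np.zeros(q), cov=R, allow_singular=True, lower_limit=lower
        )
    else:
        if np.min(np.linalg.eigvalsh(R)) < 1e-10:
            # QMC integration needs a full-rank shape; a 1e-8 shrink toward
            # the identity perturbs box probabilities by < 1e-4.
            R = (1.0 - 1e-8) * R + 1e-8 * np.eye(q)
        kwargs = {} if maxpts is None else {"maxpts": maxpts}
        p = stats.multivariate_t.cdf(
            upper,
            loc=np.zeros(q),
            shape=R,
            df=float(df),
            allow_singular=True,
            lower_limit=lower,
            random_state=np.random.default_rng(qmc_seed),
            **kwargs,
        )
    return float(min(max(p, 0.0), 1.0))


def equicoordinate_quantile(
    R: np.ndarray,
    nu: float | None,
    alpha: float,
    *,
    two_sided: bool = True,
    qmc_seed: int = _DEFAULT_QMC_SEED,
    maxpts: int | None = None,
) -> float:
    """Smallest z with ``P(max_q |T_q| <= z) = 1 - alpha`` under mvt(nu, R)."""
    R = _check_correlation(R)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    q = R.shape[0]
    # Sidak-style bracket: perfect correlation gives the univariate quantile
    # (lower end), independence the Sidak quantile (approximate upper end).
    marg = 1.0 - (1.0 - alpha) ** (1.0 / q)
    tail_lo = alpha / 2 if two_sided else alpha
    tail_hi = marg / 2 if two_sided else marg
    if nu is None or np.isinf(nu):
        lo, hi = stats.norm.isf(tail_lo), stats.norm.isf(tail_hi)
    else:
        lo, hi = stats.t.isf(tail_lo, nu), stats.t.isf(tail_hi, nu)
    lo, hi = max(lo - 0.5, 1e-3), hi + 1.0

    def f(z):
        return (
            mvt_box_prob(z, R, nu, two_sided=two_sided, qmc_seed=qmc_seed, maxpts=maxpts)
            - (1.0 - alpha)
        )

    from scipy.optimize import brentq

    while f(hi) < 0:  # widen in the rare strongly-negative-correlation case
        hi += 1.0
    if f(lo) > 0:
        lo = 1e-3
    return float(brentq(f, lo, hi, xtol=1e-5))


def studentize(
    delta_hat, spec: ContrastSpec, estimate: EffectEstimate, N: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Studentized contrast statistics and their correlation matrix.

    ``se_q = sqrt(c_q' V_hat c_q / N)``, ``T_q = delta_q / se_q``;
    degenerate contrasts (variance below ``DEGENERATE_VAR``) get T = 0 and a
    unit-diagonal, zero-off-diagonal row in the correlation matrix.
    """
    if estimate.V_hat is None:
        raise ValueError("covariance not available; run estimate_covariance first")
    V = estimate.V_hat
    if np.min(np.linalg.eigvalsh((V + V.T) / 2)) < -1e-8 * max(1.0, np.abs(V).max()):
        raise ValueError("covariance matrix is not positive semidefinite")
    C = spec.matrix
    delta = np.asarray(delta_hat, dtype=float)
    cov = C @ V @ C.T
    var = np.diag(cov).copy()
    degen = var < DEGENERATE_VAR
    se = np.sqrt(np.where(degen, np.nan, var) / N)
    T = np.where(degen, 0.0, delta / np.where(degen, 1.0, se))
    scale = np.where(degen, 1.0, np.sqrt(np.where(degen, 1.0, var)))
    R = cov / np.outer(scale, scale)
    R[degen, :] = 0.0
    R[:, degen] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    se = np.where(degen, 0.0, se)
    return T, se, R


def satterthwaite_df(spec: ContrastSpec, group_contrib, n) -> float:
    """Common Welch-Satterthwaite degrees of freedom for the contrast set.

    Per contrast, ``nu_q = (sum_g l_gq)^2 / sum_g l_gq^2 / (n_g - 1)`` with
    ``l_gq = c_q' contrib_g c_q`` the group-g share of the contrast variance.
    The common df is the minimum over non-degenerate contrasts, floored at 2
    (a conservative single-quantile construction). If every contrast is
    degenerate, returns ``inf``.
    """
    n = np.asarray(n)
    C = spec.matrix
    dfs = []
    for q in range(C.shape[0]):
        lam = np.array([C[q] @ contrib @ C[q] for contrib in group_contrib])
        lam = np.maximum(lam, 0.0)
        tot = lam.sum()
        if tot < DEGENERATE_VAR:
            continue
        denom = np.sum(lam**2 / (n - 1.0))
        dfs.append(np.inf if denom == 0 else tot**2 / denom)
    if not dfs:
        return np.inf
    return float(max(2.0, min(dfs)))


def simultaneous_ci(
    delta_hat, se, z: float, method: str = "plain"
) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous confidence bounds ``delta_q -/+ z se_q`` on the chosen scale.

    ``plain`` intervals may leave [-1, 1]; ``fisher`` intervals are computed
    on the atanh scale and mapped back, hence always inside (-1, 1). A zero
    standard error yields the degenerate interval [delta, delta].
    """
    if z <= 0:
        raise ValueError("quantile z must be positive")
    d = np.asarray(delta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if method == "plain":
        return d - z * se, d + z * se
    if method == "fisher":
        if np.any(np.abs(d) >= 1.0):
            warnings.warn("effect at the boundary; clamping for the Fisher transform")
        dc = np.clip(d, -1 + 1e-12, 1 - 1e-12)
        half = z * se / (1.0 - dc**2)
        lo, hi = np.tanh(np.arctanh(dc) - half), np.tanh(np.arctanh(dc) + half)
        return np.where(se == 0, d, lo), np.where(se == 0, d, hi)
    raise ValueError(f"unknown interval method {method!r}")


def _fisher_statistics(delta: np.ndarray, se: np.ndarray, degen: np.ndarray) -> np.ndarray:
    """Statistics on the Fisher z scale, ``atanh(d) (1 - d^2) / se``."""
    dc = np.clip(delta, -1 + 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.arctanh(dc) * (1.0 - dc**2) / se
    return np.where(degen, 0.0, T)


def _max_t_inference(
    delta: np.ndarray,
    se: np.ndarray,
    R: np.ndarray,
    degen: np.ndarray,
    df: float | None,
    alpha: float,
    interval: str,
    qmc_seed: int,
    maxpts: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Shared tail machinery: statistics, quantile, CIs and adjusted p-values."""
    if interval == "fisher":
        T = _fisher_statistics(delta, se, degen)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(degen, 0.0, delta / np.where(degen, 1.0, se))
    z = equicoordinate_quantile(R, df, alpha, qmc_seed=qmc_seed, maxpts=maxpts)
    lower, upper = simultaneous_ci(delta, se, z, method=interval)
    # a degenerate contrast (zero estimated variance) carries no information:
    # uninformative maximal interval, consistent with its p-value of 1
    lower, upper = np.where(degen, -1.0, lower), np.where(degen, 1.0, upper)
    p = np.ones_like(T)
    for q in range(T.size):
        if not degen[q] and np.abs(T[q]) > 0:
            p[q] = 1.0 - mvt_box_prob(
                float(np.abs(T[q])), R, df, qmc_seed=qmc_seed, maxpts=maxpts
            )
    return T, lower, upper, p, z


def mctp_test(
    grouped: GroupedSample,
    contrast_type: str = "marcus",
    alpha: float = 0.05,
    approx: str = "t",
    interval: str = "fisher",
    *,
    qmc_seed: int = _DEFAULT_QMC_SEED,
    maxpts: int | None = None,
) -> MctpResult:
    """Nonparametric multiple contrast test on global (pseudo-)ranks.

    Estimates the unweighted relative effects, applies the Marcus-type or
    all-pairs contrasts, and performs the max-T test with simultaneous
    confidence intervals and compatible adjusted p-values. ``approx='t'``
    (recommended for small samples) uses the common Satterthwaite df;
    ``'normal'`` the multivariate normal limit.
    """
    grouped.require_variance_estimable()
    eff = relative_effects(grouped)
    if contrast_type == "marcus":
        spec = marcus_matrix(*grouped.n)
    elif contrast_type in ("all_pairs", "all-pairs"):
        spec = all_pairs_matrix()
    else:
        raise ValueError(f"unknown contrast type {contrast_type!r}")
    delta = apply_contrasts(spec, eff.p_hat)
    T_plain, se, R = studentize(delta, spec, eff, grouped.N)
    degen = se == 0.0
    if approx == "t":
        df = satterthwaite_df(spec, eff.group_contrib, grouped.n)
    elif approx == "normal":
        df = np.inf
    else:
        raise ValueError(f"unknown approximation {approx!r}")
    T, lower, upper, p, z = _max_t_inference(
        delta, se, R, degen, df, alpha, interval, qmc_seed, maxpts
    )
    return MctpResult(
        labels=spec.labels,
        estimate=delta,
        se=se,
        statistic=T,
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
        n=tuple(int(x) for x in grouped.n),
    )


def global_p_value(
    grouped: GroupedSample,
    contrast_type: str = "marcus",
    approx: str = "t",
    scale: str = "plain",
    *,
    qmc_seed: int = _DEFAULT_QMC_SEED,
    maxpts: int | None = None,
) -> float:
    """Global max-test p-value only (single tail evaluation; used in studies)."""
    grouped.require_variance_estimable()
    eff = relative_effects(grouped)
    spec = marcus_matrix(*grouped.n) if contrast_type == "marcus" else all_pairs_matrix()
    delta = apply_contrasts(spec, eff.p_hat)
    T, se, R = studentize(delta, spec, eff, grouped.N)
    degen = se == 0.0
    if scale == "fisher":
        T = _fisher_statistics(delta, se, degen)
    df = satterthwaite_df(spec, eff.group_contrib, grouped.n) if approx == "t" else np.inf
    tmax = float(np.max(np.abs(T)))
    if tmax == 0.0:
        return 1.0
    return 1.0 - mvt_box_prob(tmax, R, df, qmc_seed=qmc_seed, maxpts=maxpts)
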