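"""Genotype-phenotype simulation study: type-I error and power.

Genotypes arise from a two-locus haplotype model: a trait locus with
risk-allele frequency ``q1`` and a marker locus with allele frequency ``q2``,
linked with linkage-disequilibrium coefficient ``delta`` (the deviation of
the risk-risk haplotype frequency from the product ``q1 q2``). Each subject
receives two haplotypes drawn independently (random mating, HWE), so the
marker genotype — the grouping variable seen by all tests — is an imperfect
surrogate for the trait genotype that actually shifts the phenotype.

Phenotypes follow the variance-explained model: genotypic values
``(0, a, 2a)`` (additive), ``(0, a, a)`` (dominant) or ``(0, 0, a)``
(recessive) at the trait locus, with ``a`` scaled so that the genetic
variance under HWE accounts for a fraction ``h2`` of the total phenotypic
variance; residuals are N(0, sigma2). Log-normal traits are produced by the
quantile transform ``Q_LN(Phi(Y))`` of the normal draw Y — a strictly
increasing map, so every rank-based test gives bit-identical decisions for
the normal and log-normal versions of the same underlying draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import all_pairs_matrix, marcus_matrix
from .mctp import _DEFAULT_QMC_SEED, global_p_value, mvt_box_prob
from .pairwise import pairwise_mctp_test
from .ranks import GroupedSample

__all__ = [
    "Scenario",
    "StudyResult",
    "delta_max",
    "haplotype_frequencies",
    "draw_genotypes",
    "genotypic_values",
    "draw_phenotypes",
    "comparator_test",
    "run_study",
]

MODES = ("additive", "dominant", "recessive")


def delta_max(q1: float, q2: float) -> float:
    """Upper feasibility bound of the LD coefficient for given frequencies."""
    return min(q1 * (1 - q2), (1 - q1) * q2)


def delta_min(q1: float, q2: float) -> float:
    return max(-q1 * q2, -(1 - q1) * (1 - q2))


@dataclass(frozen=True)
class Scenario:
    """Parameters of one simulation setting.

    ``h2 = 0`` makes the study a type-I error estimate, ``h2 > 0`` a power
    estimate. ``delta`` must lie in the feasible interval determined by the
    allele frequencies (all four haplotype frequencies non-negative).
    """

    N: int = 500
    q1: float = 0.3
    q2: float = 0.3
    delta: float = 0.105
    h2: float = 0.0
    mode: str = "additive"
    dist: str = "normal"
    sigma2: float = 1.0
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q1 < 1 and 0 < self.q2 < 1):
            raise ValueError("allele frequencies must lie in (0, 1)")
        lo, hi = delta_min(self.q1, self.q2), delta_max(self.q1, self.q2)
        if not lo <= self.delta <= hi:
            raise ValueError(
                f"delta={self.delta} infeasible for q1={self.q1}, q2={self.q2}; "
                f"feasible interval is [{lo:.4g}, {hi:.4g}]"
            )
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.dist not in ("normal", "lognormal"):
            raise ValueError("dist must be 'normal' or 'lognormal'")
        if self.N < 3:
            raise ValueError("N must be at least 3")

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


@dataclass
class StudyResult:
    """Rejection rates per method for one scenario."""

    scenario: Scenario
    alpha: float
    reps: int
    rates: dict[str, float]
    redraws: int = 0
    decisions: dict[str, np.ndarray] | None = None

    def mc_se(self, method: str) -> float:
        r = self.rates[method]
        return float(np.sqrt(r * (1.0 - r) / self.reps))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": list(self.rates),
                "rejection_rate": list(self.rates.values()),
                "mc_se": [self.mc_se(m) for m in self.rates],
                "reps": self.reps,
            }
        )


def haplotype_frequencies(q1: float, q2: float, delta: float) -> np.ndarray:
    """Frequencies of haplotypes (AB, Ab, aB, ab); A/B are the risk alleles."""
    lo, hi = delta_min(q1, q2), delta_max(q1, q2)
    if not lo <= delta <= hi:
        raise ValueError(f"delta must lie in [{lo:.4g}, {hi:.4g}] for these frequencies")
    f = np.array(
        [
            q1 * q2 + delta,
            q1 * (1 - q2) - delta,
            (1 - q1) * q2 - delta,
            (1 - q1) * (1 - q2) + delta,
        ]
    )
    return np.clip(f, 0.0, None) / np.clip(f, 0.0, None).sum()


def draw_genotypes(scenario: Scenario, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (trait, marker) genotypes in risk-allele copies for N subjects."""
    f = haplotype_frequencies(scenario.q1, scenario.q2, scenario.delta)
    hap = rng.choice(4, size=(scenario.N, 2), p=f)
    trait = np.sum(hap < 2, axis=1)  # haplotypes 0, 1 carry the trait risk allele
    marker = np.sum((hap == 0) | (hap == 2), axis=1)  # haplotypes 0, 2 carry the marker allele
    return trait, marker


def genotypic_values(mode: str, h2: float, q1: float, sigma2: float = 1.0) -> np.ndarray:
    """Genotypic means (mu_aa, mu_aA, mu_AA) realizing variance explained h2.

    The displacement ``a`` solves ``Vg / (Vg + sigma2) = h2`` with the
    genetic variance under HWE at the trait locus: ``2 q (1 - q) a^2``
    (additive), ``c (1 - c) a^2`` with carrier probability
    ``c = 1 - (1 - q)^2`` (dominant), ``r (1 - r) a^2`` with ``r = q^2``
    (recessive).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if h2 == 0.0:
        return np.zeros(3)
    if mode == "additive":
        factor = 2.0 * q1 * (1.0 - q1)
        pattern = np.array([0.0, 1.0, 2.0])
    elif mode == "dominant":
        c = 1.0 - (1.0 - q1) ** 2
        factor = c * (1.0 - c)
        pattern = np.array([0.0, 1.0, 1.0])
    elif mode == "recessive":
        r = q1**2
        factor = r * (1.0 - r)
        pattern = np.array([0.0, 0.0, 1.0])
    else:
        raise ValueError(f"mode must be one of {MODES}")
    a = np.sqrt(h2 * sigma2 / ((1.0 - h2) * factor))
    return a * pattern


def draw_phenotypes(
    trait_genotypes: np.ndarray,
    values: np.ndarray,
    dist: str,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes: normal ``mu_g + eps`` or its log-normal quantile transform."""
    y = values[trait_genotypes] + rng.normal(0.0, np.sqrt(sigma2), size=trait_genotypes.size)
    if dist == "normal":
        return y
    if dist == "lognormal":
        u = np.clip(stats.norm.cdf(y), 1e-15, 1.0 - 1e-15)
        return np.exp(stats.norm.ppf(u))  # standard log-normal quantile function
    raise ValueError("dist must be 'normal' or 'lognormal'")


def _scores_and_values(grouped: GroupedSample) -> tuple[np.ndarray, np.ndarray]:
    values = np.concatenate(grouped.groups)
    scores = np.repeat([0.0, 1.0, 2.0], grouped.n)
    return scores, values


def _parametric_mctp_p(
    grouped: GroupedSample, pooled: bool, contrast_type: str, qmc_seed: int
) -> float:
    """Global p of the parametric mean-contrast max-T test.

    ``pooled=True`` is the homoscedastic (pooled-variance, df = N - 3)
    version; ``pooled=False`` the heteroscedastic plug-in with per-contrast
    Satterthwaite df (minimum taken as the common df).
    """
    n, N = grouped.n, grouped.N
    means = np.array([np.mean(g) for g in grouped.groups])
    variances = np.array([np.var(g, ddof=1) for g in grouped.groups])
    C = (marcus_matrix(*n) if contrast_type == "marcus" else all_pairs_matrix()).matrix
    delta = C @ means
    if pooled:
        s2 = float(np.sum((n - 1) * variances) / (N - 3))
        cov = s2 * (C * (1.0 / n)) @ C.T
        df = float(N - 3)
    else:
        d = variances / n
        cov = (C * d) @ C.T
        dfs = []
        for q in range(C.shape[0]):
            v = C[q] ** 2 * d
            tot = v.sum()
            if tot <= 0:
                continue
            dfs.append(tot**2 / np.sum(v**2 / (n - 1.0)))
        df = float(max(2.0, min(dfs))) if dfs else np.inf
    var = np.diag(cov)
    if np.all(var < 1e-24):
        return 1.0
    se = np.sqrt(np.where(var > 0, var, np.inf))
    T = delta / se
    scale = np.where(var > 0, np.sqrt(var), 1.0)
    R = cov / np.outer(scale, scale)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    tmax = float(np.max(np.abs(T)))
    if tmax == 0.0:
        return 1.0
    return 1.0 - mvt_box_prob(tmax, R, df, qmc_seed=qmc_seed)


def comparator_test(
    grouped: GroupedSample,
    method: str,
    alpha: float = 0.05,
    contrast_type: str = "marcus",
    *,
    qmc_seed: int = _DEFAULT_QMC_SEED,
) -> tuple[bool, float]:
    """Global-test decision and p-value of a reference procedure.

    Methods: ``kw`` (tie-corrected Kruskal-Wallis), ``anova`` (one-way F),
    ``trend_reg`` (t-test on the slope of trait on 0/1/2 scores),
    ``mctp_param_homo`` (pooled-variance mean-contrast max-T),
    ``mctp_param_hetero`` (heteroscedastic Satterthwaite plug-in max-T).
    """
    if method == "kw":
        p = float(stats.kruskal(*grouped.groups).pvalue)
    elif method == "anova":
        p = float(stats.f_oneway(*grouped.groups).pvalue)
    elif method == "trend_reg":
        scores, values = _scores_and_values(grouped)
        p = float(stats.linregress(scores, values).pvalue)
    elif method == "mctp_param_homo":
        p = _parametric_mctp_p(grouped, True, contrast_type, qmc_seed)
    elif method == "mctp_param_hetero":
        p = _parametric_mctp_p(grouped, False, contrast_type, qmc_seed)
    else:
        raise ValueError(f"unknown comparator method {method!r}")
    if np.isnan(p):  # constant data make F/KW undefined: no evidence
        p = 1.0
    return p < alpha, p


def _method_decision(name, grouped, alpha, qmc_seed, rng) -> bool:
    if callable(name):
        return bool(name(grouped, alpha, rng))
    if name == "mctp_marcus":
        return global_p_value(grouped, "marcus", "t", qmc_seed=qmc_seed) < alpha
    if name == "mctp_marcus_fisher":
        return global_p_value(grouped, "marcus", "t", "fisher", qmc_seed=qmc_seed) < alpha
    if name == "mctp_allpairs":
        return global_p_value(grouped, "all_pairs", "t", qmc_seed=qmc_seed) < alpha
    if name == "mctp_allpairs_fisher":
        return global_p_value(grouped, "all_pairs", "t", "fisher", qmc_seed=qmc_seed) < alpha
    if name == "mctp_pairwise":
        return pairwise_mctp_test(grouped, alpha, "t", "plain", qmc_seed=qmc_seed).global_reject
    if name in ("kw", "anova", "trend_reg"):
        return comparator_test(grouped, name, alpha, qmc_seed=qmc_seed)[0]
    if name == "param_homo_marcus":
        return comparator_test(grouped, "mctp_param_homo", alpha, "marcus", qmc_seed=qmc_seed)[0]
    if name == "param_homo_allpairs":
        return comparator_test(grouped, "mctp_param_homo", alpha, "all_pairs", qmc_seed=qmc_seed)[0]
    if name == "param_hetero_marcus":
        return comparator_test(grouped, "mctp_param_hetero", alpha, "marcus", qmc_seed=qmc_seed)[0]
    if name == "param_hetero_allpairs":
        return comparator_test(
            grouped, "mctp_param_hetero", alpha, "all_pairs", qmc_seed=qmc_seed
        )[0]
    raise ValueError(f"unknown method {name!r}")


def run_study(
    scenario: Scenario,
    methods: list,
    alpha: float = 0.05,
    *,
    qmc_seed: int = _DEFAULT_QMC_SEED,
    keep_decisions: bool = False,
) -> StudyResult:
    """Monte-Carlo rejection rates of the global tests under one scenario.

    Per replicate: draw genotypes and phenotypes, group the trait by marker
    genotype, apply each method's global test at level ``alpha``. Replicates
    in which some marker genotype class has fewer than 2 subjects are redrawn
    and counted in ``redraws`` (low marker allele frequencies produce
    strongly unbalanced designs where such draws are common). Bit-identical
    results for identical seeds.
    """
    if scenario.reps < 100:
        raise ValueError("reps must be at least 100 for a meaningful rate")
    rng = np.random.default_rng(scenario.seed)
    values = genotypic_values(scenario.mode, scenario.h2, scenario.q1, scenario.sigma2)
    flags = np.zeros((len(methods), scenario.reps), dtype=bool)
    redraws = 0
    for rep in range(scenario.reps):
        while True:
            trait, marker = draw_genotypes(scenario, rng)
            counts = np.bincount(marker, minlength=3)
            if np.all(counts >= 2):
                break
            redraws += 1
        y = draw_phenotypes(trait, values, scenario.dist, scenario.sigma2, rng)
        grouped = GroupedSample.from_arrays(y, marker)
        for i, m in enumerate(methods):
            flags[i, rep] = _method_decision(m, grouped, alpha, qmc_seed, rng)
    names = [
        m if isinstance(m, str) else getattr(m, "__name__", f"method_{i}")
        for i, m in enumerate(methods)
    ]
    rates = {name: float(flags[i].mean()) for i, name in enumerate(names)}
    decisions = {name: flags[i].copy() for i, name in enumerate(names)} if keep_decisions else None
    return StudyResult(
        scenario=scenario,
        alpha=alpha,
        reps=scenario.reps,
        rates=rates,
        redraws=redraws,
        decisions=decisions,
    )
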