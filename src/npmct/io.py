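"""Reading phenotype-genotype tables, writing results, fixture generation.

TSV is the primary interchange format: columns ``id``, ``trait``,
``genotype`` with the genotype given either as 0/1/2 risk-allele copies or
as an allele-pair string (``AG``, ``A/G``) resolved against a declared risk
allele. Single-SNP extraction from a VCF plus a phenotype TSV is supported
through cyvcf2. Rows with a missing trait or genotype are dropped and
counted; no imputation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mctp import MctpResult
from .ranks import GroupedSample

__all__ = ["Dataset", "read_dataset", "write_results", "result_from_json", "generate_fixture"]

log = logging.getLogger("npmct")

_FIXTURE_KINDS = ("null", "dominant", "additive", "recessive", "tied", "unbalanced")


@dataclass
class Dataset:
    """A cleaned subject table: id, trait value, genotype in {0, 1, 2}."""

    table: pd.DataFrame
    n_dropped: int = 0

    def grouped(self) -> GroupedSample:
        return GroupedSample.from_arrays(
            self.table["trait"].to_numpy(float), self.table["genotype"].to_numpy(int)
        )


def _code_genotype(raw, risk_allele: str | None) -> int | None:
    """Risk-allele copy count from a numeric code or an allele-pair string."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.upper() in ("NA", "NAN", "."):
        return None
    if re.fullmatch(r"[012]", s):
        return int(s)
    alleles = [a for a in re.split(r"[/|]", s) if a] if ("/" in s or "|" in s) else list(s)
    if len(alleles) != 2:
        raise ValueError(f"cannot parse genotype {raw!r}")
    if risk_allele is None:
        raise ValueError("allele-string genotypes require --risk-allele")
    return sum(a.upper() == risk_allele.upper() for a in alleles)


def _validate_classes(genotypes: np.ndarray) -> None:
    counts = np.bincount(genotypes, minlength=3)
    if np.any(counts == 0):
        raise ValueError(
            f"all three genotype classes must be present; counts = {tuple(counts)}"
        )
    if np.any(counts < 2):
        raise ValueError(
            f"every genotype class needs at least 2 subjects; counts = {tuple(counts)}"
        )


def _read_tsv(path, risk_allele) -> Dataset:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "trait", "genotype"} - set(df.columns)
    if missing:
        raise ValueError(f"TSV is missing required columns: {sorted(missing)}")
    coded, keep = [], []
    for idx, row in df.iterrows():
        trait = row["trait"]
        try:
            g = _code_genotype(row["genotype"], risk_allele)
        except ValueError as exc:
            if "risk-allele" in str(exc):
                raise
            g = None
        if g is None or pd.isna(trait) or not np.isfinite(float(trait)):
            continue
        coded.append(g)
        keep.append(idx)
    out = df.loc[keep, ["id", "trait"]].copy()
    out["trait"] = out["trait"].astype(float)
    out["genotype"] = coded
    n_dropped = len(df) - len(out)
    if n_dropped:
        log.info("dropped %d rows with missing trait or genotype", n_dropped)
    return Dataset(out.reset_index(drop=True), n_dropped)


def _read_vcf(vcf_path, snp_id, pheno_path, risk_allele) -> Dataset:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variant = None
    for v in vcf:
        if v.ID == snp_id:
            variant = v
            break
    if variant is None:
        raise ValueError(f"SNP {snp_id!r} not found in {vcf_path}")
    if len(variant.ALT) != 1:
        raise ValueError(f"SNP {snp_id!r} is not biallelic")
    alleles = [variant.REF, variant.ALT[0]]
    if risk_allele is None or risk_allele.upper() == "ALT":
        risk_idx = 1
    elif risk_allele.upper() == "REF":
        risk_idx = 0
    elif risk_allele.upper() in (a.upper() for a in alleles):
        risk_idx = [a.upper() for a in alleles].index(risk_allele.upper())
    else:
        raise ValueError(f"risk allele {risk_allele!r} is not one of {alleles}")
    geno = {}
    for sample, gt in zip(samples, variant.genotypes):
        a, b = gt[0], gt[1]
        geno[sample] = None if a < 0 or b < 0 else int(a == risk_idx) + int(b == risk_idx)
    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"id": str})
    if not {"id", "trait"} <= set(pheno.columns):
        raise ValueError("phenotype TSV needs columns 'id' and 'trait'")
    rows = []
    for _, row in pheno.iterrows():
        g = geno.get(row["id"])
        if g is None or pd.isna(row["trait"]):
            continue
        rows.append((row["id"], float(row["trait"]), g))
    out = pd.DataFrame(rows, columns=["id", "trait", "genotype"])
    return Dataset(out, len(pheno) - len(out))


def read_dataset(
    path,
    format: str = "tsv",
    risk_allele: str | None = None,
    *,
    snp_id: str | None = None,
    pheno_path=None,
) -> tuple[Dataset, GroupedSample]:
    """Load a phenotype-genotype table and split it into genotype groups."""
    if format == "tsv":
        ds = _read_tsv(path, risk_allele)
    elif format == "vcf":
        if snp_id is None or pheno_path is None:
            raise ValueError("VCF input requires snp_id and pheno_path")
        ds = _read_vcf(path, snp_id, pheno_path, risk_allele)
    else:
        raise ValueError(f"unknown format {format!r}")
    if ds.table.empty:
        raise ValueError("no usable rows after filtering")
    _validate_classes(ds.table["genotype"].to_numpy(int))
    return ds, ds.grouped()


def _result_dict(result: MctpResult) -> dict:
    return {
        "contrasts": [
            {
                "model": lbl,
                "estimate": float(result.estimate[q]),
                "se": float(result.se[q]),
                "statistic": float(result.statistic[q]),
                "lower": float(result.lower[q]),
                "upper": float(result.upper[q]),
                "p_adjusted": float(result.p_adjusted[q]),
                "degenerate": bool(result.degenerate[q]),
            }
            for q, lbl in enumerate(result.labels)
        ],
        "correlation": np.asarray(result.correlation).tolist(),
        "df": float(result.df),
        "quantile": float(result.quantile),
        "alpha": float(result.alpha),
        "approx": result.approx,
        "interval": result.interval,
        "null_value": float(result.null_value),
        "ranking": result.ranking,
        "intransitive": result.intransitive,
        "n": list(result.n) if result.n is not None else None,
        "p_global": result.p_global,
        "global_reject": bool(result.global_reject),
    }


def write_results(result: MctpResult, path, format: str = "tsv") -> Path:
    """Write one row per contrast plus a global-decision footer.

    The TSV mirrors the conventional report layout (model, effect estimate,
    simultaneous interval, adjusted p); JSON is a lossless round-trip of the
    full result.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_result_dict(result), indent=2) + "\n")
        return path
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    level = int(round(100 * (1 - result.alpha)))
    lines = ["\t".join(["Model", "Effect-Estimator", f"{level}%-Simultaneous Intervals", "Adjusted p-Value"])]
    for q, lbl in enumerate(result.labels):
        lines.append(
            "\t".join(
                [
                    lbl.capitalize(),
                    f"{result.estimate[q]:.6g}",
                    f"[{result.lower[q]:.6g}; {result.upper[q]:.6g}]",
                    f"{result.p_adjusted[q]:.6g}",
                ]
            )
        )
    lines.append(
        f"# global max test: {'reject' if result.global_reject else 'retain'} "
        f"at alpha={result.alpha:g} (p = {result.p_global:.6g}, df = {result.df:g}, "
        f"quantile = {result.quantile:.4f})"
    )
    path.write_text("\n".join(lines) + "\n")
    return path


def result_from_json(path) -> MctpResult:
    """Rebuild an ``MctpResult`` from its JSON serialization."""
    d = json.loads(Path(path).read_text())
    rows = d["contrasts"]
    return MctpResult(
        labels=tuple(r["model"] for r in rows),
        estimate=np.array([r["estimate"] for r in rows]),
        se=np.array([r["se"] for r in rows]),
        statistic=np.array([r["statistic"] for r in rows]),
        lower=np.array([r["lower"] for r in rows]),
        upper=np.array([r["upper"] for r in rows]),
        p_adjusted=np.array([r["p_adjusted"] for r in rows]),
        degenerate=np.array([r["degenerate"] for r in rows]),
        correlation=np.array(d["correlation"]),
        df=d["df"],
        quantile=d["quantile"],
        alpha=d["alpha"],
        approx=d["approx"],
        interval=d["interval"],
        null_value=d["null_value"],
        ranking=d["ranking"],
        intransitive=d["intransitive"],
        n=tuple(d["n"]) if d["n"] is not None else None,
    )


def generate_fixture(kind: str, n: int, seed: int, path=None) -> pd.DataFrame:
    """Deterministic synthetic datasets exercising every test surface.

    ``n`` is the per-genotype-class size except for ``unbalanced``, where the
    class sizes mimic a low marker allele frequency. ``tied`` produces
    ordered-categorical-like data with at most 5 distinct values; group
    distributions follow the named mode of inheritance (effect size 1 on a
    unit-variance scale).
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {_FIXTURE_KINDS}")
    if n < 2:
        raise ValueError("need at least 2 subjects per genotype class")
    rng = np.random.default_rng(seed)
    shift = {"null": (0, 0, 0), "dominant": (0, 1, 1), "additive": (0, 0.5, 1), "recessive": (0, 0, 1)}
    if kind == "tied":
        sizes = (n, n, n)
        probs = [np.array([0.35, 0.3, 0.2, 0.1, 0.05]), np.array([0.2, 0.25, 0.25, 0.2, 0.1]), np.array([0.1, 0.15, 0.25, 0.3, 0.2])]
        groups = [rng.choice(5, size=n, p=p).astype(float) for p in probs]
    elif kind == "unbalanced":
        q = 0.1  # rare marker allele: HWE class probabilities (0.81, 0.18, 0.01)
        total = 3 * n
        sizes = (
            max(2, int(round(total * (1 - q) ** 2))),
            max(2, int(round(total * 2 * q * (1 - q)))),
            2,
        )
        groups = [rng.normal(0.0, 1.0, size=s) for s in sizes]
    else:
        sizes = (n, n, n)
        mu = shift[kind]
        groups = [rng.normal(m, 1.0, size=n) for m, s in zip(mu, sizes)]
    rows = []
    sid = 1
    for g, vals in enumerate(groups):
        for v in vals:
            rows.append((f"S{sid:04d}", float(v), g))
            sid += 1
    df = pd.DataFrame(rows, columns=["id", "trait", "genotype"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
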