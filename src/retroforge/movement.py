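"""Chromosomal gene-traffic analysis.

Classifies parent→retrocopy movements (interchromosomal, intrachromosomal,
scaffold/MT), selects functional and neutral interchromosomal pair sets,
regresses per-chromosome counts on chromosome covariates (gene count,
length), and tests whether the X chromosome is an outlier via the
externally studentized residual of X against an autosome-only fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .discovery import RetrocopyRecord
from .io_formats import GeneModel, GenomeAssembly
from .kaks import KaKsResult


@dataclass
class MovementRecord:
    retro_id: str
    parent_gene: str
    parent_chrom: str
    retro_chrom: str
    category: str  # interchromosomal | intrachromosomal | scaffold_mt
    cls: str
    omega: float | None


@dataclass
class RegressionResult:
    covariate: str
    slope: float
    intercept: float
    pearson_r: float
    n_points: int
    residuals: dict[str, float]
    x_chrom: str | None = None
    x_studentized: float | None = None
    x_pvalue: float | None = None
    x_direction: str | None = None  # "excess" | "deficit"


def classify_movement(
    parent_chrom: str, retro_chrom: str, genome: GenomeAssembly
) -> str:
    """interchromosomal / intrachromosomal / scaffold_mt for one pair."""
    meta = genome.metadata
    p_scaf = meta[parent_chrom].is_scaffold_or_mt if parent_chrom in meta else True
    r_scaf = meta[retro_chrom].is_scaffold_or_mt if retro_chrom in meta else True
    if p_scaf or r_scaf:
        return "scaffold_mt"
    if parent_chrom == retro_chrom:
        return "intrachromosomal"
    return "interchromosomal"


def movement_records(
    catalogue: list[RetrocopyRecord],
    kaks: dict[str, KaKsResult],
    models: list[GeneModel],
    genome: GenomeAssembly,
) -> list[MovementRecord]:
    model_of_gene = {m.gene_id: m for m in models}
    out = []
    for rec in catalogue:
        parent_chrom = model_of_gene[rec.parent_gene].chrom
        res = kaks.get(rec.retro_id)
        out.append(
            MovementRecord(
                retro_id=rec.retro_id,
                parent_gene=rec.parent_gene,
                parent_chrom=parent_chrom,
                retro_chrom=rec.chrom,
                category=classify_movement(parent_chrom, rec.chrom, genome),
                cls=rec.cls,
                omega=res.omega if res is not None else None,
            )
        )
    return out


def movement_fractions(records: list[MovementRecord]) -> pd.DataFrame:
    """Counts and percentages per movement category."""
    if not records:
        raise ValueError("no movement records")
    order = ["interchromosomal", "intrachromosomal", "scaffold_mt"]
    counts = {cat: sum(r.category == cat for r in records) for cat in order}
    total = len(records)
    return pd.DataFrame(
        {
            "category": order,
            "count": [counts[c] for c in order],
            "percent": [100.0 * counts[c] / total for c in order],
        }
    )


def select_sets(
    records: list[MovementRecord],
    functional_omega_max: float = 0.5,
    neutral_omega_range: tuple[float, float] = (0.5, 1.0),
) -> tuple[list[MovementRecord], list[MovementRecord]]:
    """Functional pairs (intact, ω < 0.5) and neutral pairs (pseudogene,
    0.5 < ω < 1.0), both restricted to interchromosomal movements."""
    lo, hi = neutral_omega_range
    functional = [
        r
        for r in records
        if r.category == "interchromosomal"
        and r.cls == "intact"
        and r.omega is not None
        and r.omega < functional_omega_max
    ]
    neutral = [
        r
        for r in records
        if r.category == "interchromosomal"
        and r.cls == "pseudogene"
        and r.omega is not None
        and lo < r.omega < hi
    ]
    return functional, neutral


def per_chromosome_counts(
    records: list[MovementRecord], genome: GenomeAssembly, side: str = "parent"
) -> dict[str, int]:
    """Counts of parents (``side='parent'``) or insertions (``'retro'``)
    per primary chromosome."""
    chroms = [
        n for n, m in genome.metadata.items() if not m.is_scaffold_or_mt
    ]
    counts = {c: 0 for c in chroms}
    for r in records:
        chrom = r.parent_chrom if side == "parent" else r.retro_chrom
        if chrom in counts:
            counts[chrom] += 1
    return counts


def regress_counts(
    counts: dict[str, int], covariate: dict[str, float]
) -> RegressionResult:
    """OLS of per-chromosome counts on a covariate over all supplied
    chromosomes (autosomes plus X), with the Pearson r over the same points."""
    chroms = sorted(set(counts) & set(covariate))
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes to regress")
    y = np.array([counts[c] for c in chroms], dtype=float)
    x = np.array([covariate[c] for c in chroms], dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    r = float(st.pearsonr(x, y).statistic) if np.std(x) > 0 and np.std(y) > 0 else 0.0
    resid = dict(zip(chroms, (y - fit.predict(X)).tolist()))
    return RegressionResult(
        covariate="covariate",
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pearson_r=r,
        n_points=len(chroms),
        residuals=resid,
    )


def x_outlier_test(
    counts: dict[str, int],
    covariate: dict[str, float],
    genome: GenomeAssembly,
    x_chrom: str | None = None,
    min_autosomes: int = 5,
) -> RegressionResult:
    """Externally studentized residual test of the X chromosome.

    The OLS line is fit on autosomes only; the X residual against that fit
    is studentized with the out-of-sample prediction standard error and
    referred to a two-sided t distribution with (n_autosomes − 3) degrees
    of freedom. ``x_direction`` reports the residual sign.
    """
    meta = genome.metadata
    if x_chrom is None:
        sex = [n for n, m in meta.items() if m.is_sex_chromosome and not m.is_scaffold_or_mt]
        if not sex:
            raise ValueError("no X chromosome in assembly metadata")
        x_chrom = sorted(sex)[0]
    autosomes = sorted(
        n
        for n, m in meta.items()
        if not m.is_sex_chromosome and not m.is_scaffold_or_mt and n in counts and n in covariate
    )
    if len(autosomes) < min_autosomes:
        raise ValueError(f"only {len(autosomes)} autosomes; X-outlier test undefined")
    if x_chrom not in counts or x_chrom not in covariate:
        raise ValueError(f"{x_chrom} missing from counts/covariate")

    y = np.array([counts[c] for c in autosomes], dtype=float)
    x = np.array([covariate[c] for c in autosomes], dtype=float)
    n = len(autosomes)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    s2 = float(fit.mse_resid)
    xbar = float(x.mean())
    sxx = float(((x - xbar) ** 2).sum())
    x0 = float(covariate[x_chrom])
    pred = float(fit.params[0] + fit.params[1] * x0)
    resid = float(counts[x_chrom]) - pred
    se = np.sqrt(s2 * (1.0 + 1.0 / n + (x0 - xbar) ** 2 / sxx))
    tstat = resid / se if se > 0 else 0.0
    df = n - 3
    p = 2.0 * float(st.t.sf(abs(tstat), df))
    r = float(st.pearsonr(x, y).statistic) if np.std(x) > 0 and np.std(y) > 0 else 0.0
    residuals = dict(zip(autosomes, (y - fit.predict(X)).tolist()))
    residuals[x_chrom] = resid
    return RegressionResult(
        covariate="covariate",
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pearson_r=r,
        n_points=n,
        residuals=residuals,
        x_chrom=x_chrom,
        x_studentized=float(tstat),
        x_pvalue=min(1.0, p),
        x_direction="excess" if resid > 0 else "deficit",
    )


def x_binomial_test(
    counts: dict[str, int],
    covariate: dict[str, float],
    genome: GenomeAssembly,
    x_chrom: str = "chrX",
    alternative: str = "greater",
) -> float:
    """One-sided binomial alternative: X's share of events vs X's share of
    the covariate (e.g. annotated genes)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no events")
    p_expected = covariate[x_chrom] / sum(covariate.values())
    return float(
        st.binomtest(counts.get(x_chrom, 0), total, p_expected, alternative=alternative).pvalue
    )


def dog_like_chromosome_set(
    n_autosomes: int = 38,
    max_genes: int = 1200,
    min_genes: int = 250,
    x_genes: int = 900,
) -> dict[str, float]:
    """A karyotype-shaped covariate: per-chromosome annotated gene counts
    declining linearly across autosomes (the canid pattern of many small
    acrocentric autosomes plus a large X)."""
    cov = {
        f"chr{i + 1}": float(round(max_genes - i * (max_genes - min_genes) / (n_autosomes - 1)))
        for i in range(n_autosomes)
    }
    cov["chrX"] = float(x_genes)
    return cov


def simulate_traffic_counts(
    covariate: dict[str, float],
    n_events: int,
    rng: np.random.Generator,
    x_chrom: str = "chrX",
    x_multiplier: float = 1.0,
) -> dict[str, int]:
    """Place events multinomially with probabilities proportional to the
    covariate, optionally enriching the X chromosome by ``x_multiplier``.
    The null model for X-outlier calibration and power studies."""
    chroms = sorted(covariate)
    w = np.array([covariate[c] for c in chroms], dtype=float)
    w[chroms.index(x_chrom)] *= x_multiplier
    draws = rng.multinomial(n_events, w / w.sum())
    return dict(zip(chroms, draws.tolist()))


def _dummy_assembly(chroms: list[str]) -> GenomeAssembly:
    return GenomeAssembly({c: "A" for c in chroms})


def x_outlier_pvalue(
    counts: dict[str, int], covariate: dict[str, float], x_chrom: str = "chrX"
) -> float:
    """Convenience wrapper running :func:`x_outlier_test` on bare
    count/covariate dicts (chromosome metadata inferred from names)."""
    res = x_outlier_test(counts, covariate, _dummy_assembly(sorted(covariate)), x_chrom)
    return float(res.x_pvalue)


def traffic_analysis(
    catalogue: list[RetrocopyRecord],
    kaks: dict[str, KaKsResult],
    models: list[GeneModel],
    genome: GenomeAssembly,
) -> dict:
    """The full traffic report: movement fractions plus the four
    regressions (parents and insertions × gene-count and length covariates)
    with X-outlier p-values, for the functional and neutral sets."""
    records = movement_records(catalogue, kaks, models, genome)
    fractions = movement_fractions(records) if records else None
    functional, neutral = select_sets(records)
    gene_counts: dict[str, float] = {}
    for m in models:
        gene_counts[m.chrom] = gene_counts.get(m.chrom, 0) + 1
    lengths = {
        n: float(l)
        for n, l in genome.lengths.items()
        if not genome.metadata[n].is_scaffold_or_mt
    }
    for c in lengths:
        gene_counts.setdefault(c, 0)

    tests = {}
    for set_name, recs in (("functional", functional), ("neutral", neutral)):
        for side in ("parent", "retro"):
            counts = per_chromosome_counts(recs, genome, side)
            for cov_name, cov in (("gene_count", gene_counts), ("length", lengths)):
                key = f"{set_name}_{side}_{cov_name}"
                try:
                    res = x_outlier_test(counts, cov, genome)
                    res.covariate = cov_name
                    tests[key] = res
                except ValueError:
                    tests[key] = None
    return {
        "records": records,
        "fractions": fractions,
        "functional": functional,
        "neutral": neutral,
        "tests": tests,
    }
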