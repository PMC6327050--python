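"""Driver-correlated gene programs, overlap enrichment, translocation outliers.

Given a blast expression cohort, the program of a driver gene is the set of
genes whose expression tracks it (Spearman, two-sided, P below a fixed
cut).  Agreement between that program and, e.g., knockdown DE genes is
scored with an upper-tail binomial null: drawing |B| genes from a universe
of N in which |A| are marked, the overlap X ~ Binomial(|B|, |A|/N).  Rare
translocated cases are scored as outliers via Z-scores against the
mean/SD of the non-translocated cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_correlate",
    "correlated_gene_set",
    "overlap_binomial",
    "top_de_genes",
    "translocation_zscore",
    "OverlapResult",
    "OutlierZ",
]


def spearman_correlate(expr: pd.DataFrame, driver: str) -> pd.DataFrame:
    """Spearman correlation of every gene against the driver gene.

    ``expr`` is genes x samples.  Ties get average ranks; rho is Pearson on
    ranks; two-sided p from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)).  |rho| = 1 is flagged exact_monotone
    with p = 0 (the t statistic diverges); constant genes get NaN.
    """
    if driver not in expr.index:
        raise ValueError(f"driver gene {driver!r} not in expression matrix")
    n = expr.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")

    ranks = expr.rank(axis=1)  # average-rank ties
    d = ranks.loc[driver].to_numpy(dtype=float)
    m = ranks.to_numpy(dtype=float)
    d_c = d - d.mean()
    m_c = m - m.mean(axis=1, keepdims=True)
    denom = np.sqrt((m_c**2).sum(axis=1) * (d_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (m_c @ d_c) / denom
    rho = np.clip(rho, -1.0, 1.0)

    exact = np.abs(rho) >= 1.0 - 1e-13
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[exact] = 0.0
    out = pd.DataFrame({"rho": rho, "p": p, "n": n,
                        "exact_monotone": exact & ~np.isnan(rho)},
                       index=expr.index)
    out.index.name = "gene"
    return out


def correlated_gene_set(
    correlations: pd.DataFrame,
    driver: str,
    p_threshold: float = 5e-4,
    adjust: str | None = None,
) -> set[str]:
    """Genes correlated with the driver at p strictly below ``p_threshold``.

    The driver itself and genes with undefined correlation are excluded.
    ``adjust='fdr_bh'`` applies Benjamini-Hochberg before thresholding
    (off by default).
    """
    p = correlations["p"].copy()
    if adjust == "fdr_bh":
        ok = p.notna()
        from statsmodels.stats.multitest import multipletests
        p.loc[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    hit = p.index[(p < p_threshold).fillna(False)]
    return set(hit) - {driver}


@dataclass
class OverlapResult:
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    expected: float
    p: float
    method: str = "binomial"
    overlap_genes: set[str] = field(default_factory=set, repr=False)


def overlap_binomial(
    universe: set[str],
    set_a: set[str],
    set_b: set[str],
    method: str = "binomial",
) -> OverlapResult:
    """Upper-tail enrichment of the overlap between two gene sets.

    P(X >= x) for X ~ Binomial(|B|, |A|/N); the hypergeometric (draw
    without replacement) null is available as an option.  Identifiers are
    deduplicated; sets must be subsets of the universe.
    """
    universe, set_a, set_b = set(universe), set(set_a), set(set_b)
    for label, s in (("set_a", set_a), ("set_b", set_b)):
        stray = s - universe
        if stray:
            raise ValueError(f"{label} not a subset of universe: {sorted(stray)[:10]}")
    n = len(universe)
    if n == 0:
        raise ValueError("universe must be non-empty")
    overlap = set_a & set_b
    x = len(overlap)
    p_success = len(set_a) / n
    expected = len(set_b) * p_success
    if method == "binomial":
        p = float(stats.binom.sf(x - 1, len(set_b), p_success))
    elif method == "hypergeometric":
        p = float(stats.hypergeom.sf(x - 1, n, len(set_a), len(set_b)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapResult(n, len(set_a), len(set_b), x, expected,
                         min(p, 1.0), method, overlap)


def top_de_genes(de_table: pd.DataFrame, k: int = 150,
                 gene_col: str = "gene", p_col: str = "padj",
                 lfc_col: str = "log_fc") -> list[str]:
    """Top-k differentially expressed genes.

    Ranked by ascending adjusted p, ties broken by descending |log fold
    change| then lexicographic gene id.  If k exceeds the table size the
    whole table is returned with a warning.
    """
    for col in (gene_col, p_col, lfc_col):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks required column {col!r}")
    df = de_table.assign(_abs_lfc=de_table[lfc_col].abs())
    df = df.sort_values([p_col, "_abs_lfc", gene_col],
                        ascending=[True, False, True], kind="mergesort")
    if k > len(df):
        warnings.warn(f"k={k} exceeds DE table size {len(df)}; returning all genes")
        k = len(df)
    return df[gene_col].head(k).tolist()


@dataclass
class OutlierZ:
    gene: str
    case_z: dict[str, float]
    mean_z: float
    cohort_mean: float
    cohort_sd: float
    n_cohort: int
    undefined: bool = False


def translocation_zscore(expr: pd.DataFrame, flags: pd.Series, gene: str) -> OutlierZ:
    """Outlier Z-score of flagged (translocated) cases for one gene.

    Cohort mean and sample SD (ddof=1) are computed over non-flagged cases
    only, on the TPM scale; each flagged case's z = (TPM - mean)/SD.  A
    zero-SD cohort is flagged undefined.
    """
    if gene not in expr.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    flags = flags.reindex(expr.columns).fillna(False).astype(bool)
    cohort = expr.loc[gene, ~flags].to_numpy(dtype=float)
    cases = expr.loc[gene, flags]
    if cohort.size < 2:
        raise ValueError("need at least two non-translocated cohort samples")
    mean = float(cohort.mean())
    sd = float(cohort.std(ddof=1))
    if sd == 0:
        return OutlierZ(gene, {c: math.nan for c in cases.index}, math.nan,
                        mean, 0.0, cohort.size, undefined=True)
    zs = {c: float((v - mean) / sd) for c, v in cases.items()}
    mean_z = float(np.mean(list(zs.values()))) if zs else math.nan
    return OutlierZ(gene, zs, mean_z, mean, sd, cohort.size)
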