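"""Copy-number-restricted, genotype-stratified expression testing.

Blasts frequently carry aneuploidies; an eQTL on a gene's own chromosome is
only interpretable in samples disomic for that chromosome, so the first step
filters samples to copy number exactly 2.  The association test is the
tie-corrected Kruskal-Wallis rank test across genotype groups, and the
reported effect size is the fold change between the two homozygote groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KWResult", "FoldResult", "disomy_filter", "kruskal_wallis",
           "homozygote_fold_change"]


@dataclass
class KWResult:
    H: float
    p: float
    group_sizes: list[int]
    group_mean_ranks: list[float]
    n: int


@dataclass
class FoldResult:
    fold: float
    mean_risk: float
    mean_nonrisk: float
    n_risk: int
    n_nonrisk: int
    undefined: bool = False


def disomy_filter(
    samples: list[str],
    copy_number_calls: dict[str, dict[str, int]] | dict[str, int],
    chromosome: str | None = None,
    missing: str = "exclude",
) -> list[str]:
    """Retain samples with copy number exactly 2 for ``chromosome``.

    ``copy_number_calls`` maps sample -> copy number, or sample ->
    {chromosome: copy number} when ``chromosome`` is given.  Samples without
    a call are excluded by default; ``missing='error'`` raises instead.
    """
    if missing not in ("exclude", "error"):
        raise ValueError("missing must be 'exclude' or 'error'")
    kept = []
    for s in samples:
        call = copy_number_calls.get(s)
        if call is not None and chromosome is not None and isinstance(call, dict):
            call = call.get(chromosome)
        if call is None:
            if missing == "error":
                raise ValueError(f"no copy-number call for sample {s!r}")
            continue
        if int(call) == 2:
            kept.append(s)
    return kept


def kruskal_wallis(groups: list[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis test across genotype groups.

    H = [12/(N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with
    (groups - 1) df.  All-identical data returns H = 0, p = 1 (the tie
    correction is degenerate there).  Ranks use average-rank tie handling.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")

    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks, idx = [], 0
    for sz in sizes:
        mean_ranks.append(float(ranks[idx:idx + sz].mean()))
        idx += sz

    h = 12.0 / (n * (n + 1)) * sum(
        sz * (rbar - (n + 1) / 2.0) ** 2 for sz, rbar in zip(sizes, mean_ranks)
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_sum / (n**3 - n)
    if correction <= 0:  # all observations identical
        return KWResult(0.0, 1.0, sizes, mean_ranks, n)
    h /= correction
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return KWResult(float(h), p, sizes, mean_ranks, n)


def kruskal_wallis_by_genotype(values: np.ndarray, dosages: np.ndarray) -> KWResult:
    """Convenience wrapper: group expression values by genotype dosage."""
    values = np.asarray(values, dtype=float)
    dosages = np.asarray(dosages)
    groups = [values[dosages == g] for g in np.unique(dosages)]
    return kruskal_wallis(groups)


def homozygote_fold_change(
    values_by_genotype: dict[int, np.ndarray],
    risk_dosage: int = 2,
    mean: str = "arithmetic",
) -> FoldResult:
    """Fold change of risk-homozygote over non-risk-homozygote expression.

    The non-risk homozygote group is dosage 0 when risk dosage is 2 (and
    vice versa).  Mean type is arithmetic by default; geometric optional.
    An empty homozygote group yields a flagged undefined result.
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    other = 0 if risk_dosage == 2 else 2
    risk = np.asarray(values_by_genotype.get(risk_dosage, []), dtype=float)
    non = np.asarray(values_by_genotype.get(other, []), dtype=float)
    if risk.size == 0 or non.size == 0:
        return FoldResult(math.nan, math.nan, math.nan, risk.size, non.size,
                          undefined=True)
    if mean == "arithmetic":
        m_r, m_n = float(risk.mean()), float(non.mean())
    else:
        m_r = float(np.exp(np.log(risk).mean()))
        m_n = float(np.exp(np.log(non).mean()))
    return FoldResult(m_r / m_n, m_r, m_n, risk.size, non.size)
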