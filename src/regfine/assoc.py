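"""Case/control association, meta-analysis, imputation-quality filtering and LD capture.

The base association test is the classical 2x2 allele-count cross-product
odds ratio with a Woolf standard error on the log scale, matching the
additive per-allele odds ratios reported for GWAS lead SNPs.  Logistic
regression appears only in the conditional analysis, where a
likelihood-ratio test asks whether a candidate SNP carries signal beyond a
covariate dosage (the lead SNP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AssocResult",
    "MetaResult",
    "InfoResult",
    "allelic_association",
    "fixed_effect_meta",
    "info_score",
    "info_filter",
    "ld_r2",
    "ld_block_capture",
    "conditional_association",
]


@dataclass
class AssocResult:
    """Per-variant allelic association summary.

    ``beta`` is the log odds ratio; ``odds_ratio == exp(beta)``.  A
    monomorphic variant yields ``undefined=True`` with NaN estimates rather
    than an exception.
    """

    variant: str
    beta: float
    se: float
    odds_ratio: float
    p: float
    maf: float
    n_cases: int
    n_controls: int
    undefined: bool = False


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect pooled estimate with Cochran heterogeneity."""

    beta: float
    se: float
    p: float
    Q: float
    p_het: float
    k: int
    weights: np.ndarray = field(repr=False, default=None)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass
class InfoResult:
    """IMPUTE-style INFO score for one variant.

    info = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta)) where
    e_i = p_i1 + 2 p_i2 is the expected dosage and f_i = p_i1 + 4 p_i2 the
    expected squared dosage; theta is the frequency estimated from dosages.
    Monomorphic variants (theta in {0, 1}) return 1 by convention.
    """

    variant: str
    theta_hat: float
    info: float


def _allele_counts(dosages: np.ndarray) -> tuple[float, float]:
    """Risk and non-risk allele counts from 0/1/2 dosages."""
    dosages = np.asarray(dosages, dtype=float)
    a = float(dosages.sum())
    return a, 2.0 * dosages.size - a


def allelic_association(
    case_dosages: np.ndarray,
    control_dosages: np.ndarray,
    variant: str = "variant",
) -> AssocResult:
    """Allele-count 2x2 association test.

    Odds ratio is the cross-product ratio of risk/non-risk allele counts in
    cases vs controls; SE via Woolf's formula; two-sided p from the normal
    approximation to the log OR.  Any zero cell triggers the
    Haldane-Anscombe 0.5 continuity correction on all four cells.
    """
    case_dosages = np.asarray(case_dosages, dtype=float)
    control_dosages = np.asarray(control_dosages, dtype=float)
    if case_dosages.size < 1 or control_dosages.size < 1:
        raise ValueError("need at least one case and one control")

    a, b = _allele_counts(case_dosages)  # risk / non-risk alleles in cases
    c, d = _allele_counts(control_dosages)
    n_cases, n_controls = case_dosages.size, control_dosages.size

    total = a + b + c + d
    risk_freq = (a + c) / total
    maf = min(risk_freq, 1.0 - risk_freq)

    if (a + c) == 0 or (b + d) == 0:  # monomorphic across the whole sample
        return AssocResult(variant, math.nan, math.nan, math.nan, math.nan,
                           maf, n_cases, n_controls, undefined=True)

    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5

    beta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return AssocResult(variant, beta, se, math.exp(beta), p, maf,
                       n_cases, n_controls)


def fixed_effect_meta(studies: list[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of (beta, se) pairs.

    Cochran's Q = sum w_i (beta_i - pooled)^2 with w_i = 1/se_i^2 is referred
    to chi-square with k-1 df; for a single study p_het = 1 by the df-0
    convention.
    """
    if len(studies) == 0:
        raise ValueError("meta-analysis requires at least one study")
    betas = np.array([b for b, _ in studies], dtype=float)
    ses = np.array([s for _, s in studies], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")

    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(pooled) / se))
    Q = float(np.sum(w * (betas - pooled) ** 2))
    k = len(studies)
    p_het = 1.0 if k == 1 else float(stats.chi2.sf(Q, k - 1))
    return MetaResult(pooled, se, p, Q, p_het, k, weights=w)


def info_score(posteriors: np.ndarray, variant: str = "variant") -> InfoResult:
    """INFO (imputation quality) score from per-sample genotype posteriors.

    ``posteriors`` is an (N, 3) array of (p0, p1, p2) triples, each summing
    to 1 within 1e-6.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[1] != 3 or post.shape[0] == 0:
        raise ValueError("posteriors must be a non-empty (N, 3) array")
    sums = post.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"posterior triple for sample {bad} sums to {sums[bad]:.8f}, not 1")

    e = post[:, 1] + 2.0 * post[:, 2]
    f = post[:, 1] + 4.0 * post[:, 2]
    n = post.shape[0]
    theta = float(e.sum() / (2.0 * n))
    if theta <= 0.0 or theta >= 1.0:
        return InfoResult(variant, theta, 1.0)
    info = 1.0 - float(np.sum(f - e**2)) / (2.0 * n * theta * (1.0 - theta))
    return InfoResult(variant, theta, float(np.clip(info, 0.0, 1.0)))


def info_filter(info_results: dict[str, InfoResult], info_min: float = 0.8) -> list[str]:
    """Variant ids passing the INFO >= ``info_min`` imputation-quality filter."""
    return [v for v, r in info_results.items() if r.info >= info_min]


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD r^2).

    Returns NaN for a constant vector (undefined, not an exception).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdCapture:
    lead: str
    captured: list[str]
    capture_fraction: float
    r2: dict[str, float]


def ld_block_capture(
    lead: str,
    dosages,  # pandas DataFrame, samples x variants
    r2_min: float = 0.4,
    maf_min: float = 0.01,
) -> LdCapture:
    """Capture the LD block of ``lead``: variants with MAF > maf_min and r^2 >= r2_min.

    The capture fraction is the share of qualifying variants (MAF above
    threshold, r^2 above threshold where computable) whose r^2 is defined;
    variants with undefined r^2 (constant dosage) count as uncaptured.
    """
    if lead not in dosages.columns:
        raise ValueError(f"lead variant {lead!r} not in genotype table")
    lead_dos = dosages[lead].to_numpy(dtype=float)

    captured: list[str] = []
    r2_map: dict[str, float] = {}
    n_undefined_qualifying = 0
    for var in dosages.columns:
        dos = dosages[var].to_numpy(dtype=float)
        af = dos.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf <= maf_min:
            continue
        r2 = ld_r2(lead_dos, dos)
        r2_map[var] = r2
        if math.isnan(r2):
            if var == lead:
                captured.append(var)  # lead trivially in its own block
            else:
                n_undefined_qualifying += 1
            continue
        if r2 >= r2_min:
            captured.append(var)
    denom = len(captured) + n_undefined_qualifying
    fraction = 1.0 if denom == 0 else len(captured) / denom
    return LdCapture(lead, captured, fraction, r2_map)


@dataclass
class ConditionalResult:
    p: float
    lrt: float
    collinear: bool = False
    converged: bool = True


def conditional_association(
    phenotype: np.ndarray,
    test_dosage: np.ndarray,
    covariate_dosage: np.ndarray,
    max_iter: int = 100,
) -> ConditionalResult:
    """Likelihood-ratio test of a SNP conditional on a covariate dosage.

    Compares logistic models {intercept, covariate} vs {intercept,
    covariate, test}.  A test dosage collinear with the covariate
    (|r| > 0.999) is flagged rather than fitted; a constant covariate is
    dropped, reducing to the unconditional LRT.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(test_dosage, dtype=float)
    c = np.asarray(covariate_dosage, dtype=float)
    if not (y.shape == x.shape == c.shape):
        raise ValueError("phenotype, test and covariate must align")

    use_cov = np.ptp(c) > 0
    if use_cov and np.ptp(x) > 0:
        r = np.corrcoef(x, c)[0, 1]
        if abs(r) > 0.999:
            return ConditionalResult(math.nan, math.nan, collinear=True)

    ones = np.ones_like(y)
    x0 = np.column_stack([ones, c]) if use_cov else ones[:, None]
    x1 = np.column_stack([x0, x])
    try:
        fit0 = sm.Logit(y, x0).fit(disp=0, maxiter=max_iter)
        fit1 = sm.Logit(y, x1).fit(disp=0, maxiter=max_iter)
    except Exception:
        return ConditionalResult(math.nan, math.nan, converged=False)
    if not (fit0.mle_retvals.get("converged", True) and fit1.mle_retvals.get("converged", True)):
        return ConditionalResult(math.nan, math.nan, converged=False)
    lrt = 2.0 * (fit1.llf - fit0.llf)
    lrt = max(lrt, 0.0)
    return ConditionalResult(float(stats.chi2.sf(lrt, 1)), float(lrt))
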