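"""ChIP-qPCR quantitation: standard curves, percent input, fold enrichment.

Quantities are interpolated from a dilution-series standard curve fitted as
Cq on log10(quantity); for perfect doubling chemistry the slope is
-1/log10(2) ~ -3.32 and the amplification efficiency 10^(-1/slope) is 2.
ChIP signal is normalised as percent of input chromatin (the input is
measured on an aliquot, hence the input-fraction correction) and expressed
as fold enrichment over the nonspecific-antibody (IgG) control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "standard_curve_fit",
    "interpolate_quantity",
    "percent_input",
    "fold_enrichment",
    "allele_preference_check",
    "replicate_t_test",
]


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    valid: bool = True


def standard_curve_fit(quantities: np.ndarray, cq: np.ndarray) -> StandardCurve:
    """Least-squares fit of Cq on log10(quantity) over a dilution series.

    Requires >= 3 strictly positive, distinct quantities.  A non-negative
    slope (Cq not decreasing with template) flags the curve invalid.
    """
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cq, dtype=float)
    if q.size < 3 or q.size != c.size:
        raise ValueError("need >= 3 matched dilution points")
    if np.any(q <= 0) or np.unique(q).size < q.size:
        raise ValueError("quantities must be strictly positive and distinct")
    fit = stats.linregress(np.log10(q), c)
    slope = float(fit.slope)
    if slope >= 0:
        return StandardCurve(slope, float(fit.intercept), math.nan,
                             float(fit.rvalue**2), valid=False)
    return StandardCurve(slope, float(fit.intercept), 10.0 ** (-1.0 / slope),
                         float(fit.rvalue**2))


def interpolate_quantity(curve: StandardCurve, cq: float) -> float:
    """Invert the standard curve: quantity = 10^((Cq - intercept)/slope)."""
    if not curve.valid:
        raise ValueError("cannot interpolate on an invalid standard curve")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def percent_input(ip_quantity: float, input_quantity: float,
                  input_fraction: float = 0.01) -> float:
    """ChIP signal as percent of total input chromatin.

    ``input_fraction`` is the share of chromatin the input aliquot
    represents; percent input = 100 * ip / (input / input_fraction).
    Returns NaN when the input quantity is zero.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input fraction must be in (0, 1]")
    if ip_quantity < 0:
        raise ValueError("quantities must be non-negative")
    if input_quantity <= 0:
        return math.nan
    return 100.0 * ip_quantity / (input_quantity / input_fraction)


def fold_enrichment(target_percent_input: float, control_percent_input: float) -> float:
    """Target percent-input over IgG-control percent-input; NaN for zero control."""
    if control_percent_input <= 0 or math.isnan(control_percent_input):
        return math.nan
    return target_percent_input / control_percent_input


@dataclass
class AllelePreference:
    preference: float
    censored: bool = False


def allele_preference_check(
    curve: StandardCurve,
    cq_matched: float,
    cq_mismatched: float,
    cq_ceiling: float | None = None,
) -> AllelePreference:
    """Fold preference of an allele-specific primer for its matched template.

    Quantities are interpolated through the fitted standard curve and
    reported as matched/mismatched ratio.  If the mismatched template is
    undetected (Cq at or beyond the instrument ceiling) the ratio is a
    censored lower bound computed at the ceiling.
    """
    q_match = interpolate_quantity(curve, cq_matched)
    if cq_ceiling is not None and cq_mismatched >= cq_ceiling:
        return AllelePreference(q_match / interpolate_quantity(curve, cq_ceiling),
                                censored=True)
    return AllelePreference(q_match / interpolate_quantity(curve, cq_mismatched))


def replicate_t_test(group_a: np.ndarray, group_b: np.ndarray,
                     paired: bool = False) -> float:
    """Two-sided t-test on qPCR replicates: Welch unpaired default, paired option.

    Degenerate groups with zero variance and equal means return p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        d = a - b
        if np.ptp(d) == 0 and d[0] == 0:
            return 1.0
        return float(stats.ttest_rel(a, b).pvalue)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
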