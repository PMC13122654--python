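"""Small shared numerics: BH adjustment and display rounding.

Display rounding is half-up at a fixed number of decimals (the convention used
for the percentage fields in reports), not banker's rounding; raw fractions are
always kept alongside rendered values.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "round_half_up", "pct", "round_sigfig"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at `decimals` places (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage numerator/denominator rendered half-up; 0.0 when denominator is 0."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, decimals)


def round_sigfig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (1.4996 -> 1.5, 1209.1 -> 1200)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")
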