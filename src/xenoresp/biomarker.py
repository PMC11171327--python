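"""Biomarker expression vs. ordinal in vivo response.

Correlates a normalized protein (or transcript) expression level, one per
xenograft model, with the model's response category encoded on the
clinical plotting scale 1=MCR .. 5=PD, so a positive Pearson r means
higher marker expression accompanies worse response (the typical pattern
for a resistance marker such as MGMT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from xenoresp.response import ResponseCall, ResponseCategory

#: Plotting-scale rank: best response first.
_RANK = {
    ResponseCategory.MCR: 1,
    ResponseCategory.CR: 2,
    ResponseCategory.PR: 3,
    ResponseCategory.SD: 4,
    ResponseCategory.PD: 5,
}


@dataclass
class BiomarkerRecord:
    model_id: str
    expression: float        # marker intensity normalized to loading control
    response_rank: int       # 1=MCR .. 5=PD

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError("expression must be >= 0")
        if self.response_rank not in range(1, 6):
            raise ValueError("response_rank must be in 1..5")


def rank_encode(category: ResponseCall | ResponseCategory) -> int:
    """Map a response category to the 1(best)..5(worst) plotting rank."""
    if isinstance(category, ResponseCall):
        category = category.category
    return _RANK[ResponseCategory(category)]


def correlate(records: list[BiomarkerRecord]) -> dict:
    """Pearson correlation of expression with response rank.

    Returns a dict with the sample size, Pearson r, its two-sided p-value
    from the t reference distribution with n-2 df, a 95% CI via the
    Fisher z-transform, and Spearman's rho as a rank-based companion.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to correlate")
    x = np.array([r.expression for r in records], dtype=float)
    y = np.array([r.response_rank for r in records], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")

    n = len(x)
    r, p = stats.pearsonr(x, y)  # p is the two-sided t-based tail
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.975)
    ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    rho, rho_p = stats.spearmanr(x, y)
    return {
        "n": n,
        "pearson_r": float(r),
        "p": float(p),
        "ci95": ci,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for an observed Pearson r at sample size n.

    Uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 df;
    useful for auditing a published (r, n) pair.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not -1 < r < 1:
        return 0.0 if abs(r) == 1 else float("nan")
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), df=n - 2))
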