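"""Four-parameter logistic dose-response fitting and fold-potentiation.

The concentration-response model is the 4PL (Hill) curve

    signal(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

for a signal that decreases with concentration (viability assays).  The
IC50 is the inflection concentration producing the half-maximal signal.
Potentiation by a sensitizer is the ratio of the IC50 of a drug alone to
its IC50 in the presence of the sensitizer (fold shift of the curve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

HILL_BOUNDS = (0.1, 10.0)
HILL_STARTS = (0.5, 1.0, 2.0)


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    hill: float
    ic50: float
    rss: float
    converged: bool
    at_bounds: bool = False

    def predict(self, conc) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float),
                       self.top, self.bottom, self.hill, self.ic50)


@dataclass
class PotentiationResult:
    ic50_single: float
    ic50_combo: float
    fold: float
    label: str = "potentiation"


def four_pl(conc, top, bottom, hill, ic50):
    """4PL response; conc=0 maps to ``top`` exactly (no log singularity)."""
    conc = np.asarray(conc, dtype=float)
    out = np.full_like(conc, top, dtype=float)
    pos = conc > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (conc[pos] / ic50) ** hill)
    return out


def _initial_ic50(conc, sig, top, bottom) -> float:
    """Log-linear interpolation of the dose bracketing the half signal."""
    half = (top + bottom) / 2.0
    pos = conc > 0
    c, s = conc[pos], sig[pos]
    order = np.argsort(c)
    c, s = c[order], s[order]
    # find first dose pair bracketing the half-signal (signal decreasing)
    for i in range(len(c) - 1):
        lo, hi = sorted((s[i], s[i + 1]))
        if lo <= half <= hi and s[i] != s[i + 1]:
            f = (s[i] - half) / (s[i] - s[i + 1])
            return float(np.exp(np.log(c[i]) + f * (np.log(c[i + 1]) - np.log(c[i]))))
    return float(np.sqrt(c[0] * c[-1]))  # geometric mid-dose fallback


def fit_4pl(concentrations, signals) -> DoseResponseFit:
    """Least-squares 4PL fit.

    Requires at least four distinct positive concentrations; zero-dose
    wells anchor the top asymptote through the residuals but are excluded
    from the power term.  Initialization takes top/bottom from the
    dose-averaged extremes, the IC50 from log-linear interpolation of the
    half-signal bracket, and multi-starts the Hill slope over
    ``HILL_STARTS``, keeping the lowest residual sum of squares.
    Degenerate (flat) data yields ``converged=False`` rather than an
    exception; fits pinned at the Hill or bottom bound are flagged.
    """
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.shape != sig.shape:
        raise ValueError("concentrations and signals must have equal length")
    if not np.all(np.isfinite(sig)):
        raise ValueError("signals must be finite")
    n_distinct = len(np.unique(conc[conc > 0]))
    if n_distinct < 4:
        raise ValueError(
            f"need >= 4 distinct positive concentrations, got {n_distinct}"
        )

    # dose-averaged signals for robust initialization under replicates
    uconc = np.unique(conc)
    means = np.array([sig[conc == u].mean() for u in uconc])
    top0, bot0 = float(means.max()), float(means.min())
    if np.allclose(sig, sig[0]) or top0 == bot0:
        return DoseResponseFit(top=top0, bottom=bot0, hill=np.nan,
                               ic50=np.nan, rss=float(np.sum((sig - sig.mean()) ** 2)),
                               converged=False)

    ic50_0 = _initial_ic50(uconc, means, top0, bot0)
    cpos = conc[conc > 0]
    lo = [bot0 - 2 * (top0 - bot0), 0.0, HILL_BOUNDS[0], cpos.min() / 1e4]
    hi = [top0 + 2 * (top0 - bot0), top0 + 2 * (top0 - bot0), HILL_BOUNDS[1], cpos.max() * 1e4]

    best = None
    for h0 in HILL_STARTS:
        p0 = [top0, max(bot0, 0.0), h0, ic50_0]
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = curve_fit(
                lambda c, t, b, h, i: four_pl(c, t, b, h, i),
                conc, sig, p0=p0, bounds=(lo, hi), maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((four_pl(conc, *popt) - sig) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)

    if best is None:
        return DoseResponseFit(top=top0, bottom=bot0, hill=np.nan, ic50=np.nan,
                               rss=np.inf, converged=False)
    (top, bottom, hill, ic50), rss = best
    at_bounds = bool(
        np.isclose(hill, HILL_BOUNDS[0]) or np.isclose(hill, HILL_BOUNDS[1])
        or np.isclose(bottom, 0.0) and bot0 > 0.05 * (top0 - bot0)
    )
    return DoseResponseFit(top=float(top), bottom=float(bottom), hill=float(hill),
                           ic50=float(ic50), rss=rss, converged=True,
                           at_bounds=at_bounds)


def potentiation_fold(fit_single: DoseResponseFit, fit_combo: DoseResponseFit,
                      label: str = "potentiation") -> PotentiationResult:
    """Fold shift in potency: IC50 of the drug alone over IC50 with the
    sensitizer present.  Fold > 1 means the sensitizer potentiates."""
    if not (fit_single.converged and fit_combo.converged):
        raise ValueError("both fits must have converged to compute a fold")
    return PotentiationResult(
        ic50_single=fit_single.ic50, ic50_combo=fit_combo.ic50,
        fold=fit_single.ic50 / fit_combo.ic50, label=label,
    )


def potentiation_with_modulator(fit_combo: DoseResponseFit,
                                fit_combo_plus_modulator: DoseResponseFit) -> PotentiationResult:
    """Additional potentiation contributed by a resistance-pathway
    modulator (e.g. an MGMT inhibitor) on top of an existing combination."""
    return potentiation_fold(fit_combo, fit_combo_plus_modulator,
                             label="modulator_potentiation")
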