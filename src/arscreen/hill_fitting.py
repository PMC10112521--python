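"""Three-parameter Hill concentration-response fitting (bottom fixed at 0).

The model is

    resp(c) = top / (1 + 10^((log10_ac50 - log10(c)) * slope))

so resp -> 0 as c -> 0, resp(AC50) = top/2 exactly, and resp -> top at
saturating concentration.  Fitting minimizes the sum of squared residuals
over well-level responses (all replicates, not per-concentration medians;
configurable) with box constraints in the tcpl tradition: slope in
[0.3, 8] and log10 AC50 within [min tested - 2, max tested + 0.5] log10 µM,
which keeps truncated curves identifiable.  A deterministic multi-start
(data-driven initial guess plus jittered restarts from a fixed seed) guards
against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .normalization import ConcentrationSeries

__all__ = [
    "SLOPE_BOUNDS",
    "HillFit",
    "predict_hill",
    "hill_response",
    "hill_param_bounds",
    "fit_hill",
    "max_median_response",
]

SLOPE_BOUNDS = (0.3, 8.0)
#: log10 AC50 box relative to the tested range, in log10 µM
AC50_MARGIN_BELOW = 2.0
AC50_MARGIN_ABOVE = 0.5


@dataclass(frozen=True)
class HillFit:
    top: float
    log10_ac50: float
    slope: float
    rss: float
    converged: bool
    n_points: int

    @property
    def ac50_uM(self) -> float:
        return float(10.0 ** self.log10_ac50)


def hill_response(
    conc_uM: np.ndarray | float, top: float, log10_ac50: float, slope: float
) -> np.ndarray | float:
    """Vectorized Hill curve; bottom implicitly 0."""
    return top / (1.0 + 10.0 ** ((log10_ac50 - np.log10(conc_uM)) * slope))


def predict_hill(fit: HillFit, conc_uM: float) -> float:
    """Response of a fitted curve at one concentration (µM)."""
    if not conc_uM > 0:
        raise ValueError(f"conc_uM must be > 0, got {conc_uM}")
    return float(hill_response(conc_uM, fit.top, fit.log10_ac50, fit.slope))


def hill_param_bounds(
    concs: np.ndarray, resps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Box constraints (lower, upper) for (top, log10_ac50, slope).

    The top is bounded by three times the largest observed response (with a
    small positive floor so null series collapse to top ~ 0); the AC50 box
    extends two decades below and half a decade above the tested range.
    """
    l10 = np.log10(concs)
    top_hi = max(3.0 * float(np.max(resps)), 1e-3)
    lo = np.array([0.0, l10.min() - AC50_MARGIN_BELOW, SLOPE_BOUNDS[0]])
    hi = np.array([top_hi, l10.max() + AC50_MARGIN_ABOVE, SLOPE_BOUNDS[1]])
    return lo, hi


def _initial_guesses(
    series: ConcentrationSeries,
    lo: np.ndarray,
    hi: np.ndarray,
    n_restarts: int,
    seed: int,
) -> list[np.ndarray]:
    medians = series.medians
    concs = series.concs
    top0 = float(np.clip(np.max(medians), lo[0] + 1e-9, hi[0]))
    # concentration whose median is nearest half the apparent top
    half_idx = int(np.argmin(np.abs(medians - top0 / 2.0)))
    ac50_0 = float(np.clip(np.log10(concs[half_idx]), lo[1], hi[1]))
    guesses = [np.array([top0, ac50_0, 1.2])]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        g = np.array(
            [
                top0 * rng.uniform(0.5, 1.5),
                ac50_0 + rng.uniform(-1.0, 1.0),
                1.2 * rng.uniform(0.5, 2.0),
            ]
        )
        guesses.append(np.clip(g, lo + 1e-9, hi - 1e-9))
    return guesses


def fit_hill(
    series: ConcentrationSeries,
    use_medians: bool = False,
    n_restarts: int = 4,
    restart_seed: int = 7,
) -> HillFit:
    """Least-squares Hill fit to a concentration series.

    Requires >= 4 distinct concentrations.  ``use_medians`` switches the
    objective from well-level responses to per-concentration medians.  The
    best of the multi-start solutions is returned; if no start converges the
    best parameters are still reported with ``converged=False``.
    """
    if use_medians:
        concs, resps = series.concs, series.medians
    else:
        concs, resps = series.well_level()
    keep = concs > 0
    concs, resps = concs[keep], resps[keep]
    if len(np.unique(concs)) < 4:
        raise ValueError(
            f"{series.chemical_id}: need >= 4 distinct concentrations, "
            f"got {len(np.unique(concs))}"
        )
    lo, hi = hill_param_bounds(concs, resps)
    l10c = np.log10(concs)

    def residuals(p: np.ndarray) -> np.ndarray:
        top, ac50, slope = p
        return top / (1.0 + 10.0 ** ((ac50 - l10c) * slope)) - resps

    best = None
    converged = False
    for x0 in _initial_guesses(series, lo, hi, n_restarts, restart_seed):
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x, sol.success)
        converged = converged or sol.success
    rss, params, _ = best
    return HillFit(
        top=float(params[0]),
        log10_ac50=float(params[1]),
        slope=float(params[2]),
        rss=rss,
        converged=converged,
        n_points=len(resps),
    )


def max_median_response(series: ConcentrationSeries) -> tuple[float, float]:
    """(conc_uM, median_resp) of the maximal per-concentration median.

    Ties are broken toward the lowest concentration.  Points are already
    sorted ascending, so the first argmax wins.
    """
    if not series.points:
        raise ValueError("empty series")
    medians = series.medians
    idx = int(np.argmax(medians))
    return float(series.concs[idx]), float(medians[idx])
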