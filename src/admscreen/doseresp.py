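"""Four-parameter logistic (4PL) concentration-response fitting.

Model: y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

with doses x > 0 in µM. After canonicalization bottom <= top and the sign of
``hill`` carries the orientation: hill > 0 means the response falls with
increasing dose (y -> top as x -> 0), hill < 0 means it rises. IC50 is the
inflection concentration in the dose units supplied.

Fitting is unweighted least squares (the common Prism-style default). The
model is linear in (top, bottom) once (hill, ic50) are fixed, so those two
asymptotes are profiled out analytically (variable projection) and the
nonlinear search runs over (hill, log10 ic50) only, seeded from a coarse
grid spanning two decades beyond the dose range; curves whose IC50 sits
outside the tested range are still recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "four_pl",
    "make_dilution_series",
    "fit_4pl",
    "simulate_dose_response",
    "fitted_curve",
]

_HILL_MIN, _HILL_MAX = 0.1, 10.0


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    hill: float   # signed; |hill| in [0.1, 10]
    ic50: float   # dose units (µM by convention)
    rss: float
    converged: bool

    def predict(self, doses) -> np.ndarray:
        return four_pl(np.asarray(doses, dtype=float), self.top, self.bottom,
                       self.hill, self.ic50)


def four_pl(x, top, bottom, hill, ic50):
    """Evaluate the 4PL model (vectorized over doses x > 0)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def make_dilution_series(top_dose: float = 10.0, n_points: int = 6,
                         factor: float = 3.162) -> list[float]:
    """Descending geometric dilution series from ``top_dose``.

    Defaults give the half-log series 10 µM ... 31.6 nM (six points at
    ~3.16-fold steps, honoring both the 10 µM top and ~32 nM bottom of the
    conventional validation range).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if top_dose <= 0:
        raise ValueError("top_dose must be positive")
    return [top_dose / factor**k for k in range(n_points)]


def _profile_top_bottom(x, y, hill, lg):
    """For fixed (hill, log10 ic50) the model is linear in (top, bottom):
    y = bottom*(1-w) + top*w with w = 1/(1 + (x/ic50)^hill). Solve by
    linear least squares; returns (top, bottom, rss)."""
    w = 1.0 / (1.0 + (x / 10.0**lg) ** hill)
    design = np.column_stack([w, 1.0 - w])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _profiled_residuals(theta, x, y):
    hill, lg = theta
    w = 1.0 / (1.0 + (x / 10.0**lg) ** hill)
    design = np.column_stack([w, 1.0 - w])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def fit_4pl(doses, responses, weights=None) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization.

    ``doses`` must contain >= 4 distinct positive values; replicate
    measurements are passed as repeated (dose, response) pairs. ``weights``
    (optional) multiply the residuals. The returned fit has the smallest
    residual sum of squares over all starts; ``converged`` is False when no
    start converges, when the data are flat, or when the fitted IC50 sits at
    the search boundary (an extrapolation the data cannot pin down).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("doses and responses must be finite")
    if np.any(x <= 0):
        raise ValueError("doses must be positive (exclude vehicle wells)")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        # curve_fit has no residual weights hook in this form; fold them in
        # by scaling both sides of the regression.
        raise NotImplementedError("weighted fits are not supported")

    if np.ptp(y) == 0.0:
        # flat data: any ic50 is equivalent; report the constant fit honestly
        return DoseResponseFit(top=float(y[0]), bottom=float(y[0]), hill=1.0,
                               ic50=float(np.median(x)), rss=0.0,
                               converged=False)

    lg_lo = np.log10(x.min()) - 2.0
    lg_hi = np.log10(x.max()) + 2.0

    # coarse grid over (hill, log ic50) with the asymptotes profiled out.
    # (hill, lg) and (-hill, lg) describe the same curve with top/bottom
    # swapped, so the grid only needs hill > 0; orientation falls out of the
    # profiled coefficients.
    hills = np.geomspace(_HILL_MIN, _HILL_MAX, 13)
    lgs = np.linspace(lg_lo, lg_hi, 41)
    grid = []
    for hill0 in hills:
        for lg0 in lgs:
            _, _, rss0 = _profile_top_bottom(x, y, hill0, lg0)
            grid.append((rss0, hill0, lg0))
    grid.sort(key=lambda g: g[0])

    # polish a few well-separated starts with bounded least squares on the
    # profiled 2-parameter objective
    starts, seen_lg = [], []
    for rss0, hill0, lg0 in grid:
        if all(abs(lg0 - s) > 0.4 for s in seen_lg):
            starts.append((hill0, lg0))
            seen_lg.append(lg0)
        if len(starts) == 4:
            break

    best = None
    for hill0, lg0 in starts:
        try:
            sol = least_squares(
                _profiled_residuals, x0=[hill0, lg0], args=(x, y),
                bounds=([_HILL_MIN, lg_lo], [_HILL_MAX, lg_hi]))
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, float(sol.x[0]), float(sol.x[1]), bool(sol.success))
    if best is None:
        best = (*grid[0][:1], grid[0][1], grid[0][2], False)
    rss, hill, lg, success = best
    top, bottom, rss = _profile_top_bottom(x, y, hill, lg)
    ic50 = float(10.0 ** lg)
    at_boundary = lg <= lg_lo + 1e-6 or lg >= lg_hi - 1e-6
    if top < bottom:  # canonicalize: bottom <= top, orientation in hill sign
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(top=float(top), bottom=float(bottom),
                           hill=float(hill), ic50=ic50, rss=float(rss),
                           converged=success and not at_boundary)


def simulate_dose_response(
    ic50: float,
    doses,
    top: float = 90.0,
    bottom: float = 5.0,
    hill: float = 1.5,
    noise_sd: float = 3.0,
    replicates: int = 4,
    rng_seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Noisy % readout drawn from a 4PL curve (tidy dose/response/replicate)."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for dose in doses:
        mu = four_pl(dose, top, bottom, hill, ic50)
        for rep in range(replicates):
            rows.append((float(dose),
                         float(mu + rng.normal(0.0, noise_sd)), rep))
    return pd.DataFrame(rows, columns=["dose", "response", "replicate"])


def fitted_curve(fit: DoseResponseFit, dose_min: float, dose_max: float,
                 n: int = 100) -> pd.DataFrame:
    """Smooth curve table (log-spaced doses) for plotting a fit."""
    doses = np.logspace(np.log10(dose_min), np.log10(dose_max), n)
    return pd.DataFrame({"dose": doses, "response": fit.predict(doses)})
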