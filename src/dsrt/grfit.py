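"""Growth-rate-corrected dose response: the GR transform and GR50 fitting.

Relative-viability IC50s conflate drug effect with how fast the control
population divides, so cell lines are only comparable after correcting
for growth rate.  The GR value of a treated condition is

    GR(c) = 2 ** ( log2(x_c / x0) / log2(x_ctrl / x0) ) - 1

where x0 is the baseline cell measure, x_ctrl the vehicle endpoint and
x_c the treated endpoint: GR = 1 means untreated growth, 0 cytostasis,
negative values net cell loss (floor -1 as x_c -> 0).  GR values over a
dose range are fitted with the four-parameter log-logistic sigmoid

    GR(c) = gr_inf + (1 - gr_inf) / (1 + (c / gec50) ** hill)

(upper asymptote fixed at 1, the untreated state), and GR50 — the
concentration where the curve crosses 0.5 — follows in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class GRError(ValueError):
    """Raised when the GR transform or fit is undefined for the input."""


@dataclass
class GRFit:
    """Fitted GR sigmoid: asymptote, inflection, slope, derived GR50."""

    gr_inf: float
    gec50: float
    hill: float
    gr50: float
    converged: bool
    residual: float


def gr_transform(x0, x_ctrl, x_c):
    """Endpoint-form GR value; scale-invariant in the three measures."""
    x0 = np.asarray(x0, dtype=float)
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    if np.any(x0 <= 0) or np.any(x_c <= 0):
        raise GRError("cell measures must be positive")
    if np.any(x_ctrl <= x0):
        raise GRError("GR undefined: control endpoint must exceed baseline x0")
    ratio = np.log2(x_c / x0) / np.log2(x_ctrl / x0)
    out = 2.0 ** ratio - 1.0
    return float(out) if out.ndim == 0 else out


def gr_curve(conc, gr_inf, gec50, hill):
    """Four-parameter log-logistic GR curve with upper asymptote 1."""
    conc = np.asarray(conc, dtype=float)
    return gr_inf + (1.0 - gr_inf) / (1.0 + (conc / gec50) ** hill)


def gr50_from_params(gr_inf: float, gec50: float, hill: float) -> float:
    """Concentration where the fitted curve crosses GR = 0.5.

    Solves 0.5 = gr_inf + (1-gr_inf)/(1+(c/gec50)^h) analytically;
    +inf sentinel when the asymptote never lets the curve reach 0.5.
    """
    if gr_inf >= 0.5:
        return float("inf")
    return float(gec50 * ((1.0 - gr_inf) / (0.5 - gr_inf) - 1.0) ** (1.0 / hill))


def gr50_from_fit(fit: GRFit) -> float:
    if not fit.converged:
        return float("inf")
    return gr50_from_params(fit.gr_inf, fit.gec50, fit.hill)


def fit_gr_curve(concentrations, gr_values, flat_alpha: float = 0.05,
                 n_starts: int = 8, hill_bounds=(0.1, 5.0)) -> GRFit:
    """Bounded least-squares fit of the GR sigmoid with a flat-model fallback.

    Replicate points enter the loss jointly.  gec50 is optimized on the
    log10 scale with multi-start over a log-spaced grid spanning
    [min_conc/100, max_conc*100]; gr_inf is bounded in [-1, 1] and the
    Hill slope in ``hill_bounds``.  When an F-test at ``flat_alpha``
    cannot reject the constant model, the fit collapses to the mean GR
    (converged=False, GR50 = +inf sentinel).
    """
    conc = np.asarray(concentrations, dtype=float)
    gr = np.asarray(gr_values, dtype=float)
    if conc.size != gr.size:
        raise GRError("concentrations and GR values must align")
    if np.unique(conc).size < 4:
        raise GRError("need >=4 distinct concentrations to fit a 4PL curve")
    if np.any(conc <= 0):
        raise GRError("concentrations must be positive")

    n = gr.size
    mean_gr = float(gr.mean())
    sse_flat = float(((gr - mean_gr) ** 2).sum())

    lg_lo = np.log10(conc.min()) - 2.0
    lg_hi = np.log10(conc.max()) + 2.0
    lo = np.array([-1.0, lg_lo, hill_bounds[0]])
    hi = np.array([1.0, lg_hi, hill_bounds[1]])

    def resid(theta):
        g_inf, lg_ec, h = theta
        return gr_curve(conc, g_inf, 10.0 ** lg_ec, h) - gr

    g0 = float(np.clip(gr.min(), -1.0, 1.0))
    # order starts from the middle of the tested range outwards: clean
    # sigmoids converge from the first one, so later starts rarely run
    mid = 0.5 * (np.log10(conc.min()) + np.log10(conc.max()))
    starts = np.linspace(lg_lo + 0.5, lg_hi - 0.5, n_starts)
    starts = starts[np.argsort(np.abs(starts - mid), kind="stable")]
    best = None
    for lg_start in starts:
        x0 = np.clip([g0, lg_start, 1.0], lo, hi)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        sse = float((sol.fun ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, sol.x)
        if sse <= 1e-10:  # essentially exact fit; further starts cannot improve
            break
    if best is None:
        raise GRError("all fit starts failed")
    sse, (g_inf, lg_ec, h) = best

    # F-test of the sigmoid (3 params) against the constant model (1 param)
    df1, df2 = 2, n - 3
    flat = df2 <= 0
    if not flat:
        if sse <= 1e-18 * max(1.0, sse_flat):
            p_flat = 0.0 if sse_flat > 1e-18 else 1.0
        else:
            f = ((sse_flat - sse) / df1) / (sse / df2)
            p_flat = float(stats.f.sf(max(f, 0.0), df1, df2))
        flat = p_flat >= flat_alpha

    if flat:
        return GRFit(gr_inf=mean_gr, gec50=float("nan"), hill=float("nan"),
                     gr50=float("inf"), converged=False, residual=sse_flat)
    gec50 = 10.0 ** lg_ec
    fit = GRFit(gr_inf=float(g_inf), gec50=float(gec50), hill=float(h),
                gr50=float("nan"), converged=True, residual=sse)
    fit.gr50 = gr50_from_fit(fit)
    return fit
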