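"""Hill-model evaluation and nonlinear fitting for ASIC dose-response data.

The central model is the Hill equation on the pH axis,

    I(pH) = I_max / (1 + (10^-pH50 / 10^-pH)^nH)
          = I_max / (1 + 10^((pH - pH50) * nH)),

which increases with acidity (decreasing pH) and passes through I_max/2 at
``pH50``.  Steady-state desensitization (SSD) curves use the complementary
("availability") form, Ca2+ inhibition curves the same logistic on the
log10-concentration axis, and the pH50-vs-[Ca2+] modulation curve a logistic
in log10[Ca2+] between two free pH50 asymptotes.

All fits are unweighted least squares (optional weights supported), run from
data-driven starting points with a small multi-start fallback, and are fully
deterministic given the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "CaModulationFit",
    "hill_activation",
    "hill_ssd",
    "hill_inhibition",
    "fit_hill",
    "pooled_fit",
    "fit_ca_inhibition",
    "fit_ph50_vs_ca",
]

#: relative tolerance on the residual sum of squares used to declare two
#: multi-start solutions equivalent and to accept convergence
SSQ_RTOL = 1e-10


def hill_activation(ph, ph50, n_h, i_max=1.0):
    """Hill activation curve: response grows as pH drops below ``ph50``.

    Parameters
    ----------
    ph : float or array
        Stimulation pH.
    ph50 : float
        pH of half-maximal activation.
    n_h : float
        Hill coefficient (> 0).
    i_max : float
        Maximal response (default 1, i.e. normalized).
    """
    ph = np.asarray(ph, dtype=float)
    out = i_max / (1.0 + 10.0 ** ((ph - ph50) * n_h))
    return out if out.ndim else float(out)


def hill_ssd(ph_conditioning, phd50, n_h):
    """Fraction of channels still available after conditioning at a given pH.

    The analogous equation to activation: availability is 1 at alkaline
    conditioning pH, 0.5 at ``phd50`` and approaches 0 with acidity.
    """
    ph = np.asarray(ph_conditioning, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** ((phd50 - ph) * n_h))
    return out if out.ndim else float(out)


def hill_inhibition(conc, ic50, n_h, i_max=1.0):
    """Concentration-inhibition curve: response falls as ``conc`` rises.

    ``response = i_max / (1 + (conc/ic50)^n_h)`` — used for Ca2+ block at
    fixed pH and for the acid inhibition of endogenous currents (where the
    "concentration" is [H+]).
    """
    conc = np.asarray(conc, dtype=float)
    out = i_max / (1.0 + (conc / ic50) ** n_h)
    return out if out.ndim else float(out)


@dataclass
class HillFit:
    """Result of a Hill-type dose-response fit.

    ``midpoint`` is pH50 for activation, pHD50 for SSD, and IC50 (in M) for
    Ca2+ inhibition.  Standard errors come from the linearized covariance at
    the optimum and are NaN when the covariance is singular.
    """

    kind: str
    midpoint: float
    n_h: float
    i_max: float
    midpoint_se: float
    n_h_se: float
    i_max_se: float
    n_points: int
    rss: float
    converged: bool
    pooled: bool = False
    flags: list = field(default_factory=list)


@dataclass
class CaModulationFit:
    """Logistic fit of pH50 as a function of free [Ca2+] (M)."""

    ic50_m: float
    upper: float     # pH50 asymptote at vanishing Ca2+
    lower: float     # pH50 asymptote at saturating Ca2+
    slope: float
    ic50_se: float
    rss: float
    n_points: int
    flags: list = field(default_factory=list)


def _logistic(x, mid, slope, amp):
    # decreasing-in-x logistic; all Hill kinds map onto this internal form
    return amp / (1.0 + 10.0 ** ((x - mid) * slope))


def _prepare(kind, x, response):
    """Map (kind, x) onto the internal decreasing-logistic axis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and response must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValueError(f"need at least 4 points to fit, got {len(x)}")
    if kind == "activation":
        return x, y, False
    if kind == "ssd":
        # availability = 1/(1 + 10^((phd50 - ph) nH)): increasing in pH,
        # i.e. decreasing in -pH — fit on the negated axis.
        return -x, y, True
    if kind == "ca_inhibition":
        if np.any(x <= 0):
            raise ValueError("concentrations must be positive")
        return np.log10(x), y, False
    raise ValueError(f"unknown fit kind: {kind!r}")


def _starting_points(u, y):
    """Data-driven (midpoint, slope, amplitude) starts on the internal axis."""
    amp0 = float(np.max(np.abs(y)))
    if amp0 == 0.0:
        amp0 = 1.0
    order = np.argsort(u)
    us, ys = u[order], y[order]
    # crossing of half-amplitude, scanned from the high-response side
    half = 0.5 * amp0
    below = np.nonzero(ys <= half)[0]
    mid0 = float(us[below[0]]) if len(below) else float(np.median(us))
    span = max(np.ptp(u), 1e-6)
    starts = []
    for m in (mid0, float(np.quantile(u, 0.25)), float(np.quantile(u, 0.75))):
        for s in (2.0 / span * 2.0, 1.0):
            starts.append((m, s, amp0))
    return starts


def fit_hill(x, response, kind="activation", weights=None, i_max_fixed=None):
    """Fit a Hill-type curve by least squares.

    Parameters
    ----------
    x : array
        pH values (activation, ssd) or concentrations in M (ca_inhibition).
    response : array
        Measured responses (normalized or raw; amplitude is free unless
        ``i_max_fixed`` is given).
    kind : {"activation", "ssd", "ca_inhibition"}
    weights : array, optional
        Per-point weights (1/sigma); default unweighted.
    i_max_fixed : float, optional
        Fix the maximal response instead of fitting it.

    Returns
    -------
    HillFit

    Raises
    ------
    ValueError
        On flat data, too few points or invalid inputs.
    RuntimeError
        When no start converges.
    """
    u, y, negate = _prepare(kind, x, response)
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        raise ValueError("response data are flat; a Hill fit is undefined")
    if kind == "ca_inhibition" and np.ptp(u) < 2.0:
        warnings.warn(
            "concentrations span less than 2 decades; IC50 poorly constrained",
            stacklevel=2,
        )
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)

    span = np.ptp(u)
    lo = [u.min() - 2 * max(span, 1.0), 1e-3, 1e-12]
    hi = [u.max() + 2 * max(span, 1.0), 50.0, 10.0 * max(np.max(np.abs(y)), 1.0)]

    if i_max_fixed is None:
        def model(uu, m, s, a):
            return _logistic(uu, m, s, a)
        nfree = 3
    else:
        def model(uu, m, s):
            return _logistic(uu, m, s, i_max_fixed)
        lo, hi = lo[:2], hi[:2]
        nfree = 2

    best = None
    for p0 in _starting_points(u, y):
        p0 = list(p0[:nfree])
        p0 = [min(max(p, l), h) for p, l, h in zip(p0, lo, hi)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, u, y, p0=p0, sigma=sigma, bounds=(lo, hi),
                    maxfev=20000, xtol=1e-14, ftol=SSQ_RTOL, gtol=1e-14,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(u, *popt) - y) ** 2))
        if best is None or rss < best[2] * (1 - SSQ_RTOL):
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError(f"Hill fit ({kind}) failed to converge from all starts")
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))

    mid, slope = popt[0], popt[1]
    amp = i_max_fixed if i_max_fixed is not None else popt[2]
    amp_se = np.nan if i_max_fixed is not None else perr[2]
    if negate:
        mid = -mid
    if kind == "ca_inhibition":
        mid_nat, mid_se = 10.0 ** mid, abs(10.0 ** mid * np.log(10) * perr[0])
    else:
        mid_nat, mid_se = mid, perr[0]

    flags = []
    xs = np.asarray(x, dtype=float)
    if kind == "ca_inhibition":
        inside = xs.min() / 10 <= mid_nat <= xs.max() * 10
    else:
        inside = xs.min() - 1.0 <= mid_nat <= xs.max() + 1.0
    if not inside:
        flags.append("midpoint_outside_sampled_range")

    return HillFit(
        kind=kind, midpoint=float(mid_nat), n_h=float(slope),
        i_max=float(amp), midpoint_se=float(mid_se), n_h_se=float(perr[1]),
        i_max_se=float(amp_se), n_points=len(u), rss=rss,
        converged=True, flags=flags,
    )


def pooled_fit(x, response, cell_id, kind="activation", **kwargs):
    """Single Hill fit over points pooled across cells.

    Used for rundown-prone constructs whose full pH dependence is assembled
    from different cells; every contributing cell must already be normalized.
    The returned fit is flagged as pooled.
    """
    cell_id = np.asarray(cell_id)
    x = np.asarray(x, dtype=float)
    if len(cell_id) != len(x):
        raise ValueError("cell_id must align with x")
    fit = fit_hill(x, response, kind=kind, **kwargs)
    fit.pooled = True
    return fit


def fit_ca_inhibition(conc_m, response, **kwargs):
    """Fit Ca2+ inhibition of the current at fixed pH; IC50 returned in M."""
    return fit_hill(conc_m, response, kind="ca_inhibition", **kwargs)


def fit_ph50_vs_ca(conc_m, ph50):
    """Fit pH50 as a logistic function of log10 free [Ca2+].

    ``pH50(c) = lower + (upper - lower) / (1 + (c / IC50)^slope)``

    Returns a :class:`CaModulationFit`; warns (flag) when the pH50 values are
    not monotonically decreasing with Ca2+ beyond small noise.
    """
    c = np.asarray(conc_m, dtype=float)
    y = np.asarray(ph50, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.ptp(y) < 1e-9:
        raise ValueError("pH50 values are flat; modulation fit is undefined")
    x = np.log10(c)

    def model(xx, logic50, slope, lower, upper):
        return lower + (upper - lower) / (1.0 + 10.0 ** ((xx - logic50) * slope))

    p0 = [float(np.median(x)), 1.0, float(y.min()), float(y.max())]
    lo = [x.min() - 4, 1e-3, y.min() - 2, y.min() - 2]
    hi = [x.max() + 4, 50.0, y.max() + 2, y.max() + 2]
    popt, pcov = curve_fit(model, x, y, p0=p0, bounds=(lo, hi),
                           maxfev=20000, xtol=1e-14, ftol=SSQ_RTOL)
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    perr = np.sqrt(np.diag(pcov))
    flags = []
    order = np.argsort(x)
    resid_scale = max(np.sqrt(rss / len(x)), 1e-6)
    if np.any(np.diff(y[order]) > 3 * resid_scale):
        flags.append("non_monotone_ph50_vs_ca")
        warnings.warn("pH50 increases with Ca2+ beyond noise", stacklevel=2)
    lower, upper = popt[2], popt[3]
    if not lower < upper:
        flags.append("asymptotes_inverted")
    return CaModulationFit(
        ic50_m=float(10.0 ** popt[0]), upper=float(upper), lower=float(lower),
        slope=float(popt[1]),
        ic50_se=float(abs(10.0 ** popt[0] * np.log(10) * perr[0])),
        rss=rss, n_points=len(c), flags=flags,
    )
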