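"""Hill-coefficient estimators for monotone saturating dose-response curves.

Three standard ultrasensitivity measures over an abstract curve:

* Goldbeter-Koshland: ``H = ln(81) / ln(EC90 / EC10)``;
* nonlinear least-squares fit of the normalized curve to the Hill function
  ``x^H / (k^H + x^H)``;
* Levitzki's n50, ``4 * EC50 * g'(EC50)`` with ``g`` the normalized curve.

``H > 1`` marks an ultrasensitive (switch-like) response, ``H = 1`` a
Michaelian one.  Effective concentrations ``EC_beta`` are found by bracketed
root search on ``log10(u)``.  Two threshold conventions are supported:
``"max"`` solves ``f(u) = beta * f_inf`` (the raw maximal-output fraction;
undefined when the basal activity already exceeds the threshold) and
``"range"`` solves ``f(u) = basal + beta * (f_inf - basal)`` (fraction of
the induced dynamic range, defined for any non-degenerate curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq, curve_fit

from . import independent as ind
from . import mwc

__all__ = [
    "DoseResponseCurve",
    "HillEstimate",
    "BracketingError",
    "effective_concentration",
    "hill_goldbeter_koshland",
    "hill_fit",
    "hill_levitzki",
    "hill_partial",
    "curve_from_params",
]


class BracketingError(RuntimeError):
    """Root bracketing failed (e.g. non-monotone or pathological curve).

    Distinct from an *undefined* effective concentration, which is the
    legitimate no-crossing case (basal activity at or above the threshold).
    """


@dataclass(frozen=True)
class DoseResponseCurve:
    """A monotone dose-response curve with known maximal output.

    ``evaluate`` maps an input concentration ``u >= 0`` to the output;
    ``max_response`` is the saturating output ``f_inf``; ``basal`` the value
    at ``u = 0``.
    """

    evaluate: Callable[[float], float]
    max_response: float
    basal: float
    label: str = ""

    def __post_init__(self):
        if not (self.max_response > 0):
            raise ValueError("max_response must be positive")
        if self.basal < 0 or self.basal > self.max_response * (1 + 1e-12):
            raise ValueError("basal must lie in [0, max_response]")

    def __call__(self, u: float) -> float:
        return self.evaluate(u)

    def normalized(self, u: float) -> float:
        """Output as a fraction of the maximal response."""
        return self.evaluate(u) / self.max_response


@dataclass(frozen=True)
class HillEstimate:
    """An ultrasensitivity measurement.

    ``defined`` is False when the estimator's effective concentrations do
    not exist (for instance when basal activity exceeds 10% of the maximal
    output under the ``"max"`` threshold convention); all numeric fields are
    then ``None``.
    """

    method: str
    H: Optional[float] = None
    ec10: Optional[float] = None
    ec50: Optional[float] = None
    ec90: Optional[float] = None
    defined: bool = False
    fit_k: Optional[float] = None

    def to_dict(self) -> dict:
        return {"method": self.method, "H": self.H, "ec10": self.ec10,
                "ec50": self.ec50, "ec90": self.ec90, "defined": self.defined,
                "fit_k": self.fit_k}


ModelParameters = Union[mwc.MWCParameters, ind.IndependentParameters]


def curve_from_params(params: ModelParameters) -> DoseResponseCurve:
    """Wrap an MWC or independent-sites parameter set as a DoseResponseCurve."""
    if isinstance(params, mwc.MWCParameters):
        return DoseResponseCurve(
            evaluate=lambda u: mwc.dose_response(params, u),
            max_response=mwc.max_response(params),
            basal=mwc.basal_response(params),
            label=f"mwc(n={params.n}, L={params.L:g})")
    if isinstance(params, ind.IndependentParameters):
        return DoseResponseCurve(
            evaluate=lambda u: ind.dose_response(params, u),
            max_response=ind.max_response(params),
            basal=ind.basal_response(params),
            label=f"independent(n={params.n}, d={params.d:g})")
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def _as_curve(curve) -> DoseResponseCurve:
    if isinstance(curve, DoseResponseCurve):
        return curve
    return curve_from_params(curve)


def effective_concentration(curve, beta: float, threshold: str = "max",
                            bracket: tuple = (1e-12, 1e12)) -> Optional[float]:
    """Input ``u`` at which the curve reaches a fraction ``beta`` of maximum.

    With ``threshold="max"`` solves ``f(u) = beta * f_inf`` and returns
    ``None`` (undefined) when ``basal >= beta * f_inf``, i.e. there is no
    crossing.  With ``threshold="range"`` solves
    ``f(u) = basal + beta * (f_inf - basal)``, which always crosses for a
    saturating curve.  The root search runs on ``log10(u)``, expanding the
    bracket outward if needed; a curve that fails to bracket raises
    :class:`BracketingError`.
    """
    curve = _as_curve(curve)
    if not 0 < beta < 1:
        raise ValueError("beta must lie strictly between 0 and 1")
    if threshold == "max":
        target = beta * curve.max_response
        if curve.basal >= target:
            return None
    elif threshold == "range":
        target = curve.basal + beta * (curve.max_response - curve.basal)
        if curve.max_response <= curve.basal:
            return None
    else:
        raise ValueError(f"unknown threshold convention {threshold!r}")

    def g(x: float) -> float:
        return curve.evaluate(10.0 ** x) - target

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    # expand outward for curves whose transition lies beyond the default span
    for _ in range(8):
        if g(lo) < 0:
            break
        lo -= 12.0
    else:
        raise BracketingError(f"no lower bracket for EC{100 * beta:g} of {curve.label!r}")
    for _ in range(8):
        if g(hi) > 0:
            break
        hi += 12.0
    else:
        raise BracketingError(f"no upper bracket for EC{100 * beta:g} of {curve.label!r}")
    x = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return 10.0 ** x


def hill_goldbeter_koshland(curve, threshold: str = "max") -> HillEstimate:
    """Goldbeter-Koshland Hill coefficient ``ln(81)/ln(EC90/EC10)``.

    Undefined (``defined=False``) whenever EC10 or EC90 does not exist under
    the chosen threshold convention.
    """
    curve = _as_curve(curve)
    ec10 = effective_concentration(curve, 0.1, threshold)
    ec90 = effective_concentration(curve, 0.9, threshold)
    if ec10 is None or ec90 is None:
        return HillEstimate(method="goldbeter_koshland")
    ec50 = effective_concentration(curve, 0.5, threshold)
    H = math.log(81.0) / math.log(ec90 / ec10)
    return HillEstimate(method="goldbeter_koshland", H=H, ec10=ec10,
                        ec50=ec50, ec90=ec90, defined=True)


def _default_fit_grid(curve: DoseResponseCurve, threshold: str) -> np.ndarray:
    ec10 = effective_concentration(curve, 0.1, threshold)
    ec90 = effective_concentration(curve, 0.9, threshold)
    if ec10 is None or ec90 is None:
        raise ValueError("cannot build a default grid: EC10/EC90 undefined")
    # two decades beyond the transition on each side, 200 points
    return np.logspace(math.log10(ec10) - 2.0, math.log10(ec90) + 2.0, 200)


def hill_fit(curve, grid: Optional[Sequence[float]] = None,
             threshold: str = "max") -> HillEstimate:
    """Least-squares fit of the normalized curve to ``x^H / (k^H + x^H)``.

    The fit runs on the 0-1 normalized scale over a log-spaced grid (default:
    200 points spanning two decades beyond [EC10, EC90]).  For an exact Hill
    function input the exponent is recovered to high precision.  Degenerate
    or non-convergent fits return an undefined estimate.
    """
    curve = _as_curve(curve)
    try:
        x = np.asarray(grid, dtype=float) if grid is not None else _default_fit_grid(curve, threshold)
    except ValueError:
        return HillEstimate(method="hill_fit")
    y = np.array([curve.normalized(u) for u in x])
    if np.ptp(y) < 1e-12:   # constant curve
        return HillEstimate(method="hill_fit")

    def model(logx, H, logk):
        return 1.0 / (1.0 + 10.0 ** (H * (logk - logx)))

    ec50 = effective_concentration(curve, 0.5, threshold)
    p0 = (1.0, math.log10(ec50) if ec50 else 0.0)
    try:
        popt, _ = curve_fit(model, np.log10(x), y, p0=p0, maxfev=10000)
    except RuntimeError:
        return HillEstimate(method="hill_fit")
    H, logk = popt
    if not (H > 0 and np.isfinite(H)):
        return HillEstimate(method="hill_fit")
    return HillEstimate(method="hill_fit", H=float(H), ec50=ec50,
                        defined=True, fit_k=float(10.0 ** logk))


def hill_levitzki(curve, threshold: str = "max",
                  step: float = 1e-6) -> HillEstimate:
    """Levitzki's n50: sensitivity at half-maximal response.

    ``H_Lev = 4 * EC50 * g'(EC50)`` where ``g`` is the curve normalized to
    its maximal output and the derivative is a central difference with
    relative step ``step``.  Undefined when EC50 does not exist.
    """
    curve = _as_curve(curve)
    ec50 = effective_concentration(curve, 0.5, threshold)
    if ec50 is None:
        return HillEstimate(method="levitzki")
    du = step * ec50
    if threshold == "range":
        rng = curve.max_response - curve.basal
        def g(u): return (curve.evaluate(u) - curve.basal) / rng
    else:
        g = curve.normalized
    slope = (g(ec50 + du) - g(ec50 - du)) / (2 * du)
    return HillEstimate(method="levitzki", H=4.0 * ec50 * slope,
                        ec50=ec50, defined=True)


def _perturb(params: ModelParameters, site: int, delta: float) -> ModelParameters:
    if isinstance(params, mwc.MWCParameters):
        c = list(params.c)
        c[site] += delta
        return replace(params, c=tuple(c))
    v = list(params.v)
    v[site] += delta
    return replace(params, v=tuple(v))


def hill_partial(params: ModelParameters, site: int = 0,
                 delta: Optional[float] = None,
                 threshold: str = "max") -> Optional[float]:
    """Forward-difference sensitivity of H to one site's activation parameter.

    Perturbs ``c_site`` (MWC) or ``v_site`` (independent model) by ``delta``
    (default ``1e-4`` times the parameter value) and differences the
    Goldbeter-Koshland H.  The sign is the quantity of interest: negative
    means strengthening the perturbed parameter lowers ultrasensitivity.
    Returns ``None`` when H is undefined at either point.
    """
    if not (0 <= site < params.n):
        raise ValueError(f"site index {site} out of range")
    base = params.c[site] if isinstance(params, mwc.MWCParameters) else params.v[site]
    if delta is None:
        delta = 1e-4 * base
    h0 = hill_goldbeter_koshland(curve_from_params(params), threshold)
    h1 = hill_goldbeter_koshland(curve_from_params(_perturb(params, site, delta)), threshold)
    if not (h0.defined and h1.defined):
        return None
    return (h1.H - h0.H) / delta
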