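"""Independent-sites (non-allosteric) multisite activation model.

The counterpart of the MWC model without conformational coupling between
sites.  Each modified form ``I`` of the target flips between an inactive
state ``B_I`` and an active state ``A_I`` with equilibrium set by
``v^I = prod_{i in I} v_i`` against a deactivation constant ``d``
(analogous to ``L``); at quasi-steady state the form is active a fraction

    Q_I = v^I / (d + v^I)

of the time.  Site modification states are independent: site ``i`` is
modified with probability ``p_i = u/(u + k_i)`` where ``k_i`` is its
dissociation constant.  The dose response is the activity expectation over
the 2^n modification forms.

``v_i > 1`` corresponds to a site whose modification favours activation
(``v_i = 1/c_i`` maps onto the MWC activation parameter).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IndependentParameters",
    "RegimeClassification",
    "activity_fraction",
    "site_occupancy",
    "dose_response",
    "max_response",
    "sigma_function",
    "classify_regime",
]

MAX_ENUMERATION_SITES = 20


@dataclass(frozen=True)
class IndependentParameters:
    """Specification of an independent-sites target.

    ``v``: conformational contributions per site (``v_i > 1`` expected; a
    warning is emitted for ``v_i <= 1``).  ``k``: per-site dissociation
    constants (default 1 everywhere, the convention used throughout the
    model's standard parameterisation).  ``d``: deactivation constant.
    """

    n: int
    v: tuple = ()
    k: tuple = ()
    d: float = 1000.0
    S_T: float = 1.0

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        v = np.asarray(self.v, dtype=float)
        k = np.asarray(self.k if len(self.k) else (1.0,) * self.n, dtype=float)
        if v.size != self.n or k.size != self.n:
            raise ValueError("v and k must each have length n")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("all v_i must be finite and strictly positive")
        if np.any(v <= 1):
            warnings.warn("v_i <= 1 found: the model assumes v_i > 1 "
                          "(modification favouring activation)", stacklevel=3)
        if np.any(k <= 0) or not np.all(np.isfinite(k)):
            raise ValueError("all k_i must be finite and strictly positive")
        if not (np.isfinite(self.d) and self.d > 0):
            raise ValueError(f"d must be a positive real, got {self.d!r}")
        if not (np.isfinite(self.S_T) and self.S_T > 0):
            raise ValueError(f"S_T must be a positive real, got {self.S_T!r}")
        object.__setattr__(self, "v", tuple(v))
        object.__setattr__(self, "k", tuple(k))
        object.__setattr__(self, "d", float(self.d))
        object.__setattr__(self, "S_T", float(self.S_T))

    @classmethod
    def uniform(cls, n: int, v: float, k: float = 1.0, d: float = 1000.0,
                S_T: float = 1.0) -> "IndependentParameters":
        return cls(n=n, v=(v,) * n, k=(k,) * n, d=d, S_T=S_T)

    def to_dict(self) -> dict:
        return {"model": "independent", "n": self.n, "v": list(self.v),
                "k": list(self.k), "d": self.d, "S_T": self.S_T}

    @classmethod
    def from_dict(cls, d: dict) -> "IndependentParameters":
        if d.get("model") != "independent":
            raise ValueError(f"not an independent parameter block: model={d.get('model')!r}")
        return cls(n=d["n"], v=tuple(d["v"]), k=tuple(d.get("k", [1.0] * d["n"])),
                   d=d["d"], S_T=d.get("S_T", 1.0))

    def replace_v(self, site: int, value: float) -> "IndependentParameters":
        v = list(self.v)
        v[site] = value
        return IndependentParameters(n=self.n, v=tuple(v), k=self.k,
                                     d=self.d, S_T=self.S_T)


@dataclass(frozen=True)
class RegimeClassification:
    """Activation regime of a 2-site independent system.

    ``both_or_none``: d > sqrt(v1 v2), efficient activation needs both sites;
    ``linear``: d = sqrt(v1 v2) (within tolerance), Hill number 1;
    ``one_plus``: d < sqrt(v1 v2), one modification nearly suffices.

    ``theorem2_condition`` records whether both singly-modified forms are
    active more than half the time (Q_01 > 1/2 and Q_10 > 1/2, equivalent to
    v_1 > d and v_2 > d), which guarantees the one_plus regime and an H that
    increases with either v_i.
    """

    regime: str
    discriminant: float
    theorem2_condition: bool


def _check_modification_vector(I: Sequence[int], n: int) -> np.ndarray:
    arr = np.asarray(I)
    if arr.shape != (n,) or not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"modification vector must be a length-{n} 0/1 sequence, got {I!r}")
    return arr.astype(bool)


def activity_fraction(params: IndependentParameters, I: Sequence[int]) -> float:
    """Fraction of time a target in modification form ``I`` is active.

    ``Q_I = v^I / (d + v^I)`` with ``v^I`` the product of ``v_i`` over
    modified sites (empty product 1).
    """
    Ivec = _check_modification_vector(I, params.n)
    vI = float(np.prod(np.asarray(params.v)[Ivec])) if Ivec.any() else 1.0
    return vI / (params.d + vI)


def site_occupancy(u: float, k_i: float) -> float:
    """Steady-state modified fraction of a single site, ``p = u/(u + k_i)``."""
    if not (math.isfinite(u) and u >= 0):
        raise ValueError(f"u must be finite and >= 0, got {u!r}")
    if k_i <= 0:
        raise ValueError("k_i must be strictly positive")
    return u / (u + k_i)


def dose_response(params: IndependentParameters, u) -> float:
    """Active target concentration at modifier concentration ``u``.

    Expectation of ``Q_I`` under the product-Bernoulli distribution of
    modification forms: ``S_T * sum_I Q_I prod_{i in I} p_i prod_{i not in I}(1-p_i)``.
    Enumerates the 2^n forms (guarded at n = 20).
    """
    if params.n > MAX_ENUMERATION_SITES:
        raise ValueError(f"enumeration too large: n={params.n} exceeds the "
                         f"{MAX_ENUMERATION_SITES}-site guard")
    v = np.asarray(params.v)
    k = np.asarray(params.k)
    scalar = np.isscalar(u) or np.ndim(u) == 0
    uu = np.atleast_1d(np.asarray(u, dtype=float))
    if not np.all(np.isfinite(uu)) or np.any(uu < 0):
        raise ValueError("all u values must be finite and >= 0")
    p = uu[:, None] / (uu[:, None] + k)          # (m, n)
    out = np.zeros(len(uu))
    for I in itertools.product((0, 1), repeat=params.n):
        Ivec = np.array(I, dtype=bool)
        vI = float(np.prod(v[Ivec])) if Ivec.any() else 1.0
        Q = vI / (params.d + vI)
        w = np.prod(np.where(Ivec, p, 1.0 - p), axis=1)
        out += Q * w
    out *= params.S_T
    return float(out[0]) if scalar else out


def max_response(params: IndependentParameters) -> float:
    """Saturating output ``S_T * Q_(1,...,1) = S_T * prod(v)/(d + prod(v))``."""
    vprod = float(np.prod(params.v))
    return params.S_T * vprod / (params.d + vprod)


def basal_response(params: IndependentParameters) -> float:
    """Activity at zero input: only the unmodified form, ``S_T/(d+1)``."""
    return params.S_T / (params.d + 1.0)


def sigma_function(params: IndependentParameters, u: float, site: int = 0,
                   h: float = 1e-5) -> Optional[float]:
    """Diagnostic for the direction of dH/dv at a single input value.

    sigma(u, v_site) = [df/dv_site - f * (df_inf/dv_site)/f_inf] / (u * df/du),
    with the partial derivatives taken by central differences (relative step
    ``h``).  If sigma is increasing along ``u``, the Hill coefficient
    increases with ``v_site``.  Returns ``None`` where the curve is flat
    (df/du <= 0), where the quotient is undefined.
    """
    if not (0 <= site < params.n):
        raise ValueError(f"site index {site} out of range for n={params.n}")
    if not (math.isfinite(u) and u > 0):
        raise ValueError(f"u must be finite and > 0, got {u!r}")
    v0 = params.v[site]
    dv = h * v0
    up = params.replace_v(site, v0 + dv)
    dn = params.replace_v(site, v0 - dv)
    f_v = (dose_response(up, u) - dose_response(dn, u)) / (2 * dv)
    finf_v = (max_response(up) - max_response(dn)) / (2 * dv)
    du = h * u
    f_u = (dose_response(params, u + du) - dose_response(params, u - du)) / (2 * du)
    if f_u <= 0:
        return None
    f = dose_response(params, u)
    return (f_v - f * finf_v / max_response(params)) / (u * f_u)


def classify_regime(params: IndependentParameters,
                    tol: float = 1e-9) -> RegimeClassification:
    """Classify a 2-site independent system by ``d`` versus ``sqrt(v1 v2)``.

    The linear band is ``|d - sqrt(v1 v2)| < tol * d`` (exact equality is
    measure-zero).  Only defined for ``n = 2``, where the analysis holds.
    """
    if params.n != 2:
        raise ValueError(f"regime classification is only defined for n=2, got n={params.n}")
    geo = math.sqrt(params.v[0] * params.v[1])
    disc = params.d - geo
    if abs(disc) < tol * params.d:
        regime = "linear"
    elif disc > 0:
        regime = "both_or_none"
    else:
        regime = "one_plus"
    thm2 = bool(params.v[0] > params.d and params.v[1] > params.d)
    return RegimeClassification(regime=regime, discriminant=disc,
                                theorem2_condition=thm2)
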