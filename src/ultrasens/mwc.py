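"""Generalized Monod-Wyman-Changeux (MWC) multisite activation model.

A target molecule with ``n`` modification/ligand-binding sites can be in a
relaxed (active, ``R``) or tense (inactive, ``T``) conformation.  ``L`` is the
conformational equilibrium constant between the unmodified tense and relaxed
states (``L > 1`` favours the inactive state at rest).  Each site ``i``
carries a microscopic association constant / modification efficiency
``alpha_i`` and an activation parameter ``c_i``: modification of site ``i``
multiplies the R-to-T equilibrium constant by ``c_i``, so ``c_i < 1`` pulls
the molecule toward the active conformation.  The site-specific
conformational free energy contribution is ``rt * ln(c_i)``.

The closed-form dose response (fraction of target in the relaxed
conformation at modifier concentration ``u``) is

    f(u) = S_T / (1 + L * prod_i (u c_i alpha_i + 1) / (u alpha_i + 1))

and the model is equilibrium-only: detailed balance holds around every cycle
of modification and conformational-flip reactions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MWCParameters",
    "EnergyConvention",
    "StateDistribution",
    "FreeEnergyResult",
    "dose_response",
    "state_distribution",
    "max_response",
    "free_energy",
]

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT_KCAL = 1.987204e-3

#: Enumeration guard: state tables above this site count are refused.
MAX_ENUMERATION_SITES = 20


def _positive_vector(name: str, values: Sequence[float], n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"{name} must be a length-{n} sequence, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"all entries of {name} must be finite and strictly positive")
    return arr


@dataclass(frozen=True)
class MWCParameters:
    """Full specification of a generalized MWC target.

    Parameters
    ----------
    n
        Number of modification / binding sites.
    c
        Activation parameters ``c_i`` (length ``n``, strictly positive).
        ``c_i < 1`` means modification of site ``i`` favours the active state.
    alpha
        Microscopic association constants / modification efficiencies
        ``alpha_i`` (length ``n``, strictly positive).
    L
        Conformational equilibrium constant between unmodified tense and
        relaxed states; ``L > 0``.
    S_T
        Total target concentration (default 1 so outputs are fractions).
    """

    n: int
    c: tuple = ()
    alpha: tuple = ()
    L: float = 1000.0
    S_T: float = 1.0

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        c = _positive_vector("c", self.c, self.n)
        alpha = _positive_vector("alpha", self.alpha, self.n)
        if not (np.isfinite(self.L) and self.L > 0):
            raise ValueError(f"L must be a positive real, got {self.L!r}")
        if not (np.isfinite(self.S_T) and self.S_T > 0):
            raise ValueError(f"S_T must be a positive real, got {self.S_T!r}")
        object.__setattr__(self, "c", tuple(c))
        object.__setattr__(self, "alpha", tuple(alpha))
        object.__setattr__(self, "L", float(self.L))
        object.__setattr__(self, "S_T", float(self.S_T))

    @classmethod
    def uniform(cls, n: int, c: float, alpha: float = 1.0, L: float = 1000.0,
                S_T: float = 1.0) -> "MWCParameters":
        """All-equal-sites convenience constructor."""
        return cls(n=n, c=(c,) * n, alpha=(alpha,) * n, L=L, S_T=S_T)

    def to_dict(self) -> dict:
        return {"model": "mwc", "n": self.n, "c": list(self.c),
                "alpha": list(self.alpha), "L": self.L, "S_T": self.S_T}

    @classmethod
    def from_dict(cls, d: dict) -> "MWCParameters":
        if d.get("model", "mwc") != "mwc":
            raise ValueError(f"not an MWC parameter block: model={d.get('model')!r}")
        return cls(n=d["n"], c=tuple(d["c"]), alpha=tuple(d["alpha"]),
                   L=d["L"], S_T=d.get("S_T", 1.0))


@dataclass(frozen=True)
class EnergyConvention:
    """Thermodynamic convention used to convert activation parameters to
    free energies, ``Delta G_i = r*t*ln(c_i)``.

    ``r`` is the gas constant in kcal/(mol*K) and ``t`` the absolute
    temperature in K; defaults give ``rt ~ 0.5925`` kcal/mol at 298.15 K.
    """

    r: float = GAS_CONSTANT_KCAL
    t: float = 298.15

    def __post_init__(self):
        if not (self.r > 0 and self.t > 0):
            raise ValueError("r and t must be positive")

    @property
    def rt(self) -> float:
        """Thermal energy scale r*t in kcal/mol."""
        return self.r * self.t


@dataclass(frozen=True)
class StateDistribution:
    """Equilibrium distribution over the 2^(n+1) conformation x modification
    states of an MWC target at a fixed input ``u``.

    Labels are ``"R|0110"`` / ``"T|0110"`` strings (conformation, then the
    modification vector in site order).  Weights follow the statistical-weight
    table of the model with the input carried explicitly as ``u^|I|``:
    ``w(R_I) = u^|I| prod_{i in I} alpha_i`` and
    ``w(T_I) = L u^|I| prod_{i in I} alpha_i c_i``.
    """

    labels: tuple
    weights: np.ndarray
    u: float

    @property
    def Z(self) -> float:
        """Partition function (sum of all statistical weights)."""
        return float(np.sum(self.weights))

    @property
    def probabilities(self) -> np.ndarray:
        return self.weights / self.Z

    def relaxed_probability(self) -> float:
        """Total probability of the relaxed (active) conformation."""
        mask = np.array([lab.startswith("R") for lab in self.labels])
        return float(np.sum(self.probabilities[mask]))


@dataclass(frozen=True)
class FreeEnergyResult:
    """Per-site and total conformational free energy contributions (kcal/mol)."""

    per_site: tuple
    total: float
    per_site_mean: float
    maintenance_adjusted: Optional[float] = None


def _validate_u(u: float) -> float:
    u = float(u)
    if not math.isfinite(u) or u < 0:
        raise ValueError(f"input concentration u must be finite and >= 0, got {u!r}")
    return u


def dose_response(params: MWCParameters, u) -> float:
    """Active (relaxed) target concentration at modifier concentration ``u``.

    Implements the closed form
    ``S_T / (1 + L * prod_i (u c_i a_i + 1)/(u a_i + 1))``.  Accepts a scalar
    or an array of ``u`` values.  At ``u = 0`` this reduces to the basal
    activity ``S_T / (1 + L)``.
    """
    c = np.asarray(params.c)
    a = np.asarray(params.alpha)
    if np.isscalar(u) or np.ndim(u) == 0:
        u = _validate_u(u)
        eta = np.prod((u * c * a + 1.0) / (u * a + 1.0))
        return params.S_T / (1.0 + params.L * eta)
    uu = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(uu)) or np.any(uu < 0):
        raise ValueError("all u values must be finite and >= 0")
    eta = np.prod((uu[..., None] * c * a + 1.0) / (uu[..., None] * a + 1.0), axis=-1)
    return params.S_T / (1.0 + params.L * eta)


def max_response(params: MWCParameters) -> float:
    """Maximal response ``f_inf = S_T / (1 + L * prod_i c_i)``.

    The saturating output depends only on the activation parameters (the
    modification efficiencies ``alpha`` cancel in the limit of large ``u``).
    """
    return params.S_T / (1.0 + params.L * float(np.prod(params.c)))


def basal_response(params: MWCParameters) -> float:
    """Activity at zero input, ``S_T / (1 + L)``."""
    return params.S_T / (1.0 + params.L)


def state_distribution(params: MWCParameters, u) -> StateDistribution:
    """Enumerate all 2^(n+1) states with their statistical weights at ``u``.

    The brute-force companion of :func:`dose_response`: summing the relaxed
    state probabilities times ``S_T`` reproduces the closed form.  Guarded to
    ``n <= 20`` to avoid accidental exponential blowup.
    """
    u = _validate_u(u)
    n = params.n
    if n > MAX_ENUMERATION_SITES:
        raise ValueError(
            f"enumeration too large: n={n} exceeds the {MAX_ENUMERATION_SITES}-site guard "
            "(use the closed-form dose_response instead)")
    c = np.asarray(params.c)
    a = np.asarray(params.alpha)
    labels = []
    weights = []
    for I in itertools.product((0, 1), repeat=n):
        Ivec = np.array(I, dtype=bool)
        bits = "".join(map(str, I))
        w_alpha = float(np.prod(a[Ivec])) if Ivec.any() else 1.0
        w_c = float(np.prod(c[Ivec])) if Ivec.any() else 1.0
        u_pow = u ** int(Ivec.sum())
        labels.append(f"R|{bits}")
        weights.append(u_pow * w_alpha)
        labels.append(f"T|{bits}")
        weights.append(params.L * u_pow * w_alpha * w_c)
    return StateDistribution(labels=tuple(labels),
                             weights=np.asarray(weights, dtype=float), u=u)


def free_energy(params: MWCParameters, convention: EnergyConvention = EnergyConvention(),
                M_c: Optional[float] = None) -> FreeEnergyResult:
    """Conformational free energy accounting for an MWC parameter set.

    Per-site contribution ``Delta G_i = rt * ln(c_i)`` (negative when the
    site activates, i.e. ``c_i < 1``) and total ``rt * ln(prod c_i)``.

    When a per-site maintenance cost ``M_c`` (kcal/mol, >= 0) is supplied,
    ``maintenance_adjusted = total + M_c * n``: reading ``total`` as an
    overall energy budget, this is the conformational free energy left after
    paying the maintenance of ``n`` modification cycles.
    """
    rt = convention.rt
    per_site = tuple(rt * math.log(ci) for ci in params.c)
    total = float(sum(per_site))
    adjusted = None
    if M_c is not None:
        if M_c < 0:
            raise ValueError("maintenance cost M_c must be >= 0")
        adjusted = total + M_c * params.n
    return FreeEnergyResult(per_site=per_site, total=total,
                            per_site_mean=total / params.n,
                            maintenance_adjusted=adjusted)
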