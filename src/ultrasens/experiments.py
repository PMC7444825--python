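"""Parameter studies of multisite ultrasensitivity.

Monte-Carlo sampling of activation parameters, mean/CV decompositions of the
Hill coefficient, sweeps of H against the total conformational free energy
(with knee detection and per-site maintenance costs), two-parameter H
heatmaps, and the proportion of random parameter sets in which H responds
with a given sign to a marginal change of one site.

All tabular outputs are pandas DataFrames with fixed column orders, so they
serialize deterministically; every stochastic operation takes an explicit
seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import independent as ind
from . import mwc
from .hill import curve_from_params, hill_goldbeter_koshland, hill_partial

__all__ = [
    "EnergySweep",
    "KneeResult",
    "sample_activation_parameters",
    "mean_cv_experiment",
    "energy_sweep",
    "knee",
    "maintenance_sweep",
    "optimal_site_number",
    "hill_heatmap",
    "HeatmapResult",
    "decreasing_proportion",
]

#: EC threshold convention used for the free-energy sweeps.  The level-off
#: analysis measures ultrasensitivity of the induced response, i.e. ECs as
#: fractions of the basal-to-maximal dynamic range; see docs/methods.md.
SWEEP_THRESHOLD = "range"


# ---------------------------------------------------------------------------
# sampling

def sample_activation_parameters(n: int, low: float, high: float, count: int,
                                 seed: int) -> np.ndarray:
    """Draw ``count`` parameter vectors of length ``n``, log-uniformly.

    Each entry is ``exp(Uniform(ln low, ln high))``, independent across sites
    and draws; this is the standard "sampled logarithmically" scheme for
    activation parameters spanning several orders of magnitude.
    """
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    return np.exp(rng.uniform(math.log(low), math.log(high), size=(count, n)))


# ---------------------------------------------------------------------------
# mean / CV decomposition

def _hill_mwc(c: Sequence[float], L: float, alpha: float = 1.0,
              threshold: str = "max"):
    params = mwc.MWCParameters(n=len(c), c=tuple(c), alpha=(alpha,) * len(c), L=L)
    return hill_goldbeter_koshland(curve_from_params(params), threshold)


def _hill_independent(v: Sequence[float], d: float, k: float = 1.0,
                      threshold: str = "max"):
    params = ind.IndependentParameters(n=len(v), v=tuple(v), k=(k,) * len(v), d=d)
    return hill_goldbeter_koshland(curve_from_params(params), threshold)


def mean_cv_experiment(model: str, n_values: Sequence[int], low: float,
                       high: float, count: int, seed: int, *,
                       L: Optional[float] = None, d: Optional[float] = None,
                       alpha: float = 1.0, k: float = 1.0) -> pd.DataFrame:
    """Compare H of random parameter vectors with H at their mean.

    For each draw the activation vector (``c`` for the MWC model, ``v`` for
    the independent model) is sampled log-uniformly on ``[low, high]``; H is
    computed for the draw and for the surrogate vector with every site set to
    the arithmetic mean.  For the MWC model the two agree closely whenever
    the mean activation is strong (H depends on the mean, not the spread);
    the independent model shows no such collapse.

    Returns a long-format table with one row per (draw, site):
    columns model, n, seed, draw, site, param_value, mean, cv, H, H_at_mean,
    defined.  Undefined-H draws are flagged, not dropped.
    """
    if model == "mwc":
        if L is None:
            raise ValueError("the MWC model requires L")
        hill = lambda vec: _hill_mwc(vec, L, alpha)
    elif model == "independent":
        if d is None:
            raise ValueError("the independent model requires d")
        hill = lambda vec: _hill_independent(vec, d, k)
    else:
        raise ValueError(f"unknown model tag {model!r}")

    rows = []
    for j, n in enumerate(n_values):
        draws = sample_activation_parameters(n, low, high, count, seed + j)
        for idx in range(count):
            vec = draws[idx]
            mean = float(vec.mean())
            cv = float(vec.std(ddof=0) / mean)
            est = hill(vec)
            est_mean = hill(np.full(n, mean))
            for site in range(n):
                rows.append({
                    "model": model, "n": n, "seed": seed, "draw": idx,
                    "site": site, "param_value": vec[site], "mean": mean,
                    "cv": cv, "H": est.H, "H_at_mean": est_mean.H,
                    "defined": est.defined and est_mean.defined,
                })
    return pd.DataFrame(rows, columns=["model", "n", "seed", "draw", "site",
                                       "param_value", "mean", "cv", "H",
                                       "H_at_mean", "defined"])


# ---------------------------------------------------------------------------
# free-energy sweeps and knee detection

@dataclass(frozen=True)
class EnergySweep:
    """H versus total conformational free energy for all-equal sites.

    ``rows`` has columns (c, dG_tot, H, defined), sorted by increasing
    ``dG_tot`` (i.e. from the strongest to the weakest activation).
    """

    rows: pd.DataFrame
    n: int
    L: float
    convention: mwc.EnergyConvention


@dataclass(frozen=True)
class KneeResult:
    """Knee of an (energy, H) sweep: the point of maximal vertical deviation
    from the secant joining the sweep's endpoints.

    The knee marks where additional conformational free energy stops buying
    substantial ultrasensitivity; ``per_site_energy`` is the corresponding
    energy investment per site.
    """

    knee_energy: float
    knee_H: float
    per_site_energy: float
    secant_deviation: float
    degenerate: bool = False


def energy_sweep(n: int, L: float, c_low: float = 1e-4, c_high: float = 0.9,
                 points: int = 1000,
                 convention: mwc.EnergyConvention = mwc.EnergyConvention(),
                 alpha: float = 1.0) -> EnergySweep:
    """Sweep the common activation parameter of an all-equal-sites MWC target.

    A log-spaced grid of ``points`` values of ``c`` on ``[c_low, c_high]``;
    each row records the total conformational free energy
    ``dG_tot = n * rt * ln(c)`` and the Goldbeter-Koshland H of the curve
    (measured on the dynamic-range convention, see module docs).
    """
    if points < 100:
        raise ValueError("points must be >= 100 for a stable sweep")
    cs = np.logspace(math.log10(c_low), math.log10(c_high), points)
    rt = convention.rt
    rows = []
    for c in cs:
        est = _hill_mwc([c] * n, L, alpha, threshold=SWEEP_THRESHOLD)
        rows.append({"c": c, "dG_tot": n * rt * math.log(c), "H": est.H,
                     "defined": est.defined})
    df = pd.DataFrame(rows).sort_values("dG_tot", ignore_index=True)
    return EnergySweep(rows=df, n=n, L=L, convention=convention)


def knee(sweep: EnergySweep, degenerate_tol: float = 1e-9) -> KneeResult:
    """Locate the knee of an H-versus-energy sweep by maximal secant deviation.

    The secant joins the lowest- and highest-energy defined rows; the knee is
    the row maximizing ``|H - secant|``, ties broken toward the more negative
    energy.  The knee H is invariant under affine rescaling of the energy
    axis (in particular under a change of temperature convention).
    """
    df = sweep.rows[sweep.rows["defined"]].reset_index(drop=True)
    if len(df) < 3:
        raise ValueError(f"knee needs at least 3 defined sweep rows, got {len(df)}")
    e = df["dG_tot"].to_numpy()
    h = df["H"].to_numpy()
    a, b = e[0], e[-1]
    secant = h[0] + (h[-1] - h[0]) * (e - a) / (b - a)
    dev = np.abs(h - secant)
    i = int(np.argmax(dev))   # first max = most negative energy on sorted rows
    return KneeResult(knee_energy=float(e[i]), knee_H=float(h[i]),
                      per_site_energy=float(e[i]) / sweep.n,
                      secant_deviation=float(dev[i]),
                      degenerate=bool(dev[i] <= degenerate_tol))


# ---------------------------------------------------------------------------
# maintenance costs

def maintenance_sweep(n_values: Sequence[int], L: float, M_c: float,
                      convention: mwc.EnergyConvention = mwc.EnergyConvention(),
                      c_low: float = 1e-4, c_high: float = 0.9,
                      points: int = 1000) -> pd.DataFrame:
    """Energy sweeps with a per-site maintenance cost folded into the abscissa.

    Maintaining a modification site (e.g. a rapid phosphorylation cycle)
    costs ``M_c`` kcal/mol per site, so the total energetic expenditure that
    buys a conformational contribution ``dG_tot`` with ``n`` sites is
    ``dG_tot - M_c * n`` (more sites push the total budget deeper).  With
    ``M_c = 0`` this reduces exactly to the plain energy sweep.

    Returns the concatenated sweeps with columns
    (n, L, c, dG_tot, adjusted_energy, H, defined).
    """
    if M_c < 0:
        raise ValueError("maintenance cost M_c must be >= 0")
    frames = []
    for n in n_values:
        sw = energy_sweep(n, L, c_low, c_high, points, convention)
        df = sw.rows.copy()
        df.insert(0, "n", n)
        df.insert(1, "L", L)
        df.insert(4, "adjusted_energy", df["dG_tot"] - M_c * n)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def optimal_site_number(n_values: Sequence[int], L: float, M_c: float,
                        budget: float,
                        convention: mwc.EnergyConvention = mwc.EnergyConvention(),
                        c_high: float = 0.9) -> pd.DataFrame:
    """Which site count maximizes H under a fixed total energy budget?

    The budget (kcal/mol, negative) must cover both the conformational
    contribution and the maintenance of every site, so ``n`` sites leave
    ``dG_tot = budget + M_c * n`` for conformational coupling, i.e. a common
    activation parameter ``c = exp(dG_tot / (n * rt))``.  Candidates whose
    required ``c`` exceeds ``c_high`` (the budget cannot even pay the
    maintenance) are infeasible.

    Returns one row per candidate n, columns
    (n, dG_tot, c, H, feasible, optimal), with exactly one optimal row when
    any candidate is feasible.
    """
    rt = convention.rt
    rows = []
    for n in n_values:
        dG = budget + M_c * n
        c = math.exp(dG / (n * rt))
        feasible = 0.0 < c <= c_high
        H = None
        if feasible:
            est = _hill_mwc([c] * n, L, threshold=SWEEP_THRESHOLD)
            H = est.H if est.defined else None
            feasible = est.defined
        rows.append({"n": n, "dG_tot": dG, "c": c, "H": H, "feasible": feasible})
    df = pd.DataFrame(rows)
    df["optimal"] = False
    feas = df[df["feasible"]]
    if len(feas):
        df.loc[feas["H"].idxmax(), "optimal"] = True
    return df


# ---------------------------------------------------------------------------
# heatmaps

@dataclass(frozen=True)
class HeatmapResult:
    """H over a two-parameter log grid, with an undefined mask.

    ``H[i, j]`` is the Hill coefficient at ``(axis1[i], axis2[j])``; NaN where
    undefined (``defined`` False).  For the independent model, ``contour``
    holds the ``d = sqrt(v1 v2)`` curve (the linear-regime locus) as
    ``(v1, v2)`` pairs within the grid range.
    """

    model: str
    axis1: np.ndarray
    axis2: np.ndarray
    H: np.ndarray
    defined: np.ndarray
    contour: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (axis1, axis2, H, defined)."""
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame({"axis1": a1.ravel(), "axis2": a2.ravel(),
                             "H": self.H.ravel(), "defined": self.defined.ravel()})


def hill_heatmap(model: str, range1: tuple, range2: tuple, grid_size: int = 20,
                 *, n: int = 2, L: Optional[float] = None,
                 d: Optional[float] = None, fixed_c: float = 0.01,
                 fixed_v: float = 100.0) -> HeatmapResult:
    """Hill coefficient over a log grid of two sites' activation parameters.

    Sites 1 and 2 sweep ``range1`` x ``range2``; any remaining sites are held
    at ``fixed_c`` (MWC) or ``fixed_v`` (independent model).  Cells where H
    is undefined (basal activity above 10% of maximum) are masked.
    """
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10 per axis")
    ax1 = np.logspace(math.log10(range1[0]), math.log10(range1[1]), grid_size)
    ax2 = np.logspace(math.log10(range2[0]), math.log10(range2[1]), grid_size)
    H = np.full((grid_size, grid_size), np.nan)
    defined = np.zeros((grid_size, grid_size), dtype=bool)
    for i, x1 in enumerate(ax1):
        for j, x2 in enumerate(ax2):
            if model == "mwc":
                if L is None:
                    raise ValueError("the MWC model requires L")
                vec = [x1, x2] + [fixed_c] * (n - 2)
                est = _hill_mwc(vec, L)
            elif model == "independent":
                if d is None:
                    raise ValueError("the independent model requires d")
                vec = [x1, x2] + [fixed_v] * (n - 2)
                est = _hill_independent(vec, d)
            else:
                raise ValueError(f"unknown model tag {model!r}")
            if est.defined:
                H[i, j] = est.H
                defined[i, j] = True
    contour = None
    if model == "independent":
        v1 = ax1
        v2 = d * d / v1
        inside = (v2 >= ax2[0]) & (v2 <= ax2[-1])
        contour = np.column_stack([v1[inside], v2[inside]])
    return HeatmapResult(model=model, axis1=ax1, axis2=ax2, H=H,
                         defined=defined, contour=contour)


# ---------------------------------------------------------------------------
# sign of dH/d(parameter) over random parameter sets

def decreasing_proportion(model: str, n_values: Sequence[int],
                          constants: Sequence[float], count: int,
                          low: float, high: float, seed: int,
                          delta_rel: float = 1e-4) -> pd.DataFrame:
    """Proportion of random parameter sets with the model's expected dH sign.

    For every (n, L) cell of the MWC model: the fraction of draws in which H
    *decreases* when ``c_1`` is marginally increased (strengthening site 1's
    free-energy contribution raises H).  For every (n, d) cell of the
    independent model: the fraction in which H *increases* with ``v_1``.
    Draws where H is undefined at either point are excluded from the
    denominator; their number is reported.

    Columns: n, L_or_d, count, defined_count, proportion.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rows = []
    for j, n in enumerate(n_values):
        for m, const in enumerate(constants):
            draws = sample_activation_parameters(
                n, low, high, count, seed + 1000 * j + m)
            signs = []
            for vec in draws:
                if model == "mwc":
                    params = mwc.MWCParameters(n=n, c=tuple(vec),
                                               alpha=(1.0,) * n, L=const)
                elif model == "independent":
                    params = ind.IndependentParameters(n=n, v=tuple(vec),
                                                       k=(1.0,) * n, d=const)
                else:
                    raise ValueError(f"unknown model tag {model!r}")
                base = vec[0]
                grad = hill_partial(params, site=0, delta=delta_rel * base)
                if grad is not None:
                    signs.append(grad < 0 if model == "mwc" else grad > 0)
            defined_count = len(signs)
            prop = float(np.mean(signs)) if defined_count else None
            rows.append({"n": n, "L_or_d": const, "count": count,
                         "defined_count": defined_count, "proportion": prop})
    return pd.DataFrame(rows, columns=["n", "L_or_d", "count",
                                       "defined_count", "proportion"])
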