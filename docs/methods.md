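# Methods

## Models

### Generalized MWC target

The target is an equilibrium two-conformation molecule: relaxed (R, active)
and tense (T, inactive), with `n` modification/binding sites. The model
state space is the `2^(n+1)` combinations of conformation and modification
vector `I ∈ {0,1}^n`. Statistical weights at modifier concentration `u` are

    w(R_I) = u^|I| · ∏_{i∈I} α_i          w(T_I) = L · u^|I| · ∏_{i∈I} α_i c_i

so the partition function factorizes,

    Z(u) = ∏_i (1 + u α_i) + L · ∏_i (1 + u c_i α_i),

and the active fraction is `f(u) = S_T · ∏(1+uα_i) / Z(u)`, equivalently
the closed form used throughout:
`f(u) = S_T / (1 + L ∏ (u c_i α_i + 1)/(u α_i + 1))`. The printed
tabulations of the n=2 and n=3 state weights correspond to these weights at
`u = 1`; the implementation carries `u` explicitly. Detailed balance holds
by construction (the weights derive from a potential), and the test suite
verifies it around every modify–flip–demodify–flip cycle.

Assumptions inherited from the model class: binding/modification is at
equilibrium (no kinetics, no energy-consuming proofreading); all relaxed
forms share one activity and all tense forms another; for phosphorylation,
the kinase/phosphatase pair is far from saturation so `u` acts like a
ligand concentration.

**Parameters.** `c_i > 0` (dimensionless): factor applied to the R↔T
equilibrium when site `i` is modified; `c_i < 1` activates, `c_i = 1` makes
the site inert (the dose response is pointwise that of an `(n−1)`-site
target). `α_i > 0`: microscopic association constant or modification
efficiency; a common rescaling of all `α_i` only shifts the input axis, so
Hill coefficients are invariant to it and `α_i = 1` is the default in all
studies. `L > 0`: conformational equilibrium of the unmodified target;
basal activity is `S_T/(1+L)`, so `L > 9` keeps the unstimulated target
below 10% active. `S_T > 0`: total target, default 1 (outputs are
fractions; all H measures are invariant to it).

**Free energies.** `ΔG_i = rt·ln(c_i)` kcal/mol with
`r = 1.987204×10⁻³ kcal/(mol·K)` and `t = 298.15 K` by default
(`rt ≈ 0.5925` kcal/mol). The temperature convention is configurable and
nothing structural depends on it: the knee statistic below is invariant
under affine rescaling of the energy axis.

### Independent-sites target

The non-allosteric counterpart drops the shared conformational flip. Each
modification form `I` equilibrates between inactive and active states with
constant `v^I/d` (`v^I = ∏_{i∈I} v_i`, `v_i = 1/c_i` in MWC terms), giving
an activity `Q_I = v^I/(d+v^I)` — the fraction of time that form is active.
The activation/deactivation step is assumed fast relative to modification,
so `Q_I` is used directly rather than integrating the relaxation ODE.
Site occupancies are independent Bernoulli variables with
`p_i = u/(u+k_i)`; the dose response is the expectation of `Q_I`. The
dissociation constants default to `k_i = 1`, the convention used in all
parameter studies. Basal output is `S_T/(d+1)` and the saturating output is
`S_T·Q_(1,…,1)`.

For `n = 2` the regime classification compares `d` with `√(v₁v₂)`:
`d` larger → *both-or-none* (activation effectively requires both sites;
strengthening a site lowers H), equal → *linear* (`H = 1`), smaller →
*1+* (one modification nearly suffices; H rises with `v`). The linear band
uses the tolerance `|d − √(v₁v₂)| < 10⁻⁹·d` since exact equality is
measure-zero. The sufficient condition `Q_01 > ½` and `Q_10 > ½`
(equivalently `v₁ > d` and `v₂ > d`) is reported alongside. The σ
diagnostic `σ(u) = [∂f/∂v − f·(∂f∞/∂v)/f∞]/(u·∂f/∂u)` is computed with
central differences (relative step `10⁻⁵`); monotonicity of σ in `u`
implies H increasing in `v`. These analytic facts are checked numerically
(finite differences over random draws), not re-proved; classification
beyond `n = 2` is deliberately not offered — only the numerical H-gradient.

## Measuring ultrasensitivity

Effective concentrations are roots of `f(u) = target` found by Brent's
method on `log10(u)`, starting from the bracket `[10⁻¹², 10¹²]` and
expanding outward when needed (`xtol 10⁻¹³`, relative tolerance near
machine precision). Two threshold conventions are supported:

- **max** (default): `target = β·f∞`. EC_β is *undefined* when the basal
  activity already meets the threshold (`basal ≥ β·f∞`) — there is no
  crossing. Undefined H values are reported as flags, not exceptions; this
  is the convention behind the masked (white) cells of the two-parameter
  heatmaps, where weakly activating parameter corners leave the response
  range too shallow for an EC10.
- **range**: `target = basal + β·(f∞ − basal)`, i.e. β of the induced
  dynamic range. Defined for any non-degenerate saturating curve.

The free-energy sweeps (and hence the knee table) use the **range**
convention: near the weak-activation end of a sweep the maximal output
approaches the basal activity, and under the max convention EC10 → 0 there,
collapsing H toward zero — an artefact of measuring the *absolute* output
rather than the *induced response*. The range convention measures the
ultrasensitivity of the induced response and produces level-off curves with
a stable H → 1 tail, which is what the knee analysis needs (and what
reproduces the reference knee table). Single-curve estimates and heatmaps
keep the max convention. Both are exposed via the `threshold` argument.

Estimators:

- **Goldbeter–Koshland**: `H = ln(81)/ln(EC90/EC10)`; exactly `h` on a pure
  Hill function `x^h/(k^h+x^h)`; invariant under rescaling of the input
  axis.
- **Hill fit**: nonlinear least squares of the normalized curve against
  `x^H/(k^H+x^H)` on the 0–1 scale, parameterized as `(H, log10 k)` with
  the GK EC50 as the initial half-max guess; default grid 200 log-spaced
  points spanning two decades beyond `[EC10, EC90]`.
- **Levitzki n50**: `4·EC50·g′(EC50)` with `g` the normalized curve and a
  central difference of relative step `10⁻⁶`.

Sensitivities `∂H/∂c_i` (or `∂H/∂v_i`) use a forward difference with
default step `10⁻⁴` times the parameter value; the sign is the quantity of
interest. Draws where H is undefined at either point return no value and
are excluded from proportions with separate accounting.

## Parameter studies

**Sampling.** Activation parameters are drawn log-uniformly,
`exp(Uniform(ln low, ln high))`, independently per site and draw — the
standard scheme for parameters spanning orders of magnitude. Default ranges
are `[10⁻⁴, 0.9]` for `c` and `[10, 10⁴]` for `v`; every stochastic
operation takes an explicit seed and is bit-for-bit reproducible.

**Mean/CV decomposition.** Each random vector is paired with an all-equal
surrogate at its arithmetic mean; comparing H across the pair separates the
effect of the mean activation from its spread. For the MWC model with
strong sites (mean c < 10⁻²) the pair collapses (median gap well below
0.05 in H) — the operational form of the result that H depends on the mean
of the activation parameters to first order, with mean-preserving
perturbations entering only at second order. The acceptance suite verifies
the scaling directly: halving a mean-preserving perturbation shrinks the H
gap ~4-fold (quadratic), halving a mean shift shrinks it ~2-fold (linear).
The independent model shows no such collapse.

**Energy sweeps and knee.** All-equal-site targets are swept over a
log-spaced grid of the common `c` (default 1000 points on `[10⁻⁴, 0.9]`;
knee values move by less than 0.02 between 1000 and 4000 points). Each row
records `ΔG_tot = n·rt·ln c` and H. The knee is the row maximizing the
vertical deviation from the secant through the sweep's endpoint rows, ties
broken toward the more negative energy; an affine H-versus-energy curve is
flagged degenerate. Because the deviation is vertical, the knee H is
invariant under any affine map of the energy axis (temperature change,
per-site versus total energy). The knee *abscissa* is less well
conditioned: the deviation profile is flat near its maximum (for n=8 it
stays within 1% of the maximum across ≈3 kcal/mol), so the reported knee
energy can shift by a few percent under small changes of convention while
the knee H barely moves. Knee energies should therefore be read as the
centre of a shallow plateau, not a sharp point.

**Maintenance costs.** Keeping a modification site running (rapid
modify/demodify cycling) is modelled as a fixed cost `M_c` kcal/mol per
site. The total energetic expenditure that buys a conformational
contribution `ΔG_tot` with `n` sites is `ΔG_tot − M_c·n` on the sweep's
abscissa (deeper budget for more sites); conversely, a total budget `B`
leaves `B + M_c·n` for conformational coupling, i.e. a common activation
parameter `c = exp((B + M_c·n)/(n·rt))`. A candidate `n` is infeasible when
that `c` exceeds the sweep ceiling (the budget cannot pay the upkeep). The
optimal-`n` query evaluates H at each feasible candidate and returns the
argmax; with `M_c = 4` and `B = −20` kcal/mol at `L = 1000` this yields
n = 3, and the optimum is non-increasing in `M_c`. With `M_c = 0` the
analysis reduces exactly to the plain sweep.

**Proportion studies.** For each `(n, L)` or `(n, d)` cell, random
parameter vectors are drawn and the sign of the finite-difference H
gradient at site 1 is tallied (MWC: fraction decreasing; independent:
fraction increasing). Counts default to 1000 draws per cell; binomial noise
at that count is ≈±1.6 percentage points. Undefined draws are excluded from
the denominator and reported.

## What the generators emulate — and what they do not

The synthetic parameter ensembles *are* the study conditions: log-uniform
site strengths over the stated ranges, equal modification efficiencies,
fixed `L`/`d`, unit dissociation constants. They emulate heterogeneous
multisite proteins whose sites differ in conformational contribution. They
do **not** emulate measurement noise, finite titration grids, kinetic
(non-equilibrium) effects, cooperativity in the modification step itself,
or cross-talk between efficiency `α_i` and strength `c_i`. Passing tests
therefore validate the model mathematics and its parameter dependence, not
the fit of either model to any particular experimental system.

## Numerical choices and degenerate inputs

- Root finding: Brent on `log10 u`, bracket `[10⁻¹², 10¹²]` expanded up to
  8×12 decades; failure to bracket raises a distinct error from the
  legitimate "no crossing" (undefined) case.
- Enumeration guard: state tables and the independent-model sum refuse
  `n > 20` (2²¹ states) with an explicit error; the MWC closed form has no
  such limit.
- Constant or affine curves: Hill fit returns an undefined estimate;
  the knee flags `degenerate=True` with zero secant deviation.
- `v_i ≤ 1` in the independent model is allowed but warns (the model's
  intended regime is activating modifications).
- CSV serialization writes undefined values as empty cells with a boolean
  flag column, uses a fixed column order, and attaches a `.meta.json`
  sidecar with the producing configuration; tables round-trip at full
  float precision.

## Known limitations

- Equilibrium only: no time courses, no energy-consuming amplification.
- No fitting of model parameters to experimental dose-response data; the
  package is for forward exploration of the parameter space.
- Regime classification is analytic only for the 2-site independent model.
- No confidence intervals on H (point estimates only).
- The knee abscissa is intrinsically shallow (see above); comparisons of
  knee *energies* across conventions are reliable only to a few percent,
  while knee H values are robust.
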