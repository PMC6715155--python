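# Methods

`multiweb` simulates the dynamics of ecological communities whose species
are coupled by feeding *and* by six kinds of non-trophic interactions
(NTIs), and quantifies what those extra interaction layers do to species
diversity, community biomass and production, and the slope of the
biodiversity–ecosystem-functioning (BEF) relationship.

## The trophic core

Communities follow an allometric bioenergetic model.  Biomass density
`B_i` (mass per unit area) of species `i` obeys

    dB_i/dt = g_i (r_i G_i + Σ_j ε_ij F_ij − x_i) B_i
              − Σ_k B_k F_ki − d_i B_i

with logistic plant growth `G_i = 1 − B_i/K_i`, a multi-prey Holling
functional response with Hill exponent `1 + q`,

    F_ij = w_i a_ij B_j^{1+q} /
           [ m_i (1 + I_ij + w_i Σ_{k∈prey(i)} a_ik h_ik B_k^{1+q}) ],

metabolic demand `x_i`, and background mortality `d_i`.  `w_i` is the
reciprocal of the structural diet size (fixed for the whole run — it
describes how the consumer splits its foraging across the web's links,
not across currently-abundant prey).  `I_ij` is the Beddington–DeAngelis
interference term described below; intraspecific interference
`i0_intra B_i` (default 0.8) is always active — without it, steady-state
diversity drops sharply.

All rates derive from body mass `m` through quarter-power scalings, with
mass anchored at the plant mass (`m = expo^(TL−1)`, `expo = 50`):

| quantity | scaling | constants |
|---|---|---|
| plant growth | `r = r0 m^−0.25` | `r0 = 1` (sets the time scale) |
| carrying capacity | `K = K0 m^0.25` | `K0 = 1` |
| metabolism (consumers) | `x = 0.314 m^−0.25` | plants: 0 (folded into `r`) |
| mortality | `d = d0 · x_sp · m^−0.25` | `d0 = 0.1`; `x_sp` 0.138 (plants) / 0.314 |
| capture | `a_ij = a0 m_i^0.45 m_j^0.15` | `a0 = 50`; a sessile end drops its mass factor |
| handling | `h_ij = h0 m_i^−0.48 m_j^−0.66` | `h0 = 0.3` |
| assimilation | `ε` = 0.45 (plant resource) / 0.85 | |
| Hill coefficient | `q = 0.5` | type II–III intermediate |

### Which trophic level sets body mass

Two trophic-level variants are computed for every web: the prey-averaged
level (`TL_i = 1 + mean of the resources' levels`, fractional) and the
shortest-chain level (`1 +` length of the shortest food chain to a
plant, integer).  Body mass uses the **shortest-chain** level; the
prey-averaged level is used to classify species into the reporting bands
TL = 1, 2 ≤ TL ≤ 3, TL > 3.

This is a substantive design choice.  Because capture rates rise with
consumer mass more slowly (`m^0.45`, and `1/m_i` in front of the
response) than metabolic costs fall (`m^−0.25`), prey-averaged masses
(up to `50^4` and beyond) starve essentially every species above TL 3:
communities collapse to ~25–45 survivors, plants routinely lose all
their consumers, and the "no disconnected plant" community filter (below)
accepts of order 1 in 10⁴ webs — a regime in which none of the ensemble
designs can operate, and in which mortality-decrease is no longer the
weakest interaction type, contradicting the calibration structure the
intensity ranges encode.  With shortest-chain masses, 60–80 of 100
species persist, every plant keeps at least one consumer in ~70% of
webs, all six NTI effect signs and their ordering (mortality decrease
weakest) come out as expected.  Ecologically: the shortest energy path
to the producers is what bounds how large a consumer the web can
actually sustain.

## The six non-trophic mechanisms

Each NTI makes one trophic parameter a linear function of the biomass of
the species exerting the effect.  Layers are Bernoulli-sampled over
type-specific eligible pairs (probabilities in parentheses; each
calibrated to ~100 non-zero matrix elements per web):

- **Competition for space** (0.098; sessile → sessile, directed):
  `g_i = 1 − c0 Σ_l γ_il B_l` with `γ_il = γ0 m_l^{2/3}`; applies only
  while the target's net growth `(r_i G_i + Σ ε F − x_i)` is positive,
  otherwise `g_i = 1`.  `g` is not clamped below zero; within the
  calibrated `c0 ≤ 0.012` it stays positive in practice.
- **Predator interference** (0.15; mobile consumers sharing ≥ 1 prey,
  symmetric): `I_ij = i0_intra B_i + i0 Σ_{s∈pred(j), s≠i} δ_si B_s`,
  `δ_si = 1/(1 + |ln m_s − ln m_i|)` — strongest between equal-mass
  predators.  The sum runs over the *other predators of the focal prey*,
  per prey, and natural logarithms are used (the base only rescales δ).
- **Refuge provisioning** (0.033; sessile → any consumed species):
  every predator's capture rate on the protected prey `j` becomes
  `a_ij / (1 + r0_refuge Σ_k φ_kj B_k)` — vanishing as facilitator
  biomass grows.
- **Recruitment facilitation** (0.063; consumer → plant):
  `r_i → r_i (1 + e0 Σ_k η_ki B_k)`.  Sources are restricted to
  non-plant species: with plant sources included the stated probability
  would produce ~125 links instead of the ~100 the per-type calibration
  requires (0.063 × 80 consumers × 20 plants ≈ 101).
- **Mortality increase / decrease** (0.01 each; any ordered pair):
  `d_i → d_i (1 + n0 Σ n_ki B_k) / (1 + p0 Σ p_ki B_k)`.

"Link" counts follow the per-element convention: a symmetric
interference pair contributes two non-zero matrix elements, and each
element is non-zero with the stated probability.  With all six
intensities zero the equations reduce *exactly* — same floating-point
operations — to the trophic-only model, which the paired experimental
design exploits.

Intensity ranges spanning a ~2.5% (minimum) to ~10% (maximum) effect on
diversity when each type acts alone: `i0 ∈ [0.75, 3]`,
`r0_refuge ∈ [0.25, 1.75]`, `c0 ∈ [0.0045, 0.012]`, `e0 ∈ [0.15, 1.8]`,
`n0 ∈ [0.75, 3]`, `p0 ∈ [5, 20]` (the decrease-in-mortality effect
saturates well below 10% however large `p0`).  In this implementation
the realized mean effects at the range maxima keep the expected signs
and ordering but are weaker than the nominal 10% for competition and
recruitment (≈ 2–4%); `calibrate_intensity` performs the bisection
calibration for users who want ranges matched to this code's dynamics,
and the shipped ranges are left at their nominal values rather than
recalibrated.

## Network generation

Trophic webs come from the classic niche model: niche values uniform on
[0, 1], feeding-range fraction Beta(1, 1/(2C) − 1) (expected connectance
C = 0.06), range centre uniform on [range/2, niche value].  Whole webs
are rejection-sampled until they have exactly 20 plants (species with
empty diets), no directed cycle of length ≥ 2 (cannibalism allowed), and
no isolated species; duplicate diets are not rejected.  Rejection is
capped at 10,000 attempts (typical acceptance ≈ 1%, dominated by the
exact-plant-count and acyclicity conditions; ~600 links per accepted
web).  Mobility is a per-species Bernoulli trait (sessile with
probability 0.8 for plants, 0.2 otherwise), redrawn wholesale until
exactly 33 species are sessile.

## Simulation protocol

Initial biomasses are i.i.d. uniform on [0.05, 1] — chosen as a
moderate stock below carrying capacity; the steady state is insensitive
to this choice (the attractor, not the start, determines survivors in
the webs tested).  Systems are integrated with an embedded
Runge–Kutta–Fehlberg 4(5) pair to t = 5000, long enough for the dynamics
to settle; the final state is treated as the steady state with no
averaging window.  A species whose biomass falls below 10⁻⁶ at an
accepted step is clamped to zero (zero is an exact fixed point of the
right-hand side, so extinction is absorbing); threshold checks happen at
accepted steps only, not via event location — the threshold sits far
below dynamical scales.  Solver tolerances default to rtol 10⁻⁸ /
atol 10⁻¹⁰ for single runs; ensemble experiments use rtol 10⁻⁶ /
atol 10⁻⁹, which leaves survivor sets unchanged and total biomass within
0.1% on test fixtures while keeping ensembles tractable.  Two backends
— a compiled RKF45 loop and SciPy's RK45 on the NumPy right-hand side —
produce matching trajectories and are cross-checked in the test suite.

At the steady state we record diversity (surviving species), total
biomass, and total production (the `g_i(r_i G_i + Σ ε F − x_i) B_i` term
summed over survivors), overall and per trophic-level band, plus the
normalized ratio `(with − without)/without` between paired runs.

## Experimental designs

All designs pair each with-NTI run against a trophic-only baseline
sharing the web, traits, parameters and initial biomasses.  A web enters
an ensemble only if its baseline run ends with every surviving plant
still having at least one surviving consumer ("no disconnected plant");
with-NTI runs must pass the same filter, and failing layer draws are
resampled up to a cap with all rejections tallied in the output's
`attrs`.

- **Single-NTI sweep**: one type, 8 evenly spaced intensities across its
  range (the grid size is a choice; the range endpoints are what carry
  meaning), one layer per (web, draw) reused across the grid; reports
  per-intensity mean ratios and the diversity-ratio-vs-intensity OLS
  slope.
- **Mixed ensemble**: the five retained types (mortality decrease is
  dropped for its negligible effect), quartered probabilities for the
  four detrimental types (≈ 25 links each, balancing the ≈ 100
  recruitment links), intensities uniform over their ranges.
- **Link-count ensemble**: fixed maximal intensities (`i0 = 3`,
  `r0_refuge = 1.75`, `c0 = 0.012`, `e0 = 1.8`, `n0 = 3`), link budgets
  (positive, negative) ∈ {(100, 100), (50, 100), (100, 50)} split
  equally over the included detrimental types.
- **Sensitivity suite**: the mixed ensemble repeated with `q ∈ {0.3,
  0.7}`, `a0 ∈ {10, 250}` (`a0 = 10` pairs with `h0 = 0.1` to avoid mass
  extinctions), `expo ∈ {25, 75}`, one at a time; reports BEF slopes
  with/without NTIs per setting.
- **Calibration**: bisection on a type's intensity until the mean
  diversity ratio over a small ensemble hits a signed target within
  ±0.005; unreachable targets (mortality decrease at ±10%) return the
  maximum achieved effect instead of converging.

The default desk-scale size is 20 webs × 10 draws; `scale_factor`
shrinks both proportionally and the full-scale ensembles (100 webs
× 50 draws for sweeps, 1000 × 100 for the mixed ensemble) are reachable
by raising the sizes.  The sign structure of the effects is stable at
desk scale; only statistical power changes, and for slope-comparison
questions the number of *webs* (each contributing one baseline) is what
carries the power, not the draws per web.

## Statistics

Intensity–response and BEF slopes are unweighted OLS with two-sided
t-tests.  Slope equality between the with- and without-NTI clouds is the
interaction term of the pooled model `y ~ x + group + x:group` — the
classic ANCOVA homogeneity-of-slopes test, with no heteroscedasticity
correction.  The without-NTI cloud uses one point per web (the baseline
is shared by all of a web's draws).  Diversity-ratio histograms use bins
of width 0.01 centred on multiples of 0.01 (diversity is integer-valued
over ~100 species, so ratios are near-multiples of 0.01); per-bin mean
NTI intensities are min–max normalized to [0, 1] over each type's
configured range.

## Randomness and reproducibility

A single root seed drives everything through named spawn keys
(`(stage, web attempt, draw, redraw)`), so any web, layer draw or run can
be regenerated in isolation and ensembles are reproducible independent
of execution order.  Identical seeds give bit-identical webs, layers,
initial biomasses and (per backend) trajectories.

## What the generator does and does not emulate

The synthetic webs reproduce the *structural rules* attributed to rocky
intertidal communities — niche-model feeding structure, a fixed sessile
guild, and the per-type NTI eligibility rules — with link positions
otherwise random.  They do not reproduce any empirical web's degree
distribution, the observed inter-layer correlations of real multiplex
networks, spatial structure, or environmental fluctuations.  Passing
tests therefore demonstrate the model's internal logic and calibration
(link budgets, effect signs, pairing equivalence, BEF slope change), not
fidelity to any particular field system.

## Known limitations

- Steady state is "state at t = 5000": persistent oscillations, if any,
  are sampled at an arbitrary phase rather than averaged.
- The net-growth switch on the competition factor makes the right-hand
  side piecewise-smooth; the adaptive solver handles the kinks by step
  rejection, at some cost in step count.
- `w_i` is never re-normalized as prey go extinct, so consumers with
  extinct prey retain a structurally diluted attack rate.
- At the maximal shipped intensities, competition and recruitment
  effects on diversity are weaker here (≈ −2 to −4% / +2 to +4%) than
  the nominal ±10% their ranges encode; interference and refuge land
  near −8%.
  The shipped ranges are kept at their nominal values; use
  `calibrate_intensity` to re-derive ranges matched to this code.
- Alternative refuge formulations (e.g. raising the predators' Hill
  coefficient), nutrient-explicit producers, adaptive foraging and
  temperature dependence are out of scope.
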