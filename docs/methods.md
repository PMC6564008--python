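# Methods

## Model structure

The package simulates one growing season of a soybean aphid population
attacked by the parasitoid *Aphelinus certus*, on a daily projection
interval, as two coupled stage-classified matrix models.

**Host.** Five stages (stadia S1–S4, adult). The transition/fertility
matrix **A** has stage survival `P_i` on the diagonal, transitions `G_i`
on the subdiagonal, adult fecundity `F_5 = 2.56` offspring/adult/day at
(1,5), and a 0.016 probability at (3,1) of a first stadium being sampled
as a third stadium a day later (fast molters crossing two stage
boundaries between samples). For every juvenile stage
`P_i + G_i (+ skip) = 1`: the life table contains no juvenile mortality
term of its own — juvenile losses come from parasitism, density
dependence, and temperature. Density dependence is logistic on the total
living host population `N = Σn + p1` (parasitized-but-living hosts
compete like healthy ones): the daily increment `(H∘A∘C − I)n` is
multiplied by `φ = (K − N)/K`, `K` = 6000 aphids/plant.

**Parasitoid.** Three stages: egg+larva inside a living host (`p1`),
mummy (`p2`), adult (`p3`). Survival/transition entries are the measured
daily probabilities; adult survival is host-density dependent through a
Verhulst (logistic) lifespan curve,
`P3(N) = 0.932 / (1 + 13.5·e^(−0.562·N))` — near-certain starvation
without hosts, saturating at the measured 0.932/day maximum. (An
alternative mapping `P3 = 1 − 1/lifespan` is available via
`survival_mode="inverse_lifespan"`.) Adult fertility is defined by attack
bookkeeping, not a fecundity constant: every host that fails to escape
receives one egg, `F3·p3 = Σ(1 − g_i)·n_i`.

**Coupling.** The escape probabilities follow a type II functional
response: per-female attack pressure on stage *i* is
`a_i·α / (1 + a_i·α·T_h·N)` with search rate `α = 0.979`
plant·wasp⁻¹·d⁻¹, handling time `T_h = 0.045` d, and attack shares
`a_i = 0.2` (no measured stage preference). Only females attack
(`p₃♀ = p3·(1 − 0.412)`; 0.412 is the brood proportion male). Because
already-parasitized hosts cannot be re-parasitized, the escape function
carries the available-host fraction `Σn/N`. Two readings are
implemented:

* `escape_mode="literal"` (default): `g_i = exp(−a_i α p₃♀ / (1 + a_i α
  T_h N)) · (Σn/N)` — the availability factor multiplies the
  exponential.
* `escape_mode="scaled_exponent"`: the factor scales the exponent
  instead, so `g = 1` exactly when no adult females are present.

The scaled reading is the more parsimonious mechanistic story (the
literal one deducts "escape" even from hosts that merely shared a plant
with parasitized neighbors), but it produces a qualitatively different —
and much weaker — control outcome: at the default parameterization the
wasp never catches the outbreak and peak pest reduction is near zero.
The literal reading yields stable dynamics and suppression of the order
reported for this system, so it is the default; the flag preserves the
other reading for comparison, and both are exercised in the tests.

**Post-parasitism reproduction.** Parasitized hosts keep reproducing for
a short time (`J = (0, 0, 0.563, 1.521, 1.471)` offspring/host/day by
stage at parasitism). Lacking a stage-structured bookkeeping of *when*
each `p1` member was parasitized, the parasitized pool is assumed to
mirror the unparasitized stage structure: recruits `Σ p1·J_i·n_i/N` are
added to `n1` each day.

## Numerical treatment of the carrying-capacity brake

The explicit one-day update `n ← n + φ·(M − I)n` is a forward-Euler
discretization of logistic growth and is well behaved only for
`φ ∈ [0, 1]`. When `N` overshoots `K` (φ < 0) while parasitism pressure
makes `M` sub-replacement, the raw formula multiplies *negative* stage
increments by a *negative* factor — mortality becomes growth and the
update diverges in a few steps. The shipped update therefore
distinguishes the two regimes: for `φ ≥ 0` it is the formula above,
verbatim; for `φ < 0` growth components of `(M − I)n` are still reversed
by `φ` (the population declines toward `K`) but decline components
proceed at their intrinsic rate rather than being amplified.

The parasitoid update is additively decomposed so the brake acts on the
host-resident stage only:
`p ← [p1,0,0] + φ⁺(V − I)[p1,0,0] + φ⁺[V13·p3,0,0] + V[0,p2,p3]` with
`φ⁺ = max(φ, 0)`. Throttling the egg-inflow term `V13·p3` by the same
factor as the host-side parasitism losses keeps the two books consistent
— without it, hosts enter the parasitized pool faster than they leave
the healthy pool as `N → K`, individuals are created from nothing, and
the coupled system destabilizes. At `N = K` the egg+larva stage is
frozen (no deaths, no maturation, no new eggs) while mummies and adults
evolve freely; above `K` the stage dies at its intrinsic rate. All state
vectors are clamped at zero after each step; densities are continuous
(no demographic stochasticity).

## Temperature

Vital rates were measured at 25 °C. Each day's matrices are rescaled by
`c = λ(T)/λ(25) = e^(r(T) − r(25))` with:

* host: modified Logan curve `r(T) = e^(ρT) − e^(ρT_max − (T_max−T)/Δ)`,
  ρ = 0.14 °C⁻¹, T_max = 34.9 °C, Δ = 7.1 °C (these three constants are
  assigned to symbols by dimensional consistency with the source curve);
* parasitoid: Brière-1 curves `r(T) = a·T·(T−T0)·√(T_max−T)` for
  egg→mummy (a = 1.19e-4, 7.8–35.7 °C) and mummy→adult
  (a = 1.37e-4, 11.6–36.9 °C); the adult entry and the fertility entry
  use the mummy→adult factor.

Transition entries scale by `c`, diagonal (resampling) entries by the
compensating `cP_i = (1 − (1−P_i)c)/P_i` (so `cP_i·P_i + c·G_i = P_i +
G_i`: warming shifts probability mass from staying to advancing without
leaking individuals), and fertility entries by `c⁴` (the matrix
approximation of reproduction's exponential thermal response). The
λ-ratio approximation is trusted on 5–30 °C only; input temperatures are
clamped to that window before computing `c`, and `cP` is clamped to
`[0, 1/P_i]` so scaled survivals stay probabilities. At exactly 25 °C
the scaling is the identity, bit for bit.

## Field-season protocol and synthetic weather

Hosts colonize on June 22 (all in stadium 1, density drawn uniformly
from 0.3–1.82 aphids/plant); parasitoids arrive 20 days later as mummies
(0.15–4.08/plant). 90 days are simulated; 10 000 replicates. Each
replicate is *paired*: the with- and without-parasitoid runs share the
host inoculum and the weather series, which removes initial-condition
noise from the peak-reduction statistic. Summary statistics: peak total
host density and its day, percent peak reduction, the fraction of
replicates below the economic threshold (ET = 250 aphids/plant) and at
or below the economic injury level (EIL = 674), and the three parasitism
measures on each replicate's peak day —

* parasitism rate `Σ(1−g_i)n_i/N` (flow: fraction attacked per day),
* percent parasitism `100·p1/N` (stock),
* mummy fraction `p2/(N + p2)` (the field-countable stock).

Because the stocks integrate the flow, their seasonal peaks lag the
rate's peak; the tests assert this on the ensemble median trajectory.

The default weather is a synthetic climatology,
`T(doy) = 23.5 − 16·(1 − cos(2π(doy − 205)/365)) + offset + N(0, 3²)` °C
— seasonal maximum 23.5 °C in late July, annual semi-amplitude 16 °C,
daily weather noise 3 °C, matching upper-Midwest (southwestern
Minnesota) climate normals. It reproduces the seasonal envelope and
day-to-day variability of a station record but not autocorrelated warm
or cold spells, so ensemble statistics under it show the model's
behavior under a *typical* season, not a particular historical one;
quantities sensitive to the weather realization (threshold fractions
especially) vary by several percentage points across climatology seeds.
A GHCN-Daily CSV reader (`TAVG` or `(TMAX+TMIN)/2`, tenths-°C
autodetected, gaps ≤ 3 d interpolated) accepts real station data.

## Sensitivity analyses and variants

All sweeps run single paired simulations at the median initial densities
(1.06 hosts, 2.115 mummies per plant), varying one input: adult
parasitoid lifespan 2–26 d (mapped to constant daily survival
`P3 = 1 − 1/L`, density dependence disabled), colonization delay 2–32 d,
21 graded host-stage preference vectors (piecewise-linear on the simplex
from a juvenile anchor {0.50, 0.35, 0.10, 0.05, 0} through uniform to
the mirrored adult anchor), and uniform temperature offsets of ±3 °C.
Expected shapes (asserted on the computed grids): reduction rises and
saturates with lifespan, steepest below 10 d; falls with delay, reaching
roughly zero past a month; is concave in preference with the interior
maximum near uniform attack; falls with warming.

The *decreasing-r* variant damps the host projection matrix by
`λ_A^(−a·t)` (a = 0.0247/d, t = days since colonization, λ_A ≈ 1.353 the
host matrix's dominant eigenvalue), emulating the seasonal decline of
plant quality; carrying capacity and parasitism remain active inside the
increment. The *exclusion* experiment reruns the ensemble with `J_i = 0`
under identical seeds and reports the change in mean peak reduction.

## What passing tests do and do not show

The suite pins every matrix entry and scalar formula against
independently coded scalar oracles, checks the structural invariants
(attack conservation, column-mass conservation under thermal scaling,
escape-probability bounds and monotonicity, non-negativity, paired-seed
reproducibility), verifies the vectorized ensemble engine against the
single-trajectory path to 1e-10, and asserts the qualitative season
shape (unimodal outbreak peaking in late July, baseline saturation at
`K`, same-order suppression, measure lag, the four sweep shapes).

Quantitative ensemble statistics depend on the escape-function reading
and on the weather series, neither of which is fully pinned down by the
printed parameterization; with the synthetic climatology the mean peak
reduction lands in the low-to-mid 70s–80s percent range across seeds.
One documented discrepancy is asserted honestly and left failing: the
exclusion of post-parasitism reproduction changes mean peak reduction by
several percentage points here, not a fraction of one — in these
dynamics a large share of the host population is parasitized near the
peak, so parasitized-host reproduction is a material growth term. The
test records the expectation of a sub-percent effect and fails against
it rather than widening the band.

## Known limitations

No immigration, emigration, or mid-summer migration; no alate/morph
structure; no hyperparasitism or predator guild; no plant-growth model
(the carrying capacity is constant except in the decreasing-r variant);
no demographic stochasticity (all randomness enters through initial
densities and weather); sub-daily thermal variation is ignored.
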