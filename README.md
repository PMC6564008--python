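# hpmatrix

A coupled, stage-classified matrix population model for host–parasitoid
dynamics, parameterized for soybean aphid (*Aphis glycines*) and the
parasitoid wasp *Aphelinus certus*. The package is aimed at population
ecologists and biological-control researchers who want to ask: *at what
parasitism pressure does a natural enemy hold a pest outbreak below
economically damaging densities?*

## The model

The host is projected daily through five stages (four nymphal stadia plus
the apterous adult) and the parasitoid through three (egg+larva inside a
living host, mummy, adult):

```
n(t+1) = n(t) + ((K − N)/K) · (H ∘ A ∘ C_SBA − I) n(t)
p(t+1) = [p1,0,0] + φ(V − I)[p1,0,0] + φ[V13·p3, 0, 0] + V[0, p2, p3],   V = W ∘ C_Ac
```

* **A** is the host transition/fertility matrix (survival `P_i` on the
  diagonal, transitions `G_i` on the subdiagonal, adult fecundity `F_5`,
  plus a small stage-1 → stage-3 "skip" probability).
* **H** carries the stage-specific probabilities of escaping parasitism,
  derived from a type II functional response in the Nicholson–Bailey
  tradition: `g_i = exp(−a_i α p₃♀ / (1 + a_i α T_h N)) · (Σn / N)`,
  where `α` is the search rate, `T_h` the handling time, `a_i` the share
  of attacks on stage *i*, and `Σn/N` the fraction of living hosts still
  unparasitized. Hosts that fail to escape become parasitoid eggs
  (`F_3 · p3 = Σ(1 − g_i) n_i`, one egg per attacked host).
* `φ = (K − N)/K` is a logistic brake on the *total* living host
  population `N = Σn + p1` (carrying capacity `K` = 6000 aphids/plant);
  it also throttles the host-resident parasitoid stage, which competes
  for the same resource. Above `K` the brake reverses growth but never
  amplifies decline (see `docs/methods.md`).
* **C** matrices rescale every entry by the temperature of the day via
  growth-rate ratios `λ(T)/λ(25 °C)` from a modified Logan curve (host)
  and Brière curves (parasitoid), with a compensating diagonal factor
  `cP_i = (1 − (1 − P_i)c)/P_i` that conserves column mass.
* Adult parasitoid survival is host-density dependent (a Verhulst
  lifespan curve saturating at 0.932/day), and parasitized hosts keep
  reproducing briefly (`J_i` fecundities).

All parameters ship as a packaged YAML (`hpmatrix/data/default_params.yaml`)
and every operator is exposed as a plain function (`build_host_matrix`,
`escape_probabilities`, `host_step`, …).

## Worked example

The dominant eigenvalue of the host matrix gives the aphid's intrinsic
capacity for increase at 25 °C:

```bash
$ hpmatrix eigen
{"lambda": 1.3530289526041412, "r": 0.302345747780203}
```

— the outbreak grows ~35 % per day when rare. A Monte-Carlo field season
(hosts colonize June 22, parasitoid mummies arrive 20 d later, initial
densities drawn from field-observed ranges, paired with/without-parasitoid
runs sharing weather and host inoculum):

```bash
$ hpmatrix simulate --reps 1000 --seed 1 --out results/demo
{
  "n_reps": 1000,
  "mean_peak_reduction_pct": 72.81878078554571,
  "frac_below_ET": 0.047,
  "frac_below_EIL": 0.264,
  "mean_rate_at_peak": 0.25085015922704784,
  "mean_peak_day": 33.24,
  "median_peak_without": 5999.999912387236,
  ...
}
```

Reading: without the parasitoid every outbreak saturates at the carrying
capacity (~6000 aphids/plant); with it, peak densities fall by ~73 % on
average, 26 % of seasons never exceed the economic injury level
(674 aphids/plant), and at the outbreak's apex about a quarter of the
host population is being parasitized per day. A sensitivity sweep, e.g.
over a uniform shift of the daily temperature series:

```bash
$ hpmatrix sweep --param temperature --seed 1
 offset_degC  peak_reduction_pct
        -3.0           94.028755
         0.0           81.127496
         3.0           50.374687
```

— cooler seasons favor the parasitoid. Other sweeps: `--param lifespan`,
`colonization`, `preference`. `--variant decreasing-r` (on `simulate`)
damps the host matrix by `λ_A^(−a·t)` (a = 0.0247/d) to emulate declining
plant quality. Real weather can be supplied from a GHCN-Daily CSV with
`--temps ghcn:<path>`; otherwise a seeded synthetic upper-Midwest
climatology is generated.

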