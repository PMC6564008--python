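# Default parameterization of the coupled soybean aphid / Aphelinus certus
# matrix model.  All rates are daily and referenced to 25 degC.
host:
  P: [0.500, 0.143, 0.311, 0.205, 0.86]     # stage survival P1..P5
  G: [0.484, 0.857, 0.689, 0.795]           # stage transition G1..G4
  G_skip13: 0.016                           # 1st stadium sampled as 3rd a day later
  F5: 2.56                                  # adult fecundity (offspring/adult/d)
  J: [0.0, 0.0, 0.563, 1.521, 1.471]        # post-parasitism fecundity by stage
  K: 6000.0                                 # carrying capacity (aphids/plant)
  ET: 250.0                                 # economic threshold (aphids/plant)
  EIL: 674.0                                # economic injury level (aphids/plant)
  thermal:
    rho: 0.14                               # 1/degC
    T_max: 34.9                             # degC
    delta: 7.1                              # degC
parasitoid:
  P: [0.832, 0.869]                         # egg+larva, mummy survival
  G: [0.168, 0.131]                         # egg+larva -> mummy, mummy -> adult
  S_adult_max: 0.932                        # max daily adult survival
  theta1: 18.6                              # max mean adult lifespan (d)
  theta2: 13.5                              # Verhulst shape
  theta3: -0.562                            # Verhulst growth rate (per aphid/plant)
  prop_male: 0.412                          # brood sex ratio (proportion male)
  attack_fractions: [0.2, 0.2, 0.2, 0.2, 0.2]
  alpha: 0.979                              # instantaneous search rate (plant/wasp/d)
  handling_time: 0.045                      # d
  thermal_egg_to_mummy:
    a: 1.19e-4
    T0: 7.8
    T_max: 35.7
  thermal_mummy_to_adult:
    a: 1.37e-4
    T0: 11.6
    T_max: 36.9
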