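# Example run configuration for `reox extract` / `reox analyze`.
constants:
  huefner: 1.35        # mL O2 per g Hb
  o2_solubility: 0.003 # mL O2 per dL per mmHg
  jo2_wall: 0.0        # trans-wall oxygen flux; 0 disables the correction.
                       # A documented illustrative non-zero value is
                       # reox.EXAMPLE_WALL_FLUX = -7e-6.
po2_cra_source: from_saturation  # from_systemic | constant
po2_cra_constant: 95.0
icc_model: two_way_mixed_absolute  # one_way_random
baseline_policy: mean_of_two       # first | second
seed: 0
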