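# Parameter presets.
#
# model/table1: the calibrated dynamical parameters (alpha, beta, gamma,
# mu_i, N) plus desk baselines r = 0.75 (= gamma) and mu = 0.04 for
# closed-form work; in the mapping pipeline r and mu are climate-driven
# and these two are ignored.
#
# life_history/parham2010: the working mortality-polynomial coefficient
# a = -0.03 (standard Martens/Parham value), used as the default for
# mapping.
#
# life_history/table1_as_printed: identical except a = -0.3.  With that
# value the lifespan quadratic a*T^2 + b*T + c is negative at every
# temperature (discriminant 1.31^2 - 4*0.3*4.4 < 0), so the mortality
# rate is invalid everywhere and every map pixel is nodata.  Kept for
# faithfulness; not usable for mapping.
model:
  table1:
    r: 0.75
    beta: 1.0
    gamma: 0.75
    alpha: 0.01
    mu: 0.04
    mu_i: 0.01
    N: 50.0
life_history:
  parham2010:
    B_E: 200.0
    theta_E: 0.9
    theta_L: 0.25
    theta_P: 0.75
    R_L: 50.0
    k1: 0.00554
    k2: -0.06737
    a: -0.03
    b: 1.31
    c: -4.4
  table1_as_printed:
    B_E: 200.0
    theta_E: 0.9
    theta_L: 0.25
    theta_P: 0.75
    R_L: 50.0
    k1: 0.00554
    k2: -0.06737
    a: -0.3
    b: 1.31
    c: -4.4
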