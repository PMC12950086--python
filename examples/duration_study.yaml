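# Two-arm competing-risks trial, 12 candidate monthly inspections.
# Decreasing baseline hazards for both risks (Weibull shapes 1/3), 30% of
# control subjects failing from each risk by the end of the horizon, equal
# long-run split between the risks (kappa = 0.5), strongly protective
# treatment on both risks.
model:
  link: multinomial
  J: 2
  q_max: 12
weibull:
  w1: 0.3
  w2: 0.3
  tau1: 0.3333333333333333
  tau2: 0.3333333333333333
  kappa: 0.5
effects: [[-2.5], [-2.5]]
cost:
  variant: until_event
  f: 1.0
  rho: 0.0
criterion:
  role: Ds
search:
  allocation: equal
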