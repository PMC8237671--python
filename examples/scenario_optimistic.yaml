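# Voluntary uptake alone surpasses the target (and here even the enforced
# curve would): intercepts differ by 5 pp, endpoints by 15 pp between regimes.
seed: 1
curves:
  voluntary: {family: gaussian_threshold, p0: 0.20, p1: 1.00, mu: 0.35, sigma: 0.12}
  enforced:  {family: gaussian_threshold, p0: 0.15, p1: 0.85, mu: 0.45, sigma: 0.25}
plan:
  regime: voluntary
  target: 0.75
  capacity: 1.0
  horizon: 10000
f0: 0.0
tol: 1.0e-9
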