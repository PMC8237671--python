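# Voluntary uptake stalls below the target; enforcement must carry coverage
# past the enforced curve's tipping point.
seed: 1
curves:
  voluntary: {family: gaussian_threshold, p0: 0.10, p1: 1.00, mu: 0.45, sigma: 0.075}
  enforced:  {family: gaussian_threshold, p0: 0.05, p1: 0.95, mu: 0.50, sigma: 0.08}
plan:
  regime: enforced
  target: 0.8
  capacity: 0.05
  horizon: 10000
f0: 0.0
tol: 1.0e-9
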