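# Cumulative Likert targets (share at level >= k) for the enforced item,
# per wave: 44/56/71/77 % in wave 1 and 28/42/58/70 % in wave 2.
enforced:
  1: {4: 0.44, 3: 0.56, 2: 0.71, 1: 0.77}
  2: {4: 0.28, 3: 0.42, 2: 0.58, 1: 0.70}
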