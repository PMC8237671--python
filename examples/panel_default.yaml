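# Default synthetic panel: two waves, n matching the survey panel size.
panel:
  n_respondents: 2653
  seed: 20
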