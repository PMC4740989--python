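# Packaged demo panel: seven sequenced male strains, two male-contaminated
# female libraries (treated as males once Sry reads are detected; their
# variant tables carry diluted alternate counts), five pure females, and
# the ten-gene duplication panel with its mechanism mix.
simulation:
  n_male_samples: 7
  n_female_samples: 5
  n_contaminated_females: 2
  coverage: 40
  contaminated_variant_fraction: 0.5
  seed: 20160203
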