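# Replicate detection patterns calibrated to the published light/dark
# comparison. Protein groups: 8661 identified, 4297 retained by the
# all-three-replicates-in-one-state filter, of which 384 single-state
# (232 light-only, 152 dark-only). Transcript classes: 66,542 detected,
# 41,045 retained under the same criterion. The split of the remaining
# retained features between fully-detected and one-full-state patterns,
# and of rejected features among incomplete patterns, is unpublished and
# fixed here once.
protein:
  n_features: 8661
  patterns:
    full_full: 3000
    full_light_partial_dark: 500
    full_dark_partial_light: 413
    light_only: 232
    dark_only: 152
    partial_partial: 2364
    sparse: 2000
transcript:
  n_features: 66542
  patterns:
    full_full: 38000
    full_light_partial_dark: 1245
    full_dark_partial_light: 800
    light_only: 600
    dark_only: 400
    partial_partial: 15000
    sparse: 10497
n_plastid_encoded: 60
effects:
  effect_sd: 0.5
  noise_sd: 0.05
  shared: plastid
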