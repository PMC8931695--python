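# Reliable-region mode: the constituent indicators of the fitted
# coactivation networks (response inhibition: one factor; error
# processing: two correlated factors). Region columns are prefixed by
# contrast (ri_ / ep_) because the same parcel can appear in both.
response_inhibition:
  - ri_lh_inferior_parietal
  - ri_lh_supramarginal
  - ri_lh_lateral_occipital
  - ri_lh_pars_orbitalis
error_processing:
  - ep_rh_lateral_orbitofrontal
  - ep_lh_lateral_orbitofrontal
  - ep_lh_pars_orbitalis
  - ep_rh_superior_parietal
  - ep_lh_superior_parietal
  - ep_lh_lateral_occipital
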