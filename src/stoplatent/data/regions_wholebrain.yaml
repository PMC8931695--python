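# Whole-brain mode: the 34 bilateral cortical parcels of the Desikan
# atlas. Each parcel yields a left- and right-hemisphere indicator per
# task contrast (prefix ri_/ep_ plus lh_/rh_ when expanded).
parcels:
  - bankssts
  - caudal_anterior_cingulate
  - caudal_middle_frontal
  - cuneus
  - entorhinal
  - frontal_pole
  - fusiform
  - inferior_parietal
  - inferior_temporal
  - insula
  - isthmus_cingulate
  - lateral_occipital
  - lateral_orbitofrontal
  - lingual
  - medial_orbitofrontal
  - middle_temporal
  - paracentral
  - parahippocampal
  - pars_opercularis
  - pars_orbitalis
  - pars_triangularis
  - pericalcarine
  - postcentral
  - posterior_cingulate
  - precentral
  - precuneus
  - rostral_anterior_cingulate
  - rostral_middle_frontal
  - superior_frontal
  - superior_parietal
  - superior_temporal
  - supramarginal
  - temporal_pole
  - transverse_temporal
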