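- name: RRIL
  notation: RRIL
  category: protease_recognition
  source: S1P (exact site)
  orientations:
  - forward
- name: S1P-degenerate
  notation: Rx[LIT][KL]
  category: protease_recognition
  source: S1P (mammalian substrate consensus)
  orientations:
  - forward
- name: Rho1-NTL7
  notation: LxLSIxGA
  category: protease_recognition
  source: Drosophila Rho-1 site as found in NTL7
  orientations:
  - forward
  cleavage_offsets:
  - 3
  - 7
- name: Rho1-relaxed
  notation: '[LF]xLSIxGA'
  category: protease_recognition
  source: Rho-1 site, relaxed first position
  orientations:
  - forward
  cleavage_offsets:
  - 3
  - 7
- name: rhomboid-AarA-type
  notation: '[ILMF]xx[GAS][AHS][IMLF]'
  category: protease_recognition
  source: bacterial/fly rhomboid substrates (TatA, LacYTM2, Gurken/Spitz, PINK1)
  orientations:
  - forward
- name: rhomboid-compact
  notation: '[ILMF]x[GAS][AHS][IMLF]'
  category: protease_recognition
  source: bacterial/fly rhomboid substrates, compact spacing
  orientations:
  - forward
- name: pan-rhomboid
  notation: '[^WP][IMYFWLV][^WPD][^WF][AGCS][^P][FIMVACLTW]'
  category: protease_recognition
  source: minimal consensus of animal+bacterial rhomboids
  orientations:
  - forward
- name: NP
  notation: NP
  category: helix_destabilizing
  source: S1P-dependent RIP substrates
  orientations:
  - forward
  - reverse
- name: NxxP
  notation: NxxP
  category: helix_destabilizing
  source: S1P-dependent RIP substrates
  orientations:
  - forward
  - reverse
- name: PxxP
  notation: PxxP
  category: helix_destabilizing
  source: S1P-dependent RIP substrates
  orientations:
  - forward
  - reverse
- name: GxxN
  notation: GxxN
  category: helix_destabilizing
  source: S1P-dependent RIP substrates
  orientations:
  - forward
  - reverse
- name: PxxN
  notation: PxxN
  category: helix_destabilizing
  source: helix-breaker variant
  orientations:
  - forward
  - reverse
- name: PN
  notation: PN
  category: helix_destabilizing
  source: helix-breaker variant
  orientations:
  - forward
  - reverse
- name: GA
  notation: GA
  category: helix_destabilizing
  source: animal/bacterial rhomboid cleavage
  orientations:
  - forward
  - reverse
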