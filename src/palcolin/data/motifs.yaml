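# Default active-site motif definitions.
# Pattern notation: plain letter = itself, X = any residue,
# [..] = alternative set.  Optional min_region/max_region restrict the
# scanned window (0-based, end-exclusive).
motifs:
- motif_id: acp_beta_gxds
  pattern: GXDS
- motif_id: ppant_attachment
  pattern: "[DE]XGXDS[LI]"
- motif_id: condensation_core
  pattern: HHXXDDG
- motif_id: kr_type_b_ldd
  pattern: LDD
- motif_id: abc_nbd
  pattern: GGNGSGKST
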