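# Palmerolide family analogue definitions (A-H).
#
# Each entry lists the feature assertions a candidate product must satisfy
# (positions use the macrolide backbone numbering: C1 = ester carbonyl) and
# the variant mechanism classes that may be invoked to produce it.  The
# known family comprises eight members; the definitions for C and G are
# simplified to the features explained by the modeled mechanisms (the C-9
# alcohol / Delta-6 olefin of palmerolide C have no modeled mechanism and
# are not asserted).
analogues:
- name: palmerolide A
  assertions:
    backbone_carbons: 24
    starter: 3-methylcrotonic acid
    terminal_olefin: false
    amide: true
    tail_extension: false
    ring: [1, 19]
    hydroxyls: {7: D, 10: null}
    olefins: {2: trans, 8: trans, 14: trans, 21: trans}
    branches: {17: internal}
    decorations: {11: [carbamate]}
  allowed_mechanisms: []
- name: palmerolide B
  assertions:
    backbone_carbons: 24
    terminal_olefin: false
    amide: true
    tail_extension: false
    hydroxyls: {8: null}
    decorations: {7: [carbamate], 11: [sulfate]}
  allowed_mechanisms: [trans_sites]
  note: carbamate on C-7, sulfate on C-11, alpha-hydroxyl moved to C-8
- name: palmerolide C
  assertions:
    backbone_carbons: 24
    terminal_olefin: false
    amide: true
    tail_extension: false
    hydroxyls: {7: D, 8: null}
    decorations: {11: [carbamate]}
  allowed_mechanisms: [trans_sites]
  note: alpha-hydroxylation at C-8 with the carbamate retained on C-11
- name: palmerolide D
  assertions:
    backbone_carbons: 26
    terminal_olefin: false
    tail_extension: true
    hydroxyls: {7: D, 10: null}
    olefins: {21: trans}
    decorations: {11: [carbamate]}
  allowed_mechanisms: []
  note: palmerolide A scaffold with an isopropyl-extended carboxylate tail
- name: palmerolide E
  assertions:
    backbone_carbons: 22
    starter: null
    glycine: false
    amide: false
    ring: [1, 19]
    hydroxyls: {10: null}
    branches: {17: internal}
    decorations: {11: [carbamate]}
  allowed_mechanisms: [post_assembly_hydrolysis]
  speculative: true
  note: requires post-assembly hydrolysis of the un-acylated glycine amide
- name: palmerolide F
  assertions:
    backbone_carbons: 24
    terminal_olefin: true
    amide: true
    tail_extension: false
    hydroxyls: {10: null}
    decorations: {11: [carbamate]}
  allowed_mechanisms: [starter_swap]
  note: terminal olefin from the isomeric 3-methyl-3-butenoate starter
- name: palmerolide G
  assertions:
    backbone_carbons: 24
    terminal_olefin: false
    amide: true
    tail_extension: false
    olefins: {21: cis}
    decorations: {11: [carbamate]}
  allowed_mechanisms: [geometry_override]
  note: cis diene geometry; biosynthetic mechanism unresolved
- name: palmerolide H
  assertions:
    backbone_carbons: 26
    terminal_olefin: true
    tail_extension: true
    hydroxyls: {8: null}
    decorations: {7: [carbamate], 11: [sulfate]}
  allowed_mechanisms: [starter_swap, trans_sites]
  note: combines the extended tail, terminal olefin and B-type decoration
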