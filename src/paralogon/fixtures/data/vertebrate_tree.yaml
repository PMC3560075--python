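# Canonical species tree used by the simulator and the relative-dating
# windows. Internal node names mark the divergences that bound the 2R and
# 3R dating windows; WGD markers sit on the branch above the named node.
newick: "(amphioxus:1.0,((human:1.4,chicken:1.4)tetrapod_crown:0.6,(gar:1.2,(zebrafish:0.9,(medaka:0.6,stickleback:0.6)acanthomorph_crown:0.3)teleost_crown:0.3)gar_teleost_split:0.8)sarcopterygian_actinopterygian_split:0.5)chordate_vertebrate_split;"
wgd:
  - label: 2R-a
    above: sarcopterygian_actinopterygian_split
    position: 0.33
  - label: 2R-b
    above: sarcopterygian_actinopterygian_split
    position: 0.66
  - label: 3R
    above: teleost_crown
    position: 0.5
windows:
  - label: 2R_window
    older_bound: chordate_vertebrate_split
    younger_bound: sarcopterygian_actinopterygian_split
  - label: 3R_window
    older_bound: gar_teleost_split
    younger_bound: teleost_crown
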