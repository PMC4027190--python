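# Nearest-neighbor stacking free energies for RNA:RNA duplexes, kcal/mol at 37 C.
# Key "XY/ZW": top strand dinucleotide 5'X Y3' (miRNA side), bottom strand
# written 3'Z W5' left-to-right so that X pairs Z and Y pairs W.
# Watson-Crick/Watson-Crick steps follow the standard unified parameter set;
# G:U wobble steps use representative published values, floored at -0.1 so
# that appending any stack never destabilizes a duplex (simplified model).
# Entries are closed under 180-degree rotation at load time:
# value("XY/ZW") == value("WZ/YX").
duplex_init: 4.09
bulge_penalty: 3.8
internal_loop_penalty: 2.8
stacks:
  # Watson-Crick / Watson-Crick
  "AA/UU": -0.93
  "AU/UA": -1.10
  "UA/AU": -1.33
  "CU/GA": -2.08
  "CA/GU": -2.11
  "GU/CA": -2.24
  "GA/CU": -2.35
  "CG/GC": -2.36
  "GG/CC": -3.26
  "GC/CG": -3.42
  # Watson-Crick / wobble
  "AG/UU": -0.55
  "AU/UG": -1.36
  "CG/GU": -1.41
  "CU/GG": -2.11
  "GG/CU": -1.53
  "GU/CG": -2.51
  "UG/AU": -1.00
  "UU/AG": -1.27
  # wobble / wobble
  "GG/UU": -0.50
  "GU/UG": -0.10
  "UG/GU": -0.57
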