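# Hydrogen-bond donor/acceptor perception rules used for the rule-of-five
# profile, and pharmacophore feature perception rules.  All patterns are
# SMARTS; shipping them as data lets a chemist adjust perception without
# touching code.
#
# Donor count = number of N/O atoms bearing at least one hydrogen, weighted
# by the hydrogen count (i.e. O-H and N-H bonds are counted, the classical
# reading of "H-bond donors").  Acceptor count = number of N and O atoms
# (the classical rule-of-five N+O count).
ro5:
  donor_atoms: "[#7,#8;!H0]"
  acceptor_atoms: "[#7,#8]"

# Pharmacophore feature anchors.  Each entry maps a feature kind to a list
# of SMARTS; the first atom of every match is the anchor heavy atom.
# Aromatic features are perceived from ring info (centroid anchor), not
# from SMARTS, and are therefore absent here.
features:
  negative:
    - "[O-]"
    - "[S-]"
    - "[$([OX1]C(=O)[O-])]"
  positive:
    - "[NX4+]"
    - "[NX3+;!$([NX3+][O-])]"
  acceptor:
    - "[$([OX1]=[CX3])]"          # carbonyl oxygen
    - "[$([OX2](C)C);!$([OX2]c)]" # dialkyl ether oxygen
    - "[$([nX2])]"                # pyridine-type aromatic nitrogen
    - "[$([NX2]=C)]"              # imine nitrogen
  donor:
    - "[$([#7;!H0])]"
    - "[$([OX2;!H0])]"
  hydrophobic:
    - "[CX4;!$([CX4][#7,#8,#16,#15]);$([CX4](-[#6])-[#6])]"
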