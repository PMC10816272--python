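# Scaffold SMILES pools for the synthetic library generator.  Stored as
# data so chemists can extend the pools without code changes.
#
# matcher scaffolds share the benzyloxy-phenyl capped benzohydroxamate core
# (ortho-substituted: methoxy / ethoxy / chloro / ... mirroring the hit
# chemotypes); alert variants carry a nitro group on the capping ring.
decoys:
  - "NC(=O)c1ccccc1"
  - "CC(=O)Nc1ccccc1"
  - "ONC(=O)C1CCCCC1"
  - "ONC(=O)c1ccccn1"
  - "c1ccc2ccccc2c1"
  - "OC(=O)c1ccccc1"
  - "CS(=O)(=O)Nc1ccccc1"
  - "Oc1ccccc1"
  - "CCOC(=O)c1ccccc1"
  - "CN(C)c1ccccc1"

neutral_benzohydroxamates:
  - "ONC(=O)c1ccccc1"
  - "ONC(=O)c1ccccc1OC"
  - "ONC(=O)c1ccccc1Cl"
  - "ONC(=O)c1ccc(C)cc1"
  - "ONC(=O)c1cccc(F)c1"
  - "ONC(=O)c1ccc(OC)cc1"

anionic_plain:
  - "[O-]NC(=O)c1ccccc1"
  - "[O-]NC(=O)c1ccccc1OC"
  - "[O-]NC(=O)c1ccccc1OCC"
  - "[O-]NC(=O)c1ccccc1Cl"
  - "[O-]NC(=O)c1ccc(C)cc1"
  - "[O-]NC(=O)c1cccc(OC)c1"
  - "[O-]NC(=O)c1ccc(CC)cc1"
  - "[O-]NC(=O)c1ccc(F)cc1F"

ro5_violators:
  - "[O-]NC(=O)c1ccc(OCCCCCCCCCCCCCCCCCC)cc1"
  - "[O-]NC(=O)c1ccc(CCCCCCCCCCCCCCCCCC)cc1"
  - "[O-]NC(=O)c1ccc(C(c2ccccc2)(c2ccccc2)c2ccccc2)cc1"

matcher_core: "[O-]NC(=O)c1cc(COc2ccccc2)ccc1"

matchers:
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1OC"
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1OCC"
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1Cl"
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1C"
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1F"
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1OC(C)C"
  - "[O-]NC(=O)c1cc(COc2ccccc2)ccc1"

alert_matchers:
  - "[O-]NC(=O)c1cc(COc2ccc([N+](=O)[O-])cc2)ccc1OC"
  - "[O-]NC(=O)c1cc(COc2ccc([N+](=O)[O-])cc2)ccc1Cl"
  - "[O-]NC(=O)c1cc(COc2ccc([N+](=O)[O-])cc2)ccc1"
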