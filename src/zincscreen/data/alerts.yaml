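# Default structural-alert set for the rapid-elimination ("swill") filter.
# Reactive, toxic or assay-interfering moieties; each pattern is a SMARTS.
# Extend or replace via AlertSet.from_pairs / a user YAML of the same shape.
alerts:
  nitro: "[N+](=O)[O-]"
  aldehyde: "[CX3H1](=O)[#6]"
  acyl_halide: "C(=O)[F,Cl,Br,I]"
  alkyl_halide_activated: "[CH2][Br,I]"
  michael_acceptor: "C=CC(=O)[!N]"
  epoxide: "C1OC1"
  aziridine: "C1NC1"
  isocyanate: "N=C=O"
  thiol: "[SX2H]"
  azo: "[#6]N=N[#6]"
  diazonium: "[N+]#N"
  peroxide: "[OX2][OX2]"
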