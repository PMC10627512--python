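# Rigid-body scheme for the HipBST heterohexamer (asymmetric half: chains
# A = HipB, B = HipS, C = HipT; C2 mates E, D, F).  Three bodies for HipB,
# one for HipS, three for HipT, with six inter-domain distance restraints
# anchored at CA atoms; targets are measured in the reference structure.
symmetry: C2
bodies:
  - {label: hipB_n,    chain: A, first: 1,   last: 31}
  - {label: hipB_mid,  chain: A, first: 32,  last: 43}
  - {label: hipB_core, chain: A, first: 44,  last: 107}
  - {label: hipS,      chain: B}
  - {label: hipT_n,    chain: C, first: 2,   last: 59}
  - {label: hipT_mid,  chain: C, first: 60,  last: 169}
  - {label: hipT_c,    chain: C, first: 170, last: 331}
restraints:
  # chain continuity at the body boundaries
  - {chain_a: A, res_a: 31,  chain_b: A, res_b: 32,  weight: 1.0}
  - {chain_a: A, res_a: 43,  chain_b: A, res_b: 44,  weight: 1.0}
  - {chain_a: C, res_a: 59,  chain_b: C, res_b: 60,  weight: 1.0}
  - {chain_a: C, res_a: 169, chain_b: C, res_b: 170, weight: 1.0}
  # additional restraints between the domains
  - {chain_a: A, res_a: 107, name_a: GLU, chain_b: D, res_b: 101, name_b: VAL, weight: 1.0}
  - {chain_a: B, res_a: 55,  name_a: PRO, chain_b: C, res_b: 154, name_b: GLY, weight: 1.0}
  - {chain_a: B, res_a: 65,  name_a: TRP, chain_b: C, res_b: 60,  name_b: GLY, weight: 1.0}
  - {chain_a: D, res_a: 100, name_a: GLY, chain_b: F, res_b: 188, name_b: ASP, weight: 1.0}
  - {chain_a: D, res_a: 6,   name_a: LEU, chain_b: F, res_b: 291, name_b: ARG, weight: 1.0}
  - {chain_a: C, res_a: 147, name_a: VAL, chain_b: B, res_b: 94,  name_b: GLY, weight: 1.0}
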