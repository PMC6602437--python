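# Van der Waals radii and atom-class assignment for protein heavy atoms.
#
# Radii follow the ProtOr united-atom conventions (Tsai et al., J Mol Biol
# 1999): one radius per element, with trigonal (sp2) carbons distinguished
# from tetrahedral (sp3) carbons.  Values in Angstrom.  Human-editable:
# the atom-type registry is rebuilt from this file at import time.
version: 1
radii:
  N: 1.64
  O: 1.46
  S: 1.77
  C_sp2: 1.76
  C_sp3: 1.88
# Carbons listed here are treated as sp2/trigonal; "*" applies to every
# residue (the backbone carbonyl carbon).  All other carbons are sp3.
sp2_carbons:
  "*": [C]
  ASP: [CG]
  GLU: [CD]
  ASN: [CG]
  GLN: [CD]
  ARG: [CZ]
  HIS: [CG, CD2, CE1]
  PHE: [CG, CD1, CD2, CE1, CE2, CZ]
  TYR: [CG, CD1, CD2, CE1, CE2, CZ]
  TRP: [CG, CD1, CD2, CE2, CE3, CZ2, CZ3, CH2]
# Non-standard residues remapped onto standard ones before typing.
residue_remap:
  MSE: MET
  SEP: SER
  TPO: THR
  PTR: TYR
  HSD: HIS
  HSE: HIS
  HID: HIS
  HIE: HIS
  CSO: CYS
  KCX: LYS
  MLY: LYS
# Atom-name remaps applied together with a residue remap.
atom_remap:
  MSE:
    SE: SD
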