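# Minimal torsion-strain rule set.  Each rule keys a 4-atom path SMARTS
# (atoms a1-a2-a3-a4 bonded in order; the dihedral is about the a2-a3 bond)
# to the allowed windows of the ABSOLUTE dihedral angle in degrees (0-180).
# A matched torsion whose |dihedral| falls outside every window counts as
# strained; unmatched torsions are unscored.
rules:
  - id: sp3_sp3_chain
    smarts: "[CX4;!R][CX4;!R][CX4;!R][CX4;!R]"
    allowed_abs_deg: [[40.0, 80.0], [150.0, 180.0]]
  - id: aryl_carbonyl
    smarts: "c:c-[CX3]=O"
    # conjugated aryl-carbonyl: near-coplanar preferred
    allowed_abs_deg: [[0.0, 40.0], [140.0, 180.0]]
  - id: amide_omega
    smarts: "O=[CX3][NX3][#6]"
    allowed_abs_deg: [[0.0, 30.0], [150.0, 180.0]]
  - id: biaryl
    smarts: "c:c-!@c:c"
    # torsion about the inter-ring single bond; twisted conformers preferred
    allowed_abs_deg: [[20.0, 90.0]]
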