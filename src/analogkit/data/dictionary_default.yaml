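# Default generic modification dictionary specification.
#
# The design space is the cross-product
#   (functional group x spacer) + (ring core x decoration x spacer),
# deduplicated by canonical fragment SMILES.  Each fragment carries exactly
# one attachment dummy ([*]).  The membership below is a reconstructed,
# versioned stand-in for a hand-curated medicinal-chemistry set; edit freely,
# the builder re-derives everything from this file.
version: 1

functional_groups:
  - {name: methyl,            smiles: "[*]C"}
  - {name: ethyl,             smiles: "[*]CC"}
  - {name: isopropyl,         smiles: "[*]C(C)C"}
  - {name: tert-butyl,        smiles: "[*]C(C)(C)C"}
  - {name: hydroxyl,          smiles: "[*]O"}
  - {name: methoxy,           smiles: "[*]OC"}
  - {name: ethoxy,            smiles: "[*]OCC"}
  - {name: amino,             smiles: "[*]N"}
  - {name: methylamino,       smiles: "[*]NC"}
  - {name: dimethylamino,     smiles: "[*]N(C)C"}
  - {name: fluoro,            smiles: "[*]F"}
  - {name: chloro,            smiles: "[*]Cl"}
  - {name: bromo,             smiles: "[*]Br"}
  - {name: trifluoromethyl,   smiles: "[*]C(F)(F)F"}
  - {name: difluoromethyl,    smiles: "[*]C(F)F"}
  - {name: trifluoromethoxy,  smiles: "[*]OC(F)(F)F"}
  - {name: cyano,             smiles: "[*]C#N"}
  - {name: nitro,             smiles: "[*][N+](=O)[O-]"}
  - {name: carboxyl,          smiles: "[*]C(=O)O"}
  - {name: methyl-ester,      smiles: "[*]C(=O)OC"}
  - {name: carboxamide,       smiles: "[*]C(N)=O"}
  - {name: n-methylamide,     smiles: "[*]C(=O)NC"}
  - {name: acetamido,         smiles: "[*]NC(C)=O"}
  - {name: acetyl,            smiles: "[*]C(C)=O"}
  - {name: formyl,            smiles: "[*]C=O"}
  - {name: sulfonamide,       smiles: "[*]S(N)(=O)=O"}
  - {name: methylsulfonyl,    smiles: "[*]S(C)(=O)=O"}
  - {name: methylthio,        smiles: "[*]SC"}
  - {name: vinyl,             smiles: "[*]C=C"}
  - {name: ethynyl,           smiles: "[*]C#C"}

rings:
  cores:
    # carbocyclic, sizes 3-6
    - {name: cyclopropane,  smiles: "C1CC1"}
    - {name: cyclobutane,   smiles: "C1CCC1"}
    - {name: cyclopentane,  smiles: "C1CCCC1"}
    - {name: cyclohexane,   smiles: "C1CCCCC1"}
    - {name: benzene,       smiles: "c1ccccc1"}
    # nitrogen heterocycles
    - {name: aziridine,     smiles: "C1CN1"}
    - {name: azetidine,     smiles: "C1CNC1"}
    - {name: pyrrolidine,   smiles: "C1CCNC1"}
    - {name: piperidine,    smiles: "C1CCNCC1"}
    - {name: piperazine,    smiles: "C1CNCCN1"}
    - {name: pyridine,      smiles: "c1ccncc1"}
    - {name: pyrimidine,    smiles: "c1cncnc1"}
    - {name: pyrrole,       smiles: "c1cc[nH]c1"}
    - {name: imidazole,     smiles: "c1c[nH]cn1"}
    - {name: pyrazole,      smiles: "c1cc[nH]n1"}
    # oxygen heterocycles
    - {name: oxirane,         smiles: "C1CO1"}
    - {name: oxetane,         smiles: "C1COC1"}
    - {name: tetrahydrofuran, smiles: "C1CCOC1"}
    - {name: tetrahydropyran, smiles: "C1CCOCC1"}
    - {name: furan,           smiles: "c1ccoc1"}
    - {name: morpholine,      smiles: "C1COCCN1"}
    - {name: oxazole,         smiles: "c1ocnc1"}
  decorations:
    positions: [none, ortho, meta, para]
    groups:
      - {name: methyl,  smiles: "[*]C"}
      - {name: fluoro,  smiles: "[*]F"}
      - {name: methoxy, smiles: "[*]OC"}

spacers:
  lengths: [0, 1, 2]
  atoms: [C, O, N]
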