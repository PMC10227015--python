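"""Dictionary construction and analog enumeration."""

import pytest
from rdkit import Chem

from analogkit.chem import Molecule, canonical_smiles
from analogkit.errors import AttachmentError, ConfigError, EmptyLibraryError
from analogkit.library import (AttachmentSite, FragmentEntry,
                               build_generic_dictionary,
                               attach_fragment, default_dictionary_spec,
                               enumerate_library, spacer_compositions)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_fragments(spec):
    """Brute-force nested-loop fragment enumeration by string assembly.

    Fragments are assembled as '[*]' + spacer + payload text (all shipped
    payloads are written dummy-first), then canonicalized and deduplicated.
    Completely independent of the builder's RWMol surgery.
    """
    spacers = [""]
    cfg = spec.get("spacers", {})
    spacers = []
    import itertools
    for n in sorted(set(cfg.get("lengths", [0]))):
        for comp in itertools.product(sorted(cfg.get("atoms", ["C"])), repeat=n):
            spacers.append("".join(comp))
    out = set()
    for fg in spec.get("functional_groups", []):
        payload = fg["smiles"].replace("[*]", "", 1)
        for sp in spacers:
            m = Chem.MolFromSmiles("[*]" + sp + payload)
            if m is not None:
                out.add(canonical_smiles(m))
    # ring payload strings, written per (core, position) by hand below
    ring_payloads = spec.get("_oracle_ring_payloads", [])
    for payload in ring_payloads:
        for sp in spacers:
            m = Chem.MolFromSmiles("[*]" + sp + payload)
            if m is not None:
                out.add(canonical_smiles(m))
    return out


def oracle_attach(seed_mol, site_atom, fragment_text):
    """Independent attachment via RDKit molzip (dummy-label pairing)."""
    from rdkit.Chem import RWMol

    rw = RWMol(seed_mol)
    atom = rw.GetAtomWithIdx(site_atom)
    if atom.GetTotalNumHs() < 1:
        return None
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    d = rw.AddAtom(Chem.Atom(0))
    rw.GetAtomWithIdx(d).SetAtomMapNum(7)
    rw.AddBond(site_atom, d, Chem.BondType.SINGLE)
    frag = Chem.MolFromSmiles(fragment_text)
    if frag is None or frag.GetNumHeavyAtoms() == 0:
        return None
    frag = Chem.RWMol(frag)
    for a in frag.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(7)
    try:
        product = Chem.molzip(Chem.CombineMols(rw.GetMol(), frag.GetMol()))
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return canonical_smiles(product)


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def test_empty_spec_gives_empty_dictionary():
    d = build_generic_dictionary({"functional_groups": [],
                                  "rings": {"cores": []},
                                  "spacers": {"lengths": [0], "atoms": ["C"]}})
    assert len(d) == 0


def test_single_cross_product_cell():
    spec = {"functional_groups": [],
            "rings": {"cores": [{"name": "benzene", "smiles": "c1ccccc1"}],
                      "decorations": {"positions": ["none"], "groups": []}},
            "spacers": {"lengths": [0], "atoms": ["C"]}}
    d = build_generic_dictionary(spec)
    assert len(d) == 1
    assert d.entries[0].fragment_text == canonical_smiles(
        Chem.MolFromSmiles("[*]c1ccccc1"))


def test_dictionary_matches_bruteforce_oracle():
    """Builder output equals an independent string-assembly enumeration."""
    spec = {
        "functional_groups": [
            {"name": "methyl", "smiles": "[*]C"},
            {"name": "methoxy", "smiles": "[*]OC"},
            {"name": "cyano", "smiles": "[*]C#N"},
        ],
        "rings": {
            "cores": [{"name": "benzene", "smiles": "c1ccccc1"},
                      {"name": "cyclopropane", "smiles": "C1CC1"}],
            "decorations": {"positions": ["none", "ortho", "meta", "para"],
                            "groups": [{"name": "methyl", "smiles": "[*]C"}]},
        },
        "spacers": {"lengths": [0, 1], "atoms": ["C", "O"]},
        # hand-assembled (core, position) payload strings for the oracle
        "_oracle_ring_payloads": [
            "c1ccccc1", "c1c(C)cccc1", "c1cc(C)ccc1", "c1ccc(C)cc1",
            "C1CC1", "C1C(C)C1",
        ],
    }
    d = build_generic_dictionary(spec)
    assert {e.fragment_text for e in d.entries} == oracle_fragments(spec)


def test_dictionary_deterministic_and_sorted():
    spec = default_dictionary_spec()
    d1 = build_generic_dictionary(spec)
    d2 = build_generic_dictionary(spec)
    texts = [e.fragment_text for e in d1.entries]
    assert texts == sorted(texts)
    assert texts == [e.fragment_text for e in d2.entries]
    assert d1.spec_digest == d2.spec_digest


def test_bad_specs_rejected():
    with pytest.raises(ConfigError):
        build_generic_dictionary(
            {"rings": {"cores": [{"name": "big", "smiles": "C1CCCCCC1"}],
                       "decorations": {"positions": ["none"], "groups": []}},
             "spacers": {"lengths": [0], "atoms": ["C"]}})
    with pytest.raises(ConfigError):
        FragmentEntry("[*]C[*]", "functional_group", "two-dummies")
    with pytest.raises(ConfigError):
        spacer_compositions([0], ["Si"])


# ---------------------------------------------------------------------------
# attachment
# ---------------------------------------------------------------------------

def test_methyl_on_benzene_gives_toluene(benzene):
    frag = FragmentEntry("[*]C", "functional_group", "methyl")
    out = attach_fragment(benzene, AttachmentSite(0, "A"), frag)
    assert out.molecule.canonical_text == Molecule.from_smiles("Cc1ccccc1").canonical_text


def test_hydrogen_fragment_is_identity(benzene):
    frag = FragmentEntry("[*][H]", "functional_group", "hydrogen")
    out = attach_fragment(benzene, AttachmentSite(3, "A"), frag)
    assert out.molecule == benzene


def test_no_free_valence_raises():
    pyridine = Molecule.from_smiles("c1ccncc1", "pyridine")
    n_idx = next(a.GetIdx() for a in pyridine.rdkit.GetAtoms()
                 if a.GetSymbol() == "N")
    frag = FragmentEntry("[*]C", "functional_group", "methyl")
    with pytest.raises(AttachmentError):
        attach_fragment(pyridine, AttachmentSite(n_idx), frag)


def test_replace_terminal_group():
    toluene = Molecule.from_smiles("Cc1ccccc1")
    ipso = next(a.GetIdx() for a in toluene.rdkit.GetAtoms()
                if a.GetIsAromatic() and
                any(n.GetDegree() == 1 for n in a.GetNeighbors()))
    frag = FragmentEntry("[*]O", "functional_group", "hydroxyl")
    out = attach_fragment(toluene, AttachmentSite(ipso, mode="replace_terminal_group"),
                          frag)
    assert out.molecule.canonical_text == Molecule.from_smiles("Oc1ccccc1").canonical_text


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_single_site_single_entry(benzene):
    frag = FragmentEntry("[*]C", "functional_group", "methyl")
    lib = enumerate_library(benzene, [AttachmentSite(0)], [frag])
    assert len(lib) == 1
    assert lib[0].molecule.canonical_text == Molecule.from_smiles("Cc1ccccc1").canonical_text


def test_symmetric_sites_collapse():
    """Two symmetry-equivalent sites on para-xylene give one unique product."""
    xylene = Molecule.from_smiles("Cc1ccc(C)cc1", "para-xylene")
    aromatic_ch = [a.GetIdx() for a in xylene.rdkit.GetAtoms()
                   if a.GetIsAromatic() and a.GetTotalNumHs() == 1]
    sites = [AttachmentSite(aromatic_ch[0], "s1"),
             AttachmentSite(aromatic_ch[-1], "s2")]
    frag = FragmentEntry("[*]C", "functional_group", "methyl")
    lib = enumerate_library(xylene, sites, [frag])
    assert len(lib) == 1


def test_enumeration_matches_molzip_oracle(benzene, small_dictionary):
    """Library contents equal an independent molzip-based enumerator."""
    assert len(small_dictionary) <= 50
    site = AttachmentSite(0, "A")
    lib = enumerate_library(benzene, [site], small_dictionary)
    expected = set()
    for entry in small_dictionary:
        got = oracle_attach(benzene.rdkit, 0, entry.fragment_text)
        if got is not None:
            expected.add(got)
    assert {c.molecule.canonical_text for c in lib} == expected


def test_enumeration_bound_and_idempotent_dedup(benzene, small_dictionary):
    sites = [AttachmentSite(0, "a"), AttachmentSite(2, "b")]
    lib = enumerate_library(benzene, sites, small_dictionary)
    assert len(lib) <= len(sites) * len(small_dictionary)
    twice = enumerate_library(benzene, sites, small_dictionary)
    assert ([c.molecule.canonical_text for c in lib]
            == [c.molecule.canonical_text for c in twice])
    # all products pass the same validity notion as inputs
    for c in lib:
        assert Chem.MolFromSmiles(c.molecule.canonical_text) is not None


def test_all_attachments_failing_raises():
    pyridine = Molecule.from_smiles("c1ccncc1", "pyridine")
    n_idx = next(a.GetIdx() for a in pyridine.rdkit.GetAtoms()
                 if a.GetSymbol() == "N")
    frag = FragmentEntry("[*]C", "functional_group", "methyl")
    with pytest.raises(EmptyLibraryError) as err:
        enumerate_library(pyridine, [AttachmentSite(n_idx, "N")], [frag])
    assert err.value.failure_counts == {"N": 1}
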