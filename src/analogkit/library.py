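"""Generic-dictionary construction and seed-analog enumeration.

The design space is a "generic dictionary" of small chemical modifications:
functional groups, 3-6-membered rings (bare or decorated at ortho/meta/para
positions) and short C/O/N spacers.  Each entry is a fragment SMILES with a
single attachment dummy atom ``[*]``; libraries are enumerated by replacing
the dummy with a single bond to a user-chosen attachment atom on a seed
molecule, exhaustively over (site, entry) pairs, with no diversity pruning.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import yaml
from rdkit import Chem

from .chem import Molecule, canonical_smiles
from .errors import AttachmentError, ChemistryError, ConfigError, EmptyLibraryError

_VALID_SPACER_ATOMS = {"C", "O", "N"}
_DECORATION_POSITIONS = ("none", "ortho", "meta", "para")
# ring-walk distance from the attachment atom for each decoration label
_POSITION_DISTANCE = {"ortho": 1, "meta": 2, "para": 3}


@dataclass(frozen=True)
class AttachmentSite:
    """Where and how a fragment is joined to the seed.

    ``substitute_hydrogen`` replaces one hydrogen on the seed atom by the
    fragment; ``replace_terminal_group`` first removes the lowest-index
    degree-1 heavy neighbor of the seed atom.  Atom indices are 0-based.
    """

    seed_atom_index: int
    site_label: str = ""
    mode: str = "substitute_hydrogen"

    def __post_init__(self):
        if self.mode not in ("substitute_hydrogen", "replace_terminal_group"):
            raise ConfigError(f"unknown attachment mode: {self.mode!r}")


@dataclass(frozen=True)
class FragmentEntry:
    """One modification: fragment SMILES with exactly one dummy atom."""

    fragment_text: str
    category: str  # functional_group | ring | spacer_combo
    name: str = ""
    ring_size: Optional[int] = None
    decoration: Optional[str] = None
    spacer_composition: Tuple[str, ...] = ()

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.fragment_text)
        if mol is None:
            raise ConfigError(f"unparsable fragment {self.name!r}: {self.fragment_text!r}")
        n_dummy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if n_dummy != 1:
            raise ConfigError(
                f"fragment {self.name!r} must carry exactly one attachment dummy, "
                f"found {n_dummy}: {self.fragment_text!r}"
            )
        if self.category == "ring" and self.ring_size not in (3, 4, 5, 6, None):
            raise ConfigError(f"ring size outside 3-6 for fragment {self.name!r}")


@dataclass(frozen=True)
class GenericDictionary:
    """Deduplicated, lexicographically ordered set of fragment entries."""

    entries: Tuple[FragmentEntry, ...]
    spec_digest: str

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class DesignedCompound:
    """Product molecule plus full provenance of how it was designed."""

    molecule: Molecule
    seed_name: str
    site_label: str
    fragment_name: str
    round_index: int = 1


# ---------------------------------------------------------------------------
# dictionary construction
# ---------------------------------------------------------------------------

def _spec_digest(spec: dict) -> str:
    blob = yaml.safe_dump(spec, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def spacer_compositions(lengths: Sequence[int], atoms: Sequence[str]) -> List[Tuple[str, ...]]:
    """All spacer atom sequences, shortest first, lexicographic within length."""
    for a in atoms:
        if a not in _VALID_SPACER_ATOMS:
            raise ConfigError(f"spacer atom {a!r} not in {{C,O,N}}")
    for n in lengths:
        if not 0 <= int(n) <= 3:
            raise ConfigError(f"spacer length {n} outside 0-3")
    out: List[Tuple[str, ...]] = []
    for n in sorted(set(int(x) for x in lengths)):
        out.extend(itertools.product(sorted(atoms), repeat=n))
    return out


def _locate_dummy(mol: Chem.Mol) -> Tuple[int, int]:
    """Return (dummy_idx, anchor_idx) of the single attachment dummy."""
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ConfigError(f"expected exactly one dummy atom, found {len(dummies)}")
    nbrs = mol.GetAtomWithIdx(dummies[0]).GetNeighbors()
    if len(nbrs) != 1:
        raise ConfigError("attachment dummy must have exactly one neighbor")
    return dummies[0], nbrs[0].GetIdx()


def add_spacer(fragment_text: str, composition: Sequence[str]) -> Optional[str]:
    """Insert a C/O/N spacer chain between the dummy and the payload.

    ``composition[0]`` ends up adjacent to the dummy (i.e. bonded to the seed
    after attachment).  Returns canonical fragment SMILES, or None if the
    spliced fragment cannot be sanitized.
    """
    if not composition:
        mol = Chem.MolFromSmiles(fragment_text)
        return canonical_smiles(mol) if mol is not None else None
    payload = Chem.MolFromSmiles(fragment_text)
    if payload is None:
        return None
    dummy_idx, anchor_idx = _locate_dummy(payload)
    rw = Chem.RWMol(payload)
    rw.RemoveAtom(dummy_idx)
    if anchor_idx > dummy_idx:
        anchor_idx -= 1
    prev = anchor_idx
    for sym in reversed(list(composition)):
        new_idx = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(prev, new_idx, Chem.BondType.SINGLE)
        prev = new_idx
    dummy = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(prev, dummy, Chem.BondType.SINGLE)
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return canonical_smiles(mol)


def _ring_order(mol: Chem.Mol) -> List[int]:
    rings = mol.GetRingInfo().AtomRings()
    if len(rings) != 1:
        raise ConfigError("ring cores must be monocyclic")
    return list(rings[0])


def _positions_for_size(size: int) -> Tuple[str, ...]:
    """Decoration labels meaningful for a given ring size."""
    if size <= 3:
        return ("none", "ortho")
    if size <= 5:
        return ("none", "ortho", "meta")
    return ("none", "ortho", "meta", "para")


def decorated_ring_fragment(core_smiles: str, position: str,
                            decoration_smiles: Optional[str]) -> Optional[str]:
    """Build ``[*]``-ring fragment, optionally decorated at a relative position.

    The attachment atom is the first ring atom (in ring order) bearing a
    hydrogen; the decoration sits at ring-walk distance 1/2/3 (ortho/meta/
    para) from it, on the lower-index side of the ring walk.  Returns None
    when the geometry is impossible (position beyond the ring, no free
    valence at the decoration atom).
    """
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        raise ConfigError(f"unparsable ring core: {core_smiles!r}")
    ring = _ring_order(core)
    size = len(ring)
    attach_at = next((i for i in ring if core.GetAtomWithIdx(i).GetTotalNumHs() >= 1), None)
    if attach_at is None:
        return None
    rw = Chem.RWMol(core)
    bond_type = Chem.BondType.SINGLE
    dummy = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(attach_at, dummy, bond_type)
    if position != "none":
        if position not in _positions_for_size(size):
            return None
        dist = _POSITION_DISTANCE[position]
        pos_in_ring = ring.index(attach_at)
        candidate = ring[(pos_in_ring + dist) % size]
        if core.GetAtomWithIdx(candidate).GetTotalNumHs() < 1:
            # try walking the other way round the ring
            candidate = ring[(pos_in_ring - dist) % size]
            if core.GetAtomWithIdx(candidate).GetTotalNumHs() < 1:
                return None
        deco = Chem.MolFromSmiles(decoration_smiles)
        if deco is None:
            raise ConfigError(f"unparsable decoration: {decoration_smiles!r}")
        d_dummy, d_anchor = _locate_dummy(deco)
        offset = rw.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(rw.GetMol(), deco))
        combined.AddBond(candidate, offset + d_anchor, Chem.BondType.SINGLE)
        combined.RemoveAtom(offset + d_dummy)
        rw = combined
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return canonical_smiles(mol)


def default_dictionary_spec() -> dict:
    """The versioned default dictionary spec shipped with the package."""
    text = importlib.resources.files("analogkit.data").joinpath(
        "dictionary_default.yaml").read_text()
    return yaml.safe_load(text)


def build_generic_dictionary(spec: dict) -> GenericDictionary:
    """Build the full cross-product dictionary from a structured spec.

    Cross product: (functional group x spacer) + (ring core x decoration
    position x decoration group x spacer), deduplicated by canonical
    fragment SMILES (first categorisation wins) and ordered
    lexicographically by canonical text.
    """
    spacer_cfg = spec.get("spacers", {"lengths": [0], "atoms": ["C"]})
    spacers = spacer_compositions(spacer_cfg.get("lengths", [0]),
                                  spacer_cfg.get("atoms", ["C"]))
    seen: dict[str, FragmentEntry] = {}

    def _register(text: Optional[str], **kw) -> None:
        if text is None or text in seen:
            return
        seen[text] = FragmentEntry(fragment_text=text, **kw)

    for fg in spec.get("functional_groups", []) or []:
        base = fg["smiles"]
        if Chem.MolFromSmiles(base) is None:
            raise ConfigError(f"unparsable functional group {fg.get('name')!r}")
        for comp in spacers:
            _register(add_spacer(base, comp),
                      category="functional_group", name=fg.get("name", ""),
                      spacer_composition=tuple(comp))

    rings = spec.get("rings") or {}
    cores = rings.get("cores", []) or []
    deco_cfg = rings.get("decorations", {}) or {}
    positions = deco_cfg.get("positions", ["none"])
    for p in positions:
        if p not in _DECORATION_POSITIONS:
            raise ConfigError(f"unknown decoration position {p!r}")
    deco_groups = deco_cfg.get("groups", []) or [None]
    for core in cores:
        core_mol = Chem.MolFromSmiles(core["smiles"])
        if core_mol is None:
            raise ConfigError(f"unparsable ring core {core.get('name')!r}")
        size = len(_ring_order(core_mol))
        if not 3 <= size <= 6:
            raise ConfigError(f"ring size {size} outside 3-6 for core {core.get('name')!r}")
        for position in positions:
            groups = [None] if position == "none" else deco_groups
            for grp in groups:
                grp_smiles = grp["smiles"] if grp else None
                base = decorated_ring_fragment(core["smiles"], position, grp_smiles)
                if base is None:
                    continue
                label = core.get("name", "")
                if position != "none" and grp:
                    label = f"{label}-{position}-{grp.get('name', '')}"
                for comp in spacers:
                    _register(add_spacer(base, comp),
                              category="ring", name=label, ring_size=size,
                              decoration=position, spacer_composition=tuple(comp))

    entries = tuple(seen[k] for k in sorted(seen))
    return GenericDictionary(entries=entries, spec_digest=_spec_digest(spec))


# ---------------------------------------------------------------------------
# attachment and enumeration
# ---------------------------------------------------------------------------

def _is_identity_fragment(frag: Chem.Mol) -> bool:
    """True for fragments like ``[*][H]`` whose payload is empty."""
    return frag.GetNumHeavyAtoms() == 0 or all(
        a.GetAtomicNum() in (0, 1) for a in frag.GetAtoms())


def attach_fragment(seed: Molecule, site: AttachmentSite,
                    fragment: FragmentEntry) -> DesignedCompound:
    """Join a fragment to the seed at the given site via a single bond.

    The fragment's dummy atom is deleted and its anchor atom bonded to the
    seed atom; the product is re-sanitized (aromaticity re-perceived,
    hydrogens implicit).
    """
    seed_mol = seed.rdkit
    n_seed = seed_mol.GetNumAtoms()
    if not 0 <= site.seed_atom_index < n_seed:
        raise AttachmentError(
            f"seed atom index {site.seed_atom_index} outside molecule "
            f"({n_seed} atoms)")
    frag = Chem.MolFromSmiles(fragment.fragment_text)
    if frag is None:
        raise ChemistryError(f"unparsable fragment: {fragment.name or fragment.fragment_text}")

    if _is_identity_fragment(frag):
        return DesignedCompound(molecule=seed, seed_name=seed.name or "seed",
                                site_label=site.site_label,
                                fragment_name=fragment.name or fragment.fragment_text)

    rw = Chem.RWMol(seed_mol)
    target = site.seed_atom_index
    if site.mode == "replace_terminal_group":
        terminal = sorted(
            n.GetIdx() for n in rw.GetAtomWithIdx(target).GetNeighbors()
            if n.GetDegree() == 1)
        if not terminal:
            raise AttachmentError(
                f"no terminal group to replace at atom {target}")
        rw.RemoveAtom(terminal[0])
        if terminal[0] < target:
            target -= 1
    else:
        atom = rw.GetAtomWithIdx(target)
        if atom.GetTotalNumHs() < 1:
            raise AttachmentError(
                f"no free valence (hydrogen) at seed atom {site.seed_atom_index}")
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
        atom.SetNoImplicit(False)

    d_dummy, d_anchor = _locate_dummy(frag)
    offset = rw.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(rw.GetMol(), frag))
    combined.AddBond(target, offset + d_anchor, Chem.BondType.SINGLE)
    combined.RemoveAtom(offset + d_dummy)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise ChemistryError(
            f"sanitization failed attaching {fragment.name or fragment.fragment_text}: {exc}"
        ) from exc
    return DesignedCompound(
        molecule=Molecule.from_rdkit(product),
        seed_name=seed.name or "seed",
        site_label=site.site_label,
        fragment_name=fragment.name or fragment.fragment_text)


def enumerate_library(seed: Molecule, sites: Sequence[AttachmentSite],
                      dictionary: Iterable[FragmentEntry] | GenericDictionary,
                      round_index: int = 1) -> List[DesignedCompound]:
    """Exhaustive (site x entry) enumeration with canonical dedup.

    Every close analog is kept (no diversity pruning); duplicates by
    canonical product SMILES collapse to the first occurrence.  Ordering is
    deterministic: sites in input order, entries in dictionary order.
    """
    if not sites:
        raise ConfigError("at least one attachment site required")
    entries = list(dictionary)
    products: List[DesignedCompound] = []
    seen: set[str] = set()
    failures = {s.site_label or str(s.seed_atom_index): 0 for s in sites}
    for site in sites:
        key = site.site_label or str(site.seed_atom_index)
        for entry in entries:
            try:
                compound = attach_fragment(seed, site, entry)
            except (AttachmentError, ChemistryError):
                failures[key] += 1
                continue
            text = compound.molecule.canonical_text
            if text in seen:
                continue
            seen.add(text)
            products.append(DesignedCompound(
                molecule=compound.molecule, seed_name=compound.seed_name,
                site_label=compound.site_label,
                fragment_name=compound.fragment_name, round_index=round_index))
    if not products:
        raise EmptyLibraryError(
            f"all attachments failed across {len(sites)} site(s)", failures)
    return products
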