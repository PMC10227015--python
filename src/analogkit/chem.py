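"""Core molecule wrapper.

A :class:`Molecule` is a thin, immutable-by-convention wrapper around an
RDKit mol that pins down the single identity notion used everywhere in the
toolkit: the canonical isomeric SMILES of the sanitized graph.  Every stage
(enumeration, dedup, filtering, ledger keys) compares molecules through
:attr:`Molecule.canonical_text` and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

from .errors import ChemistryError

# RDKit is chatty about kekulization failures during exhaustive enumeration;
# invalid candidates are handled explicitly, so silence the C++ logger.
RDLogger.DisableLog("rdApp.*")


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES of an already-sanitized RDKit mol."""
    return Chem.MolToSmiles(mol, canonical=True)


def mol_from_smiles(text: str) -> Chem.Mol:
    """Parse and sanitize SMILES, raising :class:`ChemistryError` on failure."""
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ChemistryError(f"unparsable or valence-invalid SMILES: {text!r}")
    return mol


@dataclass(frozen=True)
class Molecule:
    """Valence-checked molecular graph with a canonical text form.

    Parameters
    ----------
    canonical_text:
        Canonical isomeric SMILES; computed by :meth:`from_smiles` /
        :meth:`from_rdkit`, never supplied free-form.
    name:
        Optional human-readable label carried through pipelines.
    """

    canonical_text: str
    name: Optional[str] = None
    _mol: Chem.Mol = field(repr=False, compare=False, hash=False, default=None)

    @classmethod
    def from_smiles(cls, text: str, name: Optional[str] = None) -> "Molecule":
        mol = mol_from_smiles(text)
        return cls(canonical_text=canonical_smiles(mol), name=name, _mol=mol)

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: Optional[str] = None) -> "Molecule":
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - rdkit raises varied types
            raise ChemistryError(f"sanitization failed: {exc}") from exc
        return cls(canonical_text=canonical_smiles(mol), name=name, _mol=mol)

    @property
    def rdkit(self) -> Chem.Mol:
        """The underlying RDKit mol (re-parsed lazily if absent)."""
        if self._mol is None:
            object.__setattr__(self, "_mol", mol_from_smiles(self.canonical_text))
        return self._mol

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdkit.GetNumHeavyAtoms()

    def with_name(self, name: str) -> "Molecule":
        return Molecule(self.canonical_text, name, self._mol)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.canonical_text == other.canonical_text

    def __hash__(self) -> int:
        return hash(self.canonical_text)
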