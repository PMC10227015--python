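"""Standardization, physicochemical profiling and library filtering.

Enumerated compounds are standardized (neutralized where chemically safe,
canonical tautomer chosen), profiled (MW, Wildman-Crippen logP, H-bond
donors/acceptors, rotatable bonds, TPSA) and screened against property
windows plus a named-SMARTS alert list.  Default windows (MW <= 650,
logP <= 6, rotatable bonds <= 12) are campaign-tunable defaults, not
literature constants.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem import Molecule
from .errors import ConfigError
from .library import DesignedCompound

log = logging.getLogger(__name__)

#: campaign-tunable default property windows: field -> (min, max)
DEFAULT_WINDOWS: Dict[str, Tuple[Optional[float], Optional[float]]] = {
    "molecular_weight": (None, 650.0),
    "logp": (None, 6.0),
    "rotatable_bonds": (None, 12.0),
}

_PROFILE_FIELDS = ("molecular_weight", "logp", "hbd_count", "hba_count",
                   "rotatable_bonds", "tpsa")


@dataclass(frozen=True)
class PhyschemProfile:
    """Computed physicochemical profile of a standardized molecule.

    logP uses the Wildman & Crippen (1999) atomic-contribution scheme as
    implemented in RDKit (pinned by the RDKit version in the environment).
    """

    molecular_weight: float  # g/mol, average atomic masses incl. implicit H
    logp: float
    hbd_count: int
    hba_count: int
    rotatable_bonds: int
    tpsa: float  # Angstrom^2

    def value(self, fieldname: str) -> float:
        if fieldname not in _PROFILE_FIELDS:
            raise ConfigError(f"unknown property {fieldname!r}")
        return float(getattr(self, fieldname))


@dataclass
class Verdict:
    compound_index: int
    canonical_text: str
    retained: bool
    triggered_rules: Tuple[str, ...] = ()


@dataclass
class FilterReport:
    """Accounting of a filter run; retained + first-rule rejections = input."""

    input_count: int
    retained_count: int
    rejections_by_rule: Dict[str, int]
    verdicts: List[Verdict]

    def accounting_holds(self) -> bool:
        rejected = sum(1 for v in self.verdicts if not v.retained)
        return (self.retained_count + rejected == self.input_count
                and len(self.verdicts) == self.input_count)


# ---------------------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()


def standardize(mol: Molecule) -> Molecule:
    """Neutralize safe charges and pick the canonical tautomer.

    Deterministic and idempotent.  Permanent charges (e.g. quaternary
    nitrogen) that cannot be neutralized pass through unchanged with a
    logged note.
    """
    rd = Chem.Mol(mol.rdkit)
    cleaned = rdMolStandardize.Cleanup(rd)
    neutral = _UNCHARGER.uncharge(cleaned)
    if Chem.GetFormalCharge(neutral) != 0:
        log.info("permanent charge retained on %s", mol.canonical_text)
    canonical = _TAUTOMERIZER.Canonicalize(neutral)
    return Molecule.from_rdkit(canonical, name=mol.name)


def physchem_profile(mol: Molecule) -> PhyschemProfile:
    """Profile a (standardized) molecule; bit-stable on the canonical form.

    Descriptors are computed on the canonical re-parsed graph, so the result
    is independent of the input atom ordering down to the last bit.
    """
    from .chem import mol_from_smiles

    rd = mol_from_smiles(mol.canonical_text)
    return PhyschemProfile(
        molecular_weight=Descriptors.MolWt(rd),
        logp=Crippen.MolLogP(rd),
        hbd_count=rdMolDescriptors.CalcNumHBD(rd),
        hba_count=rdMolDescriptors.CalcNumHBA(rd),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(rd),
        tpsa=rdMolDescriptors.CalcTPSA(rd),
    )


def load_alerts(path=None) -> List[Tuple[str, str]]:
    """Load ``id<TAB>SMARTS`` alert lines (default: the shipped list)."""
    if path is None:
        text = importlib.resources.files("analogkit.data").joinpath(
            "alerts_default.smarts").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    alerts = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alert_id, _, smarts = line.partition("\t")
        if not smarts:
            raise ConfigError(f"malformed alert line: {line!r}")
        alerts.append((alert_id.strip(), smarts.strip()))
    return alerts


def substructure_alerts(mol: Molecule,
                        alert_set: Sequence[Tuple[str, str]]) -> List[str]:
    """Ids of alert patterns with at least one substructure match."""
    rd = mol.rdkit
    hits = []
    for alert_id, smarts in alert_set:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ConfigError(f"unparsable alert pattern {alert_id!r}: {smarts!r}")
        if rd.HasSubstructMatch(patt):
            hits.append(alert_id)
    return hits


def _normalize_windows(windows: Mapping[str, Sequence[Optional[float]]]):
    norm = {}
    for key, bounds in (windows or {}).items():
        if key not in _PROFILE_FIELDS:
            raise ConfigError(f"unknown property in windows: {key!r}")
        lo, hi = bounds
        if lo is not None and hi is not None and lo > hi:
            raise ConfigError(f"window min > max for {key!r}: {bounds}")
        norm[key] = (lo, hi)
    return norm


def filter_library(
    lib: Sequence[DesignedCompound],
    windows: Optional[Mapping[str, Sequence[Optional[float]]]] = None,
    alert_set: Optional[Sequence[Tuple[str, str]]] = None,
    profiles: Optional[Sequence[PhyschemProfile]] = None,
) -> Tuple[List[DesignedCompound], FilterReport]:
    """Discard compounds with alert hits or out-of-window properties.

    Rules are evaluated in a fixed order (alerts first, then windows in the
    order given); the report counts each rejection under the first rule
    that fired, and every triggering rule is recorded on the verdict.
    ``profiles`` may supply precomputed physchem profiles (index-aligned).
    """
    windows = _normalize_windows(windows or {})
    alert_set = list(alert_set or [])
    retained: List[DesignedCompound] = []
    verdicts: List[Verdict] = []
    rejections: Dict[str, int] = {}
    for i, compound in enumerate(lib):
        triggered: List[str] = []
        hits = substructure_alerts(compound.molecule, alert_set)
        triggered.extend(f"alert:{h}" for h in hits)
        profile = profiles[i] if profiles is not None else physchem_profile(compound.molecule)
        for key, (lo, hi) in windows.items():
            v = profile.value(key)
            if (lo is not None and v < lo) or (hi is not None and v > hi):
                triggered.append(f"window:{key}")
        ok = not triggered
        verdicts.append(Verdict(i, compound.molecule.canonical_text, ok,
                                tuple(triggered)))
        if ok:
            retained.append(compound)
        else:
            rejections[triggered[0]] = rejections.get(triggered[0], 0) + 1
    report = FilterReport(
        input_count=len(lib), retained_count=len(retained),
        rejections_by_rule=rejections, verdicts=verdicts)
    return retained, report
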