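"""Template-constrained 3D evaluation of designed compounds.

A designed analog is embedded in 3D, mapped onto the reference bioactive
conformation through a maximum common substructure, rigidly superimposed
(closed-form least-squares / Kabsch) and then judged on mapped-atom RMSD,
van der Waals clashes against the receptor pocket and against itself,
torsion-window violations and physchem-window compliance.  The resulting
priority score is a transparent weighted sum of those terms: a deliberate,
fully-inspectable surrogate for proprietary template-docking scorers.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS

from .chem import Molecule
from .errors import (ConfigError, DegenerateAlignmentError, EmbeddingError,
                     NoTemplateOverlapError)


def load_vdw_radii(path=None) -> Dict[str, float]:
    if path is None:
        text = importlib.resources.files("analogkit.data").joinpath(
            "vdw_radii.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return {str(k): float(v) for k, v in yaml.safe_load(text).items()}


def load_torsion_rules(path=None) -> List[dict]:
    if path is None:
        text = importlib.resources.files("analogkit.data").joinpath(
            "torsion_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)["rules"]


@dataclass
class Conformer3D:
    """3D coordinates (Angstrom) for every atom of a molecule (incl. H)."""

    molecule: Molecule
    coordinates: np.ndarray  # (n_atoms, 3)
    elements: Tuple[str, ...]
    seed: int = 0
    rdkit_h: Optional[Chem.Mol] = field(default=None, repr=False)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ConfigError("coordinate count must equal atom count")

    @property
    def heavy_indices(self) -> List[int]:
        return [i for i, e in enumerate(self.elements) if e != "H"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer3D":
        return Conformer3D(self.molecule,
                           self.coordinates @ rotation.T + translation,
                           self.elements, self.seed, self.rdkit_h)


@dataclass(frozen=True)
class AtomMapping:
    """Injective atom correspondence (query index, template index) pairs."""

    pairs: Tuple[Tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def query_indices(self) -> List[int]:
        return [q for q, _ in self.pairs]

    @property
    def template_indices(self) -> List[int]:
        return [t for _, t in self.pairs]


@dataclass
class ReceptorPocket:
    """Heavy-atom coordinates of the binding pocket (real or synthetic)."""

    coordinates: np.ndarray
    elements: Tuple[str, ...]
    source: str = "synthetic"

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.elements) == 0:
            raise ConfigError("pocket must contain at least one atom")
        if self.coordinates.shape != (len(self.elements), 3):
            raise ConfigError("coordinate count must equal atom count")


@dataclass
class PoseEvaluation:
    mapped_atom_rmsd: float
    inter_clash_count: int
    intra_clash_count: int
    strained_torsion_count: int
    physchem_ok: bool = True
    priority_score: float = 0.0


#: default weights of the transparent priority score
DEFAULT_WEIGHTS: Dict[str, float] = {
    "inter_clash": 1.0,
    "intra_clash": 1.0,
    "torsion": 0.5,
    "rmsd": 0.25,
    "physchem": 1.0,
}


# ---------------------------------------------------------------------------
# common substructure mapping
# ---------------------------------------------------------------------------

def _connected_components(mol: Chem.Mol, atoms: Sequence[int]) -> List[List[int]]:
    atom_set = set(atoms)
    seen, comps = set(), []
    for start in atoms:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nb.GetIdx()
                if i in atom_set and i not in seen:
                    seen.add(i)
                    stack.append(i)
        comps.append(sorted(comp))
    return comps


def common_substructure_map(query: Molecule, template: Molecule,
                            min_atoms: int = 5) -> AtomMapping:
    """Maximum common connected substructure mapping, deterministic.

    Element and exact bond-order compatibility; among equivalent maximum
    matches the lexicographically smallest mapped index sequence is chosen.
    """
    q, t = query.rdkit, template.rdkit
    res = rdFMCS.FindMCS(
        [q, t],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        matchValences=False,
        ringMatchesRingOnly=False,
        completeRingsOnly=False,
        timeout=30,
    )
    if res.canceled or res.numAtoms == 0:
        raise NoTemplateOverlapError("no common substructure found")
    patt = Chem.MolFromSmarts(res.smartsString)
    q_matches = sorted(q.GetSubstructMatches(patt, uniquify=False))
    t_matches = sorted(t.GetSubstructMatches(patt, uniquify=False))
    if not q_matches or not t_matches:
        raise NoTemplateOverlapError("MCS pattern failed to match back")
    q_match, t_match = q_matches[0], t_matches[0]
    pairs = tuple(zip(q_match, t_match))
    # keep the largest connected piece on the query side
    comps = _connected_components(q, [p[0] for p in pairs])
    largest = max(comps, key=lambda c: (len(c), [-i for i in c]))
    keep = set(largest)
    pairs = tuple(p for p in pairs if p[0] in keep)
    if len(pairs) < min_atoms:
        raise NoTemplateOverlapError(
            f"common substructure has {len(pairs)} atoms (< {min_atoms})")
    return AtomMapping(pairs)


# ---------------------------------------------------------------------------
# conformer embedding
# ---------------------------------------------------------------------------

def embed_conformer(mol: Molecule, seed: int, max_retries: int = 5) -> Conformer3D:
    """Distance-geometry embedding + force-field cleanup; seed-deterministic."""
    mh = Chem.AddHs(mol.rdkit)
    conf_id = -1
    for attempt in range(max_retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        conf_id = AllChem.EmbedMolecule(mh, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(
            f"embedding failed after {max_retries} attempts for "
            f"{mol.canonical_text}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(mh):
            AllChem.MMFFOptimizeMolecule(mh, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mh, maxIters=500)
    except Exception:
        pass  # unoptimized geometry is still usable
    coords = mh.GetConformer().GetPositions()
    elements = tuple(a.GetSymbol() for a in mh.GetAtoms())
    return Conformer3D(mol, np.array(coords), elements, int(seed), mh)


# ---------------------------------------------------------------------------
# rigid superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, target: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation R and translation t minimizing ||moving@R.T + t - target||.

    Closed-form least-squares rigid superposition via SVD, with the
    determinant correction that excludes reflections.  Returns (R, t, rmsd).
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    mu_m, mu_t = moving.mean(axis=0), target.mean(axis=0)
    A, B = moving - mu_m, target - mu_t
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    moved = A @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return R, t, rmsd


def template_superimpose(conf: Conformer3D, template_conf: Conformer3D,
                         mapping: AtomMapping) -> Tuple[Conformer3D, float]:
    """Rigidly fit the conformer onto the template over mapped atoms."""
    if len(mapping) < 3:
        raise DegenerateAlignmentError(
            f"{len(mapping)} mapped atoms; need at least 3")
    q_idx, t_idx = mapping.query_indices, mapping.template_indices
    R, t, rmsd = kabsch(conf.coordinates[q_idx],
                        template_conf.coordinates[t_idx])
    return conf.transformed(R, t), rmsd


# ---------------------------------------------------------------------------
# clash scoring
# ---------------------------------------------------------------------------

def clash_scores(conf: Conformer3D, pocket: Optional[ReceptorPocket],
                 scale: float = 0.7,
                 radii: Optional[Mapping[str, float]] = None) -> Tuple[int, int]:
    """Count vdW overlaps: ligand-pocket (inter) and ligand-ligand (intra).

    A pair clashes when d < scale * (r_i + r_j).  Intra pairs separated by
    1, 2 or 3 bonds (1-2/1-3/1-4) are excluded.  Hydrogens are ignored.
    """
    if not 0 < scale <= 1:
        raise ConfigError(f"clash scale {scale} outside (0, 1]")
    radii = dict(radii) if radii is not None else load_vdw_radii()

    def radius(e: str) -> float:
        if e not in radii:
            raise ConfigError(f"unknown element in vdW table: {e!r}")
        return radii[e]

    heavy = conf.heavy_indices
    lig_xyz = conf.coordinates[heavy]
    lig_r = np.array([radius(conf.elements[i]) for i in heavy])

    inter = 0
    if pocket is not None and len(pocket.elements):
        poc_r = np.array([radius(e) for e in pocket.elements])
        d = np.linalg.norm(lig_xyz[:, None, :] - pocket.coordinates[None, :, :],
                           axis=2)
        inter = int(np.sum(d < scale * (lig_r[:, None] + poc_r[None, :])))

    intra = 0
    mol = conf.rdkit_h
    topo = Chem.GetDistanceMatrix(mol) if mol is not None else None
    n = len(heavy)
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = heavy[a], heavy[b]
            if topo is not None and topo[ia][ib] <= 3:
                continue
            d = float(np.linalg.norm(lig_xyz[a] - lig_xyz[b]))
            if d < scale * (lig_r[a] + lig_r[b]):
                intra += 1
    return inter, intra


# ---------------------------------------------------------------------------
# torsion quality
# ---------------------------------------------------------------------------

def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of the path p0-p1-p2-p3."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def torsion_quality(conf: Conformer3D, rules: Optional[Sequence[dict]] = None) -> int:
    """Count matched torsions whose |dihedral| is outside every allowed window."""
    if rules is None:
        rules = load_torsion_rules()
    mol = conf.rdkit_h if conf.rdkit_h is not None else conf.molecule.rdkit
    strained = 0
    seen: set = set()
    for rule in rules:
        patt = Chem.MolFromSmarts(rule["smarts"])
        if patt is None or patt.GetNumAtoms() != 4:
            raise ConfigError(f"torsion rule {rule.get('id')!r} must be a 4-atom SMARTS")
        windows = [(float(lo), float(hi)) for lo, hi in rule["allowed_abs_deg"]]
        for match in mol.GetSubstructMatches(patt):
            a1, a2, a3, a4 = match
            key = min((a1, a2, a3, a4), (a4, a3, a2, a1))
            if key in seen:
                continue
            seen.add(key)
            ang = abs(dihedral_deg(*(conf.coordinates[i] for i in match)))
            if not any(lo <= ang <= hi for lo, hi in windows):
                strained += 1
    return strained


# ---------------------------------------------------------------------------
# prioritization
# ---------------------------------------------------------------------------

def priority_score(ev: PoseEvaluation, weights: Mapping[str, float]) -> float:
    """Transparent weighted score; higher is better."""
    for k, w in weights.items():
        if w < 0:
            raise ConfigError(f"negative weight for {k!r}")
    w = {**DEFAULT_WEIGHTS, **weights}
    return (-w["inter_clash"] * ev.inter_clash_count
            - w["intra_clash"] * ev.intra_clash_count
            - w["torsion"] * ev.strained_torsion_count
            - w["rmsd"] * ev.mapped_atom_rmsd
            + w["physchem"] * (1.0 if ev.physchem_ok else 0.0))


def prioritize(evals: Sequence[Tuple[str, PoseEvaluation]],
               weights: Optional[Mapping[str, float]] = None) -> List[str]:
    """Rank compound ids by priority score (stable; ties by id/canonical text)."""
    weights = dict(weights or {})
    scored = []
    for cid, ev in evals:
        s = priority_score(ev, weights)
        ev.priority_score = s
        scored.append((cid, s))
    return [cid for cid, _ in sorted(scored, key=lambda x: (-x[1], x[0]))]
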