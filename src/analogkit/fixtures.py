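"""Synthetic fixtures with known ground truth for every pipeline input.

Everything the test surface consumes is generated here, deterministically
from a seed: toy seed molecules, miniature dictionary specs, melt curves,
NADH-decay kinetic traces, dose-response tables, ITC isotherms, pseudo-atom
pocket shells and the main-text SAR table.  Each written fixture is
accompanied by a manifest recording the generating parameters, so recovery
tests are self-contained.

Noise is additive Gaussian on fluorescence/heat.  Dose-response grids are
log-spaced over the campaign's cellular assay range (10 pM - 40 uM).
"""

from __future__ import annotations

import json
import math
import os
import urllib.request
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .assays import (DoseResponse, ItcIsotherm, ItcSite, KineticTrace,
                     MeltCurve, boltzmann, four_pl, itc_injection_heats)
from .chem import Molecule
from .errors import ConfigError
from .pose import Conformer3D, ReceptorPocket

#: masitinib - the campaign's parent compound and default toy seed
MASITINIB_SMILES = "CN1CCN(Cc2ccc(C(=O)Nc3ccc(C)c(Nc4nc(-c5cccnc5)cs4)c3)cc2)CC1"

KINDS = ("seed_set", "dictionary", "melt_curve", "kinetic_trace",
         "dose_response", "itc_isotherm", "pocket", "sar_ledger")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown fixture kind {self.kind!r}")


# ---------------------------------------------------------------------------
# in-memory generators
# ---------------------------------------------------------------------------

def toy_seed_set() -> List[Molecule]:
    """Masitinib plus small aromatic seeds used across the test surface."""
    return [
        Molecule.from_smiles(MASITINIB_SMILES, "masitinib"),
        Molecule.from_smiles("c1ccccc1", "benzene"),
        Molecule.from_smiles("Cc1ccc(C)cc1", "para-xylene"),
        Molecule.from_smiles("c1ccc(-c2ccccc2)cc1", "biphenyl"),
        Molecule.from_smiles("O=C(Nc1ccccc1)c1ccccc1", "benzanilide"),
    ]


def small_dictionary_spec(n_groups: int = 3) -> dict:
    """A miniature dictionary spec for oracle-scale tests (<= 50 entries)."""
    groups = [
        {"name": "methyl", "smiles": "[*]C"},
        {"name": "hydroxyl", "smiles": "[*]O"},
        {"name": "fluoro", "smiles": "[*]F"},
        {"name": "amino", "smiles": "[*]N"},
        {"name": "cyano", "smiles": "[*]C#N"},
    ][:n_groups]
    return {
        "version": 0,
        "functional_groups": groups,
        "rings": {
            "cores": [{"name": "cyclopropane", "smiles": "C1CC1"},
                      {"name": "benzene", "smiles": "c1ccccc1"}],
            "decorations": {"positions": ["none", "ortho", "para"],
                            "groups": [{"name": "methyl", "smiles": "[*]C"}]},
        },
        "spacers": {"lengths": [0, 1], "atoms": ["C", "O"]},
    }


def make_melt_curve(tm: float = 50.0, bottom: float = 0.1, top: float = 1.1,
                    slope: float = 1.0, noise_sd: float = 0.0, seed: int = 0,
                    t_min: float = 25.0, t_max: float = 95.0,
                    step: float = 0.5, label: str = "apo") -> MeltCurve:
    """Boltzmann melt curve with optional additive Gaussian noise."""
    T = np.arange(t_min, t_max + step / 2, step)
    F = boltzmann(T, bottom, top, tm, slope)
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, T.size)
    return MeltCurve(T, F, label)


def make_kinetic_trace(slope: float = -3.0, intercept: float = 1000.0,
                       n_points: int = 50, t_max: float = 100.0,
                       plateau_fraction: float = 0.0, noise_sd: float = 0.0,
                       seed: int = 0, condition: str = "drug-free") -> KineticTrace:
    """Linear NADH decay, optionally flattening into a plateau at the end."""
    t = np.linspace(0.0, t_max, n_points)
    if plateau_fraction > 0:
        t_break = t_max * (1.0 - plateau_fraction)
        f = np.where(t < t_break, intercept + slope * t,
                     intercept + slope * t_break)
    else:
        f = intercept + slope * t
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return KineticTrace(t, f, condition)


def make_dose_response(ic50_nM: float = 150.0, hill: float = 1.0,
                       top: float = 100.0, bottom: float = 0.0,
                       noise_frac: float = 0.03, seed: int = 7,
                       n_concentrations: int = 8, replicates: int = 3,
                       c_min_nM: float = 0.01, c_max_nM: float = 40000.0
                       ) -> DoseResponse:
    """4PL dose-response over a log-spaced grid (default 10 pM - 40 uM)."""
    grid = np.logspace(math.log10(c_min_nM), math.log10(c_max_nM),
                       n_concentrations)
    conc = np.repeat(grid, replicates)
    resp = four_pl(conc, bottom, top, ic50_nM, hill)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_frac * top, conc.size)
    reps = list(np.tile(np.arange(replicates), n_concentrations))
    return DoseResponse(conc, resp, reps)


def make_itc_isotherm(sites: Sequence[ItcSite] = (ItcSite(1.0, 37.0, -10.0),),
                      n_injections: int = 15, ratio_max: float = 2.5,
                      cell_uM: float = 80.0, syringe_uM: float = 400.0,
                      noise_sd: float = 0.0, seed: int = 0,
                      temperature_C: float = 25.0) -> ItcIsotherm:
    """Independent-sites isotherm (reverse-titration geometry by default:
    the compound sits in the cell, protein in the syringe)."""
    ratios = np.linspace(ratio_max / n_injections, ratio_max, n_injections)
    heats = itc_injection_heats(ratios, cell_uM * 1e-6, list(sites))
    if noise_sd > 0:
        heats = heats + np.random.default_rng(seed).normal(0.0, noise_sd,
                                                           ratios.size)
    return ItcIsotherm(ratios, heats, cell_uM, syringe_uM, temperature_C)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    theta = phi * i
    return np.column_stack([r * np.cos(theta), y, r * np.sin(theta)])


def make_pocket_shell(conformer: Conformer3D, radius: Optional[float] = None,
                      n_points: int = 64) -> ReceptorPocket:
    """Pseudo-carbon shell centered on the ligand - a clash-free pocket.

    With ``radius=None`` the shell sits 4 A beyond the ligand's furthest
    heavy atom (at least 12 A), guaranteeing no vdW contact.
    """
    center = conformer.coordinates[conformer.heavy_indices].mean(axis=0)
    if radius is None:
        extent = float(np.max(np.linalg.norm(
            conformer.coordinates[conformer.heavy_indices] - center, axis=1)))
        radius = max(12.0, extent + 4.0)
    coords = center + radius * fibonacci_sphere(n_points)
    return ReceptorPocket(coords, tuple(["C"] * n_points), source="synthetic")


def pocket_to_pdb_text(pocket: ReceptorPocket, resname: str = "SHL") -> str:
    """Serialize a pocket as HETATM records (strict PDB columns)."""
    lines = []
    for i, (xyz, el) in enumerate(zip(pocket.coordinates, pocket.elements),
                                  start=1):
        name = f" {el:<3s}" if len(el) == 1 else f"{el:<4s}"
        lines.append(
            f"HETATM{i:5d} {name}{'':1s}{resname:<3s} A{i:4d}{'':4s}"
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"{'':10s}{el:>2s}")
    return "\n".join(lines) + "\nEND\n"


def fetch_pdb(pdb_id: str, out_path: str) -> str:  # pragma: no cover
    """Convenience download of a deposited structure (never used by tests)."""
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    urllib.request.urlretrieve(url, out_path)
    return out_path


# ---------------------------------------------------------------------------
# file-writing front end
# ---------------------------------------------------------------------------

def _write(path: str, text: str) -> None:
    with open(path, "w") as fh:
        fh.write(text)


def _csv_text(header: Sequence[str], rows) -> str:
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join(
            f"{v:.10g}" if isinstance(v, float) else str(v) for v in row))
    return "\n".join(lines) + "\n"


def make_fixture(spec: FixtureSpec, out_dir: str) -> Dict[str, str]:
    """Write fixture files + a ground-truth manifest; byte-deterministic."""
    os.makedirs(out_dir, exist_ok=True)
    p = dict(spec.parameters)
    paths: Dict[str, str] = {}

    if spec.kind == "seed_set":
        seeds = toy_seed_set()
        path = os.path.join(out_dir, "seeds.smi")
        _write(path, "".join(f"{m.canonical_text} {m.name}\n" for m in seeds))
        paths["seeds"] = path
        truth = {"names": [m.name for m in seeds]}

    elif spec.kind == "dictionary":
        import yaml
        dspec = small_dictionary_spec(**p)
        path = os.path.join(out_dir, "dictionary.yaml")
        _write(path, yaml.safe_dump(dspec, sort_keys=True))
        paths["dictionary"] = path
        truth = {"spec": dspec}

    elif spec.kind == "melt_curve":
        curve = make_melt_curve(seed=spec.seed, **p)
        path = os.path.join(out_dir, "melt_curve.csv")
        _write(path, _csv_text(
            ("temperature_C", "fluorescence", "label"),
            ((float(t), float(f), curve.label)
             for t, f in zip(curve.temperature, curve.fluorescence))))
        paths["curve"] = path
        truth = {"tm": p.get("tm", 50.0), **p}

    elif spec.kind == "kinetic_trace":
        trace = make_kinetic_trace(seed=spec.seed, **p)
        path = os.path.join(out_dir, "kinetic_trace.csv")
        _write(path, _csv_text(
            ("time_s", "fluorescence", "condition"),
            ((float(t), float(f), trace.condition)
             for t, f in zip(trace.time, trace.fluorescence))))
        paths["trace"] = path
        truth = {"slope": p.get("slope", -3.0), **p}

    elif spec.kind == "dose_response":
        dr = make_dose_response(seed=spec.seed, **p)
        path = os.path.join(out_dir, "dose_response.csv")
        _write(path, _csv_text(
            ("concentration_nM", "response_pct", "replicate"),
            ((float(c), float(r), int(rep)) for c, r, rep in
             zip(dr.concentrations, dr.responses, dr.replicate_ids))))
        paths["dose_response"] = path
        truth = {"ic50_nM": p.get("ic50_nM", 150.0),
                 "hill": p.get("hill", 1.0), **p}

    elif spec.kind == "itc_isotherm":
        raw_sites = p.pop("sites", [{"n": 1.0, "kd_nM": 37.0,
                                     "dH_kcal_mol": -10.0}])
        sites = [ItcSite(**s) for s in raw_sites]
        iso = make_itc_isotherm(sites=sites, seed=spec.seed, **p)
        path = os.path.join(out_dir, "itc_isotherm.csv")
        _write(path, _csv_text(
            ("molar_ratio", "heat_kcal_per_mol_injectant"),
            ((float(r), float(h)) for r, h in
             zip(iso.molar_ratios, iso.heats))))
        paths["isotherm"] = path
        truth = {"sites": [s.__dict__ for s in sites],
                 "cell_uM": iso.cell_concentration_uM,
                 "syringe_uM": iso.syringe_concentration_uM, **p}

    elif spec.kind == "pocket":
        from .pose import embed_conformer
        template_smiles = p.pop("template_smiles", "c1ccccc1")
        conf = embed_conformer(Molecule.from_smiles(template_smiles),
                               seed=spec.seed)
        pocket = make_pocket_shell(conf, **p)
        path = os.path.join(out_dir, "pocket.pdb")
        _write(path, pocket_to_pdb_text(pocket))
        paths["pocket"] = path
        truth = {"template_smiles": template_smiles,
                 "radius": p.get("radius", 12.0),
                 "n_points": p.get("n_points", 64)}

    elif spec.kind == "sar_ledger":
        from .sar import maintext_ledger
        ledger = maintext_ledger()
        path = os.path.join(out_dir, "sar_ledger.csv")
        _write(path, ledger.to_csv())
        paths["ledger"] = path
        truth = {"n_records": len(ledger.records)}

    else:  # pragma: no cover - guarded by FixtureSpec
        raise ConfigError(f"unknown fixture kind {spec.kind!r}")

    manifest = {"kind": spec.kind, "seed": spec.seed,
                "parameters": spec.parameters, "ground_truth": truth,
                "files": {k: os.path.basename(v) for k, v in paths.items()}}
    mpath = os.path.join(out_dir, "manifest.json")
    _write(mpath, json.dumps(manifest, indent=2, sort_keys=True,
                             default=float) + "\n")
    paths["manifest"] = mpath
    return paths
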