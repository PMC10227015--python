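"""Shared format readers/writers, run configuration and the full pipeline.

Formats: SMILES lists and SDF for molecules, PDB for receptor pockets
(Biopython parser; waters excluded, highest-occupancy alternate locations
kept), tidy CSV for assay curves, CSV/JSON for reports.  Per-record errors
in molecule files are isolated: the bad record is skipped and logged, the
run continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser
from rdkit import Chem

from .assays import DoseResponse, ItcIsotherm, KineticTrace, MeltCurve
from .chem import Molecule
from .errors import (ConfigError, EmptyInputError, EmptyLibraryError,
                     EmptySelectionError)
from .filtering import (DEFAULT_WINDOWS, filter_library, load_alerts,
                        physchem_profile, standardize)
from .library import (AttachmentSite, DesignedCompound,
                      build_generic_dictionary, default_dictionary_spec,
                      enumerate_library)
from .pose import (PoseEvaluation, ReceptorPocket, clash_scores,
                   common_substructure_map, embed_conformer, prioritize,
                   template_superimpose, torsion_quality)

log = logging.getLogger(__name__)

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def read_molecules(path: str, fmt: Optional[str] = None) -> List[Molecule]:
    """Read molecules from a SMILES list or SDF with per-record isolation."""
    if fmt is None:
        fmt = "sdf" if str(path).lower().endswith(".sdf") else "smiles"
    mols: List[Molecule] = []
    skipped = 0
    if fmt == "smiles":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                smiles, _, name = line.partition(" ")
                rd = Chem.MolFromSmiles(smiles)
                if rd is None:
                    skipped += 1
                    log.warning("skipping unparsable SMILES record: %r", line)
                    continue
                mols.append(Molecule.from_rdkit(rd, name.strip() or None))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for rd in supplier:
            if rd is None:
                skipped += 1
                log.warning("skipping unparsable SDF record in %s", path)
                continue
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else None
            mols.append(Molecule.from_rdkit(rd, name or None))
    else:
        raise ConfigError(f"unknown molecule format {fmt!r}")
    if not mols:
        raise EmptyInputError(f"no valid molecule records in {path}")
    log.info("read %d molecules (%d skipped) from %s", len(mols), skipped, path)
    return mols


def write_library_sdf(lib: Sequence[DesignedCompound], prefix: str) -> Tuple[str, str]:
    """Write an enumerated library as SDF + provenance sidecar CSV."""
    sdf_path, csv_path = f"{prefix}.sdf", f"{prefix}.csv"
    writer = Chem.SDWriter(sdf_path)
    rows = []
    for i, c in enumerate(lib):
        rd = Chem.Mol(c.molecule.rdkit)
        cid = f"{c.seed_name}-{i:05d}"
        rd.SetProp("_Name", cid)
        rd.SetProp("seed", c.seed_name)
        rd.SetProp("site", c.site_label)
        rd.SetProp("fragment", c.fragment_name)
        writer.write(rd)
        rows.append((cid, c.seed_name, c.site_label, c.fragment_name,
                     c.molecule.canonical_text))
    writer.close()
    pd.DataFrame(rows, columns=["compound_id", "seed", "site", "fragment_id",
                                "canonical_text"]).to_csv(csv_path, index=False)
    return sdf_path, csv_path


# ---------------------------------------------------------------------------
# receptor pocket
# ---------------------------------------------------------------------------

def read_pocket(path: str, chains: Optional[Sequence[str]] = None,
                resnames: Optional[Sequence[str]] = None,
                exclude_waters: bool = True) -> ReceptorPocket:
    """Heavy atoms of the selected PDB records, 0-based internal indexing.

    Biopython keeps the highest-occupancy conformer of alternate locations;
    hydrogens and (by default) waters are dropped.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pocket", str(path))
    coords, elements = [], []
    for model in structure:
        for chain in model:
            if chains and chain.id not in chains:
                continue
            for residue in chain:
                resname = residue.get_resname().strip()
                if exclude_waters and resname in _WATER_RESNAMES:
                    continue
                if resnames and resname not in resnames:
                    continue
                for atom in residue:
                    el = (atom.element or "").strip().capitalize()
                    if el in ("H", "D", ""):
                        continue
                    coords.append(atom.get_coord())
                    elements.append(el)
        break  # first model only
    if not coords:
        raise EmptySelectionError(f"selection matched no atoms in {path}")
    return ReceptorPocket(np.array(coords, float), tuple(elements),
                          source=str(path))


# ---------------------------------------------------------------------------
# assay curve CSV readers (tidy, one row per point)
# ---------------------------------------------------------------------------

def read_melt_curve(path: str) -> MeltCurve:
    df = pd.read_csv(path)
    label = str(df["label"].iloc[0]) if "label" in df else "apo"
    return MeltCurve(df["temperature_C"].to_numpy(),
                     df["fluorescence"].to_numpy(), label)


def read_kinetic_trace(path: str) -> KineticTrace:
    df = pd.read_csv(path)
    condition = str(df["condition"].iloc[0]) if "condition" in df else "drug-free"
    return KineticTrace(df["time_s"].to_numpy(),
                        df["fluorescence"].to_numpy(), condition)


def read_dose_response(path: str) -> DoseResponse:
    df = pd.read_csv(path)
    reps = df["replicate"].tolist() if "replicate" in df else None
    return DoseResponse(df["concentration_nM"].to_numpy(),
                        df["response_pct"].to_numpy(), reps)


def read_itc_isotherm(path: str, cell_uM: float, syringe_uM: float,
                      temperature_C: float = 25.0) -> ItcIsotherm:
    df = pd.read_csv(path)
    return ItcIsotherm(df["molar_ratio"].to_numpy(),
                       df["heat_kcal_per_mol_injectant"].to_numpy(),
                       cell_uM, syringe_uM, temperature_C)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Single source of tunables for the end-to-end pipeline."""

    seed_smiles: str
    sites: List[dict] = field(default_factory=list)
    seed_name: str = "seed"
    dictionary_spec: Optional[str] = None  # path; None -> shipped default
    windows: Optional[Dict[str, list]] = None  # None -> DEFAULT_WINDOWS
    alerts: Optional[str] = None  # path; None -> shipped default list
    use_alerts: bool = True
    pocket: Optional[str] = None  # PDB path; None -> synthetic shell
    clash_scale: float = 0.7
    mcs_min_atoms: int = 5
    weights: Dict[str, float] = field(default_factory=dict)
    evaluate_limit: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _attachment_sites(site_dicts: Sequence[dict]) -> List[AttachmentSite]:
    return [AttachmentSite(seed_atom_index=int(s["atom"]),
                           site_label=str(s.get("label", s["atom"])),
                           mode=s.get("mode", "substitute_hydrogen"))
            for s in site_dicts]


def run_pipeline(config: RunConfig) -> dict:
    """enumerate -> standardize -> filter -> embed -> align -> evaluate ->
    prioritize, with per-stage counts and a JSON-serializable report.

    Fully reproducible from the config and its global seed; any stage error
    aborts with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    report: dict = {"config": config.to_dict(), "stages": {}}
    stage = "setup"
    t_start = time.time()
    try:
        stage = "enumerate"
        seed_mol = Molecule.from_smiles(config.seed_smiles, config.seed_name)
        if config.dictionary_spec:
            with open(config.dictionary_spec) as fh:
                dspec = yaml.safe_load(fh)
        else:
            dspec = default_dictionary_spec()
        dictionary = build_generic_dictionary(dspec)
        sites = _attachment_sites(config.sites)
        library = enumerate_library(seed_mol, sites, dictionary)
        report["stages"]["enumerated"] = len(library)

        stage = "standardize"
        library = [dataclasses.replace(c, molecule=standardize(c.molecule))
                   for c in library]
        report["stages"]["standardized"] = len(library)

        stage = "filter"
        alert_set = (load_alerts(config.alerts) if config.use_alerts else [])
        windows = config.windows if config.windows is not None else DEFAULT_WINDOWS
        retained, filt_report = filter_library(library, windows, alert_set)
        report["stages"]["retained"] = filt_report.retained_count
        report["filter"] = {
            "input": filt_report.input_count,
            "retained": filt_report.retained_count,
            "rejections_by_rule": filt_report.rejections_by_rule,
        }

        stage = "evaluate"
        template_conf = embed_conformer(seed_mol, seed=config.seed)
        pocket = (read_pocket(config.pocket) if config.pocket else None)
        if pocket is None:
            from .fixtures import make_pocket_shell
            pocket = make_pocket_shell(template_conf)
        to_eval = retained[: config.evaluate_limit]
        evals: List[Tuple[str, PoseEvaluation]] = []
        for compound in to_eval:
            try:
                mapping = common_substructure_map(
                    compound.molecule, seed_mol, min_atoms=config.mcs_min_atoms)
                conf = embed_conformer(compound.molecule, seed=config.seed)
                aligned, rmsd = template_superimpose(conf, template_conf, mapping)
                inter, intra = clash_scores(aligned, pocket, config.clash_scale)
                strained = torsion_quality(aligned)
            except Exception as exc:
                log.warning("evaluation skipped for %s: %s",
                            compound.molecule.canonical_text, exc)
                continue
            evals.append((compound.molecule.canonical_text,
                          PoseEvaluation(rmsd, inter, intra, strained)))
        report["stages"]["evaluated"] = len(evals)

        stage = "prioritize"
        ranking = prioritize(evals, config.weights)
        report["ranking"] = ranking
        report["evaluations"] = {
            cid: {"rmsd": ev.mapped_atom_rmsd,
                  "inter_clashes": ev.inter_clash_count,
                  "intra_clashes": ev.intra_clash_count,
                  "strained_torsions": ev.strained_torsion_count,
                  "priority_score": ev.priority_score}
            for cid, ev in evals}
    except Exception as exc:
        report["aborted_at"] = stage
        report["error"] = str(exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        report["elapsed_s"] = round(time.time() - t_start, 3)

    stable = {k: v for k, v in report.items() if k != "elapsed_s"}
    blob = json.dumps(stable, sort_keys=True, default=str).encode()
    report["report_digest"] = hashlib.sha256(blob).hexdigest()
    return report
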