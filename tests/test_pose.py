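"""Common-substructure mapping, embedding, superposition and pose scoring."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from analogkit.chem import Molecule
from analogkit.errors import (ConfigError, DegenerateAlignmentError,
                              NoTemplateOverlapError)
from analogkit.pose import (AtomMapping, Conformer3D, PoseEvaluation,
                            ReceptorPocket, clash_scores,
                            common_substructure_map, dihedral_deg,
                            embed_conformer, kabsch, load_vdw_radii,
                            prioritize, priority_score, template_superimpose,
                            torsion_quality)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def grid_oracle_rmsd(moving, target, n_grid=14):
    """Rotation-grid + local-refinement superposition oracle."""
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    A = moving - moving.mean(axis=0)
    B = target - target.mean(axis=0)

    def rmsd_of(euler):
        R = Rotation.from_euler("zyx", euler).as_matrix()
        return math.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1)))

    best, best_e = np.inf, None
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    half = np.linspace(-np.pi / 2, np.pi / 2, n_grid // 2)
    for e in itertools.product(grid, half, grid):
        v = rmsd_of(e)
        if v < best:
            best, best_e = v, e
    res = minimize(rmsd_of, best_e, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return min(best, float(res.fun))


def brute_force_mcs_size(mol_a, mol_b):
    """Largest connected common subgraph by exhaustive search (tiny mols)."""
    import networkx as nx
    from networkx.algorithms import isomorphism as iso

    def graph(mol):
        g = nx.Graph()
        for a in mol.GetAtoms():
            g.add_node(a.GetIdx(), el=a.GetSymbol())
        for b in mol.GetBonds():
            g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                       order=str(b.GetBondType()))
        return g

    ga, gb = graph(mol_a), graph(mol_b)
    nm = iso.categorical_node_match("el", "")
    em = iso.categorical_edge_match("order", "")
    # search connected subgraphs of ga from largest size down
    for size in range(min(len(ga), len(gb)), 0, -1):
        for nodes in itertools.combinations(ga.nodes, size):
            sub = ga.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            gm = iso.GraphMatcher(gb, sub, node_match=nm, edge_match=em)
            if gm.subgraph_is_isomorphic():
                return size
    return 0


# ---------------------------------------------------------------------------
# common substructure
# ---------------------------------------------------------------------------

def test_self_mapping_is_identity(benzene):
    m = common_substructure_map(benzene, benzene)
    assert len(m) == benzene.num_heavy_atoms
    assert all(q == t for q, t in m.pairs)


def test_toluene_to_benzene_maps_ring(benzene):
    m = common_substructure_map(Molecule.from_smiles("Cc1ccccc1"), benzene)
    assert len(m) == 6


def test_mcs_size_matches_bruteforce():
    a = Molecule.from_smiles("c1ccc2ccccc2c1")  # naphthalene
    b = Molecule.from_smiles("c1ccc2[nH]ccc2c1")  # indole
    m = common_substructure_map(a, b)
    assert len(m) == brute_force_mcs_size(a.rdkit, b.rdkit)


def test_no_overlap_raises(benzene):
    with pytest.raises(NoTemplateOverlapError):
        common_substructure_map(Molecule.from_smiles("CC"), benzene)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def test_methane_geometry():
    conf = embed_conformer(Molecule.from_smiles("C"), seed=3)
    d = np.linalg.norm(conf.coordinates[1:] - conf.coordinates[0], axis=1)
    assert np.all(np.abs(d - 1.09) < 0.16)


def test_embedding_deterministic(masitinib):
    c1 = embed_conformer(masitinib, seed=42)
    c2 = embed_conformer(masitinib, seed=42)
    assert np.array_equal(c1.coordinates, c2.coordinates)


def test_cyclohexane_geometry_audit():
    conf = embed_conformer(Molecule.from_smiles("C1CCCCC1"), seed=5)
    heavy = conf.heavy_indices
    xyz = conf.coordinates[heavy]
    mol = conf.rdkit_h
    topo = Chem.GetDistanceMatrix(mol)
    for i in range(6):
        for j in range(i + 1, 6):
            d = np.linalg.norm(xyz[i] - xyz[j])
            if topo[heavy[i]][heavy[j]] == 1:
                assert abs(d - 1.54) < 0.23
            else:
                assert d > 1.8


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(0, 2**31)))).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t


def test_exact_copy_rmsd_zero(benzene):
    conf = embed_conformer(benzene, seed=1)
    mapping = AtomMapping(tuple((i, i) for i in range(6)))
    _, rmsd = template_superimpose(conf, conf, mapping)
    assert rmsd < 1e-10


def test_rigid_motion_invariance(rng):
    conf = embed_conformer(Molecule.from_smiles("CCO"), seed=2)
    R, t = _random_rigid(rng)
    moved = conf.transformed(R, t)
    mapping = AtomMapping(tuple((i, i) for i in range(len(conf.elements))))
    _, rmsd = template_superimpose(moved, conf, mapping)
    assert rmsd < 1e-9


def test_kabsch_matches_grid_oracle(rng):
    """Closed-form rmsd equals the SO(3) grid+refine oracle within 1e-4 A."""
    for _ in range(4):
        n = int(rng.integers(4, 8))
        target = rng.uniform(-3, 3, (n, 3))
        moving = target + rng.normal(0, 0.4, (n, 3))
        R, t = _random_rigid(rng)
        moving = moving @ R.T + t
        _, _, rmsd = kabsch(moving, target)
        oracle = grid_oracle_rmsd(moving, target)
        assert rmsd <= oracle + 1e-4
        assert abs(rmsd - oracle) < 1e-4


def test_degenerate_mapping_raises(benzene):
    conf = embed_conformer(benzene, seed=1)
    with pytest.raises(DegenerateAlignmentError):
        template_superimpose(conf, conf, AtomMapping(((0, 0), (1, 1))))


# ---------------------------------------------------------------------------
# clash scores
# ---------------------------------------------------------------------------

def test_distant_pocket_no_inter_clash(benzene):
    conf = embed_conformer(benzene, seed=1)
    pocket = ReceptorPocket(conf.coordinates[:1] + 20.0, ("C",))
    inter, intra = clash_scores(conf, pocket, 0.7)
    assert inter == 0


def test_forced_overlap_clashes(benzene):
    conf = embed_conformer(benzene, seed=1)
    pocket = ReceptorPocket(conf.coordinates[[0]] + [0.5, 0, 0], ("C",))
    inter, _ = clash_scores(conf, pocket, 0.7)
    assert inter >= 1


def test_clash_counts_match_double_loop(rng):
    """Vectorized counts equal a plain O(n^2) reference on random fixtures."""
    radii = load_vdw_radii()
    conf = embed_conformer(Molecule.from_smiles("CCCCO"), seed=9)
    heavy = conf.heavy_indices
    topo = Chem.GetDistanceMatrix(conf.rdkit_h)
    for _ in range(25):
        scale = float(rng.uniform(0.3, 1.0))
        pocket_xyz = rng.uniform(-4, 4, (int(rng.integers(3, 20)), 3))
        elements = tuple(rng.choice(["C", "N", "O", "S"], len(pocket_xyz)))
        pocket = ReceptorPocket(pocket_xyz, elements)
        inter, intra = clash_scores(conf, pocket, scale, radii)
        ref_inter = 0
        for i in heavy:
            for j in range(len(elements)):
                d = np.linalg.norm(conf.coordinates[i] - pocket_xyz[j])
                if d < scale * (radii[conf.elements[i]] + radii[elements[j]]):
                    ref_inter += 1
        ref_intra = 0
        for ai in range(len(heavy)):
            for aj in range(ai + 1, len(heavy)):
                i, j = heavy[ai], heavy[aj]
                if topo[i][j] <= 3:
                    continue
                d = np.linalg.norm(conf.coordinates[i] - conf.coordinates[j])
                if d < scale * (radii[conf.elements[i]] + radii[conf.elements[j]]):
                    ref_intra += 1
        assert (inter, intra) == (ref_inter, ref_intra)


def test_clash_monotone_in_scale(benzene, rng):
    conf = embed_conformer(benzene, seed=1)
    pocket = ReceptorPocket(rng.uniform(-3, 3, (10, 3)),
                            tuple(["C"] * 10))
    counts = [sum(clash_scores(conf, pocket, s)) for s in (0.3, 0.5, 0.7, 1.0)]
    assert counts == sorted(counts)


def test_unknown_element_rejected(benzene):
    conf = embed_conformer(benzene, seed=1)
    pocket = ReceptorPocket(np.zeros((1, 3)), ("Xx",))
    with pytest.raises(ConfigError):
        clash_scores(conf, pocket, 0.7)


# ---------------------------------------------------------------------------
# torsion quality
# ---------------------------------------------------------------------------

def _butane_at(angle_deg):
    from rdkit.Chem import rdMolTransforms
    conf = embed_conformer(Molecule.from_smiles("CCCC"), seed=2)
    mol = Chem.Mol(conf.rdkit_h)
    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    rdMolTransforms.SetDihedralDeg(mol.GetConformer(), *carbons, angle_deg)
    return Conformer3D(conf.molecule,
                       np.array(mol.GetConformer().GetPositions()),
                       conf.elements, 2, mol), carbons


def test_anti_butane_unstrained():
    conf, _ = _butane_at(180.0)
    assert torsion_quality(conf) == 0


def test_eclipsed_butane_strained():
    conf, _ = _butane_at(0.0)
    assert torsion_quality(conf) == 1


def test_torsion_counts_match_manual_dihedral():
    """Strain counts agree with the 4-point dihedral formula applied by hand."""
    rules = [{"id": "sp3", "smarts": "[CX4][CX4][CX4][CX4]",
              "allowed_abs_deg": [[40.0, 80.0], [150.0, 180.0]]}]
    for angle in (0.0, 20.0, 60.0, 90.0, 120.0, 150.0, 180.0, -60.0, -120.0, -170.0):
        conf, carbons = _butane_at(angle)
        manual = abs(dihedral_deg(*(conf.coordinates[i] for i in carbons)))
        expected = 0 if (40 <= manual <= 80 or 150 <= manual <= 180) else 1
        assert torsion_quality(conf, rules) == expected


# ---------------------------------------------------------------------------
# prioritization
# ---------------------------------------------------------------------------

def test_single_compound_ranks_alone():
    assert prioritize([("only", PoseEvaluation(1.0, 0, 0, 0))]) == ["only"]


def test_clash_free_dominates():
    clean = PoseEvaluation(0.5, 0, 0, 0)
    clashed = PoseEvaluation(0.5, 1, 0, 0)
    for w in (0.1, 1.0, 10.0):
        assert prioritize([("clashed", clashed), ("clean", clean)],
                          {"inter_clash": w}) == ["clean", "clashed"]


def test_ranking_matches_reference_rescoring(rng):
    evals = []
    for i in range(20):
        evals.append((f"c{i:02d}", PoseEvaluation(
            float(rng.uniform(0, 3)), int(rng.integers(0, 4)),
            int(rng.integers(0, 3)), int(rng.integers(0, 5)),
            bool(rng.integers(0, 2)))))
    weights = {"inter_clash": 2.0, "intra_clash": 1.0, "torsion": 0.5,
               "rmsd": 0.25, "physchem": 1.5}
    ranked = prioritize(evals, weights)
    ref = sorted(evals, key=lambda kv: (-(
        -2.0 * kv[1].inter_clash_count - 1.0 * kv[1].intra_clash_count
        - 0.5 * kv[1].strained_torsion_count - 0.25 * kv[1].mapped_atom_rmsd
        + 1.5 * (1.0 if kv[1].physchem_ok else 0.0)), kv[0]))
    assert ranked == [cid for cid, _ in ref]


def test_lowering_penalty_never_lowers_rank(rng):
    base = [(f"c{i}", PoseEvaluation(float(rng.uniform(0, 2)),
                                     int(rng.integers(0, 3)), 0,
                                     int(rng.integers(0, 3))))
            for i in range(8)]
    ranked = prioritize(base)
    target = "c3"
    improved = [(cid, PoseEvaluation(ev.mapped_atom_rmsd,
                                     max(0, ev.inter_clash_count - 1)
                                     if cid == target else ev.inter_clash_count,
                                     ev.intra_clash_count,
                                     ev.strained_torsion_count))
                for cid, ev in base]
    ranked2 = prioritize(improved)
    assert ranked2.index(target) <= ranked.index(target)


def test_negative_weight_rejected():
    with pytest.raises(ConfigError):
        priority_score(PoseEvaluation(0, 0, 0, 0), {"rmsd": -1.0})
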