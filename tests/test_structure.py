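import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from foldswitch.structure import (Atom, ContactMap, RegionSpec, Residue,
                                  StructureModel, contact_map,
                                  interchain_contacts, kabsch_superpose, lddt,
                                  pairwise_lddt_matrix, pairwise_tm_matrix,
                                  read_pdb, secondary_structure, tm_d0,
                                  tm_d0_raw, tm_score, write_pdb)
from foldswitch.synth import make_backbone, perturb

from conftest import random_rotation


def rotate_model(model, R, t=np.zeros(3)):
    residues = []
    for res in model.residues:
        atoms = [Atom(a.name, a.element, tuple(R @ a.coords + t))
                 for a in res.atoms]
        residues.append(Residue(res.index, res.name, res.chain, atoms))
    return StructureModel(residues, model.confidence)


# ---------------------------------------------------------------------------
# PDB I/O

def test_pdb_round_trip(tmp_path, helix30):
    path = tmp_path / "h.pdb"
    write_pdb(helix30, path)
    back = read_pdb(path)
    assert len(back) == 30
    np.testing.assert_allclose(back.ca_coords(), helix30.ca_coords(),
                               atol=1.5e-3)


def test_read_pdb_hand_written_minimal(tmp_path):
    lines = []
    serial = 1
    for i, (x, name) in enumerate([(0.0, "ALA"), (3.8, "GLY"), (7.6, "SER")]):
        for aname, dx in (("N", -1.0), ("CA", 0.0), ("C", 1.0)):
            lines.append(
                f"ATOM  {serial:5d} {aname:<4s} {name:<3s} A{i + 1:4d}    "
                f"{x + dx:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{77.0:6.2f}"
                f"          {aname[0]:>2s}")
            serial += 1
    (tmp_path / "toy.pdb").write_text("\n".join(lines) + "\nEND\n")
    model = read_pdb(tmp_path / "toy.pdb")
    assert len(model) == 3
    assert [r.name for r in model.residues] == ["ALA", "GLY", "SER"]
    assert model.confidence[0] == pytest.approx(77.0)


def test_altloc_keeps_highest_occupancy_tie_to_a(tmp_path):
    pdb = "\n".join([
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C",
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C",
        "ATOM      3  CA AALA A   2       3.800   0.000   0.000  0.50 10.00           C",
        "ATOM      4  CA BALA A   2       9.000   0.000   0.000  0.50 10.00           C",
        "END",
    ])
    (tmp_path / "alt.pdb").write_text(pdb + "\n")
    model = read_pdb(tmp_path / "alt.pdb")
    assert model.residues[0].ca.xyz[0] == pytest.approx(5.0)   # occ 0.60 wins
    assert model.residues[1].ca.xyz[0] == pytest.approx(3.8)   # tie -> A


def test_residue_without_ca_dropped_with_warning(tmp_path):
    pdb = "\n".join([
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C",
        "ATOM      2  N   ALA A   2       3.800   0.000   0.000  1.00 10.00           N",
        "END",
    ])
    (tmp_path / "noca.pdb").write_text(pdb + "\n")
    with pytest.warns(UserWarning, match="no CA"):
        model = read_pdb(tmp_path / "noca.pdb")
    assert len(model) == 1


# ---------------------------------------------------------------------------
# Kabsch

def test_kabsch_identity():
    A = np.random.default_rng(0).normal(size=(10, 3))
    R, t, rmsd = kabsch_superpose(A, A)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-9)


def test_kabsch_recovers_known_transform():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(12, 3))
    R_true = random_rotation(rng)
    t_true = np.array([1.0, -2.0, 0.5])
    B = A @ R_true.T + t_true
    R, t, rmsd = kabsch_superpose(A, B)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(R, R_true, atol=1e-8)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_kabsch_never_worse_than_unsuperposed():
    rng = np.random.default_rng(2)
    for _ in range(20):
        A = rng.normal(size=(8, 3))
        B = A + rng.normal(scale=0.5, size=(8, 3))
        _, _, rmsd = kabsch_superpose(A, B)
        raw = np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1)))
        assert rmsd <= raw + 1e-12


def test_kabsch_matches_rotation_grid_oracle():
    """Grid over SO(3) + local polish must agree with the closed form."""
    rng = np.random.default_rng(3)
    A = np.array([[0, 0, 0], [1.5, 0, 0], [1.5, 2.0, 0], [0.3, 1.0, 1.2]])
    B = A + rng.normal(scale=0.3, size=A.shape)
    _, _, rmsd = kabsch_superpose(A, B)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        Ar = (A - A.mean(0)) @ R.T + B.mean(0)
        return np.sqrt(np.mean(np.sum((Ar - B) ** 2, axis=1)))

    best = np.inf
    for rv in Rotation.random(300, random_state=7).as_rotvec():
        res = minimize(objective, rv, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 4000})
        best = min(best, res.fun)
    assert rmsd == pytest.approx(best, abs=1e-6)


def test_kabsch_rejects_tiny_input():
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# TM-score

def test_d0_formula_and_floor():
    # bare formula at L=21: 1.24 * 6^(1/3) - 1.8
    assert tm_d0_raw(21) == pytest.approx(0.4532, abs=1e-4)
    assert tm_d0(21) == 0.5          # conventional floor engages
    assert tm_d0(120) == pytest.approx(1.24 * 105 ** (1 / 3) - 1.8)


def test_tm_score_self_is_one(helix30, hairpin30):
    assert tm_score(helix30, helix30) == pytest.approx(1.0)
    assert tm_score(hairpin30, hairpin30) == pytest.approx(1.0)
    region = RegionSpec.parse("5-20")
    assert tm_score(helix30, helix30, region) == pytest.approx(1.0)


def test_tm_score_rigid_invariance(helix30, hairpin30):
    rng = np.random.default_rng(4)
    base = tm_score(helix30, hairpin30)
    for _ in range(10):
        moved = rotate_model(helix30, random_rotation(rng),
                             rng.normal(scale=20, size=3))
        assert tm_score(moved, hairpin30) == pytest.approx(base, abs=1e-3)


def test_tm_score_beats_any_single_superposition(helix30, hairpin30):
    x = helix30.ca_coords()
    y = hairpin30.ca_coords()
    R, t, _ = kabsch_superpose(x, y)
    d = np.linalg.norm(x @ R.T + t - y, axis=1)
    d0 = tm_d0(len(y))
    single = np.mean(1.0 / (1.0 + (d / d0) ** 2))
    assert tm_score(helix30, hairpin30) >= single - 1e-9


def test_tm_score_matches_restart_optimization_oracle(helix30, hairpin30):
    """Heuristic must reach the max found by many random-restart local opts."""
    x = helix30.ca_coords()
    y = hairpin30.ca_coords()
    d0 = tm_d0(len(y))

    def neg_tm(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        d = np.linalg.norm(x @ R.T + params[3:] - y, axis=1)
        return -np.mean(1.0 / (1.0 + (d / d0) ** 2))

    best = 0.0
    rng = np.random.default_rng(5)
    for rv in Rotation.random(80, random_state=11).as_rotvec():
        R0 = Rotation.from_rotvec(rv).as_matrix()
        t0 = y.mean(0) - R0 @ x.mean(0)
        res = minimize(neg_tm, np.concatenate([rv, t0]),
                       method="Nelder-Mead",
                       options={"maxiter": 3000, "xatol": 1e-6, "fatol": 1e-9})
        best = max(best, -res.fun)
    ours = tm_score(helix30, hairpin30)
    assert ours == pytest.approx(best, abs=0.01)
    assert ours < 0.5   # different folds


def test_region_tm_score_full_region_equals_global(helix30, hairpin30):
    region = RegionSpec(((1, 30),))
    assert tm_score(helix30, hairpin30, region) == pytest.approx(
        tm_score(helix30, hairpin30), abs=1e-6)


def test_region_too_short_rejected(helix30):
    with pytest.raises(ValueError):
        tm_score(helix30, helix30, RegionSpec(((1, 2),)))
    with pytest.raises(ValueError):
        tm_score(helix30, helix30, RegionSpec(((100, 120),)))


def test_region_superpose_scope_flag(helix30):
    # hinge-bend model: region 16-30 identical to the reference, 1-15 swung
    rng = np.random.default_rng(9)
    bent_res = []
    R = random_rotation(rng)
    pivot = helix30.residues[15].ca.coords
    for r in helix30.residues:
        if r.index <= 15:
            atoms = [Atom(a.name, a.element,
                          tuple(R @ (a.coords - pivot) + pivot))
                     for a in r.atoms]
            bent_res.append(Residue(r.index, r.name, r.chain, atoms))
        else:
            bent_res.append(r)
    bent = StructureModel(bent_res)
    region = RegionSpec.parse("16-30")
    local = tm_score(bent, helix30, region, "region")
    glob = tm_score(bent, helix30, region, "global")
    assert local == pytest.approx(1.0)      # region superposes exactly
    assert 0.0 < glob <= 1.0 + 1e-9
    # full-structure score is hurt by the swung arm
    assert tm_score(bent, helix30) < 1.0


# ---------------------------------------------------------------------------
# lDDT

def test_lddt_self_and_rigid_invariance(helix30):
    assert lddt(helix30, helix30) == pytest.approx(1.0)
    rng = np.random.default_rng(6)
    moved = rotate_model(helix30, random_rotation(rng), np.array([5, 5, 5.0]))
    assert lddt(moved, helix30) == pytest.approx(1.0)


def test_lddt_matches_hand_enumeration():
    """5-residue toy, one CA displaced 3 Å, checked pair by pair."""
    coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                       [11.4, 0, 0], [15.2, 0, 0.0]])
    moved = coords.copy()
    moved[2, 2] += 3.0

    def model_from(ca):
        residues = [Residue(i + 1, "ALA", "A", [Atom("CA", "C", tuple(c))])
                    for i, c in enumerate(ca)]
        return StructureModel(residues)

    expected_fracs = []
    for thr in (0.5, 1.0, 2.0, 4.0):
        hits = total = 0
        for i in range(5):
            for j in range(i + 1, 5):
                dref = np.linalg.norm(coords[i] - coords[j])
                if j - i < 2 or dref >= 15.0:
                    continue
                total += 1
                dmod = np.linalg.norm(moved[i] - moved[j])
                hits += abs(dmod - dref) < thr
        expected_fracs.append(hits / total)
    expected = np.mean(expected_fracs)
    got = lddt(model_from(moved), model_from(coords))
    assert got == pytest.approx(expected, abs=1e-12)


def test_lddt_requires_qualifying_pairs():
    residues = [Residue(i + 1, "ALA", "A",
                        [Atom("CA", "C", (i * 100.0, 0, 0))])
                for i in range(3)]
    far = StructureModel(residues)
    with pytest.raises(ValueError, match="qualifying"):
        lddt(far, far)


# ---------------------------------------------------------------------------
# contacts

def brute_force_contacts(model, cutoff, min_sep):
    pairs = set()
    rs = model.residues
    for i in range(len(rs)):
        for j in range(len(rs)):
            a, b = rs[i], rs[j]
            if b.index - a.index < min_sep or b.index <= a.index:
                continue
            for at1 in a.atoms:
                if at1.is_hydrogen:
                    continue
                for at2 in b.atoms:
                    if at2.is_hydrogen:
                        continue
                    if np.linalg.norm(at1.coords - at2.coords) <= cutoff:
                        pairs.add((a.index, b.index))
    return pairs


@pytest.mark.parametrize("seed", range(8))
def test_contact_map_equals_brute_force(seed):
    model = make_backbone("coil", 15, seed=seed)
    cm = contact_map(model, cutoff=8.0, min_sep=1)
    assert cm.pairs == frozenset(brute_force_contacts(model, 8.0, 1))


def test_contact_cutoff_boundary():
    def two_res(dist):
        residues = [
            Residue(1, "ALA", "A", [Atom("CA", "C", (0.0, 0, 0))]),
            Residue(2, "ALA", "A", [Atom("CA", "C", (dist, 0, 0))]),
        ]
        return StructureModel(residues)

    assert (1, 2) in contact_map(two_res(7.9))
    assert (1, 2) not in contact_map(two_res(8.1))


def test_contact_min_separation():
    model = make_backbone("helix", 12)
    cm = contact_map(model, min_sep=6)
    assert all(j - i >= 6 for i, j in cm.pairs)


def test_interchain_contacts_empty_when_far(helix30):
    far = rotate_model(helix30, np.eye(3), np.array([500.0, 0, 0]))
    far = StructureModel([Residue(r.index, r.name, "B", r.atoms)
                          for r in far.residues])
    assembly = StructureModel(helix30.residues + far.residues)
    assert len(interchain_contacts(assembly)) == 0


def test_interchain_contacts_match_brute_force_and_symmetry(helix30):
    shifted = StructureModel([
        Residue(r.index, r.name, "B",
                [Atom(a.name, a.element, (a.xyz[0], a.xyz[1] + 6.0, a.xyz[2]))
                 for a in r.atoms])
        for r in helix30.residues])
    assembly = StructureModel(helix30.residues + shifted.residues)
    cm = interchain_contacts(assembly, cutoff=8.0)
    assert len(cm) > 0
    expected = set()
    for r1 in helix30.residues:
        for r2 in shifted.residues:
            if r1.index == r2.index:
                continue
            dmin = min(np.linalg.norm(a.coords - b.coords)
                       for a in r1.atoms for b in r2.atoms)
            if dmin <= 8.0:
                expected.add((min(r1.index, r2.index),
                              max(r1.index, r2.index)))
    assert cm.pairs == frozenset(expected)
    # homodimer: swapping chain roles leaves the chain-1-indexed map unchanged
    swapped = StructureModel(shifted.residues + helix30.residues)
    assert interchain_contacts(swapped).pairs == cm.pairs


def test_interchain_requires_two_chains(helix30):
    with pytest.raises(ValueError, match="2 chains"):
        interchain_contacts(helix30)


# ---------------------------------------------------------------------------
# secondary structure

def test_ideal_helix_mostly_h():
    ss = secondary_structure(make_backbone("helix", 20))
    assert ss.count("H") / len(ss) >= 0.8


def test_isolated_extended_chain_all_coil():
    ss = secondary_structure(make_backbone("strand", 20))
    assert set(ss) == {"C"}


def test_hairpin_has_strand_residues_in_both_arms():
    L = 24
    ss = secondary_structure(make_backbone("hairpin", L))
    first, second = ss[:L // 2 - 2], ss[L // 2 + 2:]
    assert "E" in first and "E" in second


def test_missing_backbone_labels_coil():
    model = make_backbone("helix", 12)
    residues = list(model.residues)
    residues[5] = Residue(residues[5].index, "ALA", "A",
                          [a for a in residues[5].atoms if a.name == "CA"])
    broken = StructureModel(residues)
    with pytest.warns(UserWarning, match="incomplete backbone"):
        ss = secondary_structure(broken)
    assert ss[5] == "C"


# ---------------------------------------------------------------------------
# batched pairwise scores

def test_pairwise_matrices_agree_with_scalar(small_ensemble):
    models = small_ensemble.models[:12]
    coords = np.stack([m.ca_coords() for m in models])
    S_tm = pairwise_tm_matrix(coords)
    S_l = pairwise_lddt_matrix(coords)
    assert np.allclose(S_tm, S_tm.T) and np.allclose(S_l, S_l.T)
    assert np.allclose(np.diag(S_tm), 1.0) and np.allclose(np.diag(S_l), 1.0)
    rng = np.random.default_rng(8)
    for _ in range(6):
        i, j = rng.choice(len(models), 2, replace=False)
        scalar_tm = tm_score(models[i], models[j])
        assert S_tm[i, j] <= scalar_tm + 1e-9   # scalar searches more seeds
        assert S_tm[i, j] == pytest.approx(scalar_tm, abs=0.05)
        sym = 0.5 * (lddt(models[i], models[j]) + lddt(models[j], models[i]))
        assert S_l[i, j] == pytest.approx(sym, abs=1e-9)
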