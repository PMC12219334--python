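"""Structure containers and core coordinate computations.

Everything downstream of the predictor works on :class:`StructureModel`:
PDB I/O, Kabsch superposition, TM-score (global and region-restricted),
superposition-free lDDT, heavy-atom contact maps, and a three-state
secondary-structure assignment in the Kabsch-Sander style.

Residue correspondence between two models is positional (by residue index):
within one prediction run all models share the query sequence, so no
structural alignment search is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "RegionSpec",
    "ContactMap",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "tm_d0",
    "tm_d0_raw",
    "tm_score",
    "lddt",
    "contact_map",
    "interchain_contacts",
    "secondary_structure",
    "pairwise_tm_matrix",
    "pairwise_lddt_matrix",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    index: int              # 1-based author numbering
    name: str               # 3-letter amino-acid code
    chain: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class StructureModel:
    """An ordered polypeptide model, possibly multi-chain.

    ``confidence`` carries per-residue predictor confidence (plDDT, 0-100)
    aligned to ``residues``; it is optional for experimental references.
    """

    residues: list[Residue]
    confidence: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for r in self.residues:
            prev = seen.get(r.chain)
            if prev is not None and r.index <= prev:
                raise ValueError(
                    f"residue indices must strictly increase within chain "
                    f"{r.chain!r}: {r.index} after {prev}"
                )
            seen[r.chain] = r.index
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if len(self.confidence) != len(self.residues):
                raise ValueError("confidence length must equal residue count")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def chain(self, chain_id: str) -> "StructureModel":
        rows = [i for i, r in enumerate(self.residues) if r.chain == chain_id]
        conf = self.confidence[rows] if self.confidence is not None else None
        return StructureModel([self.residues[i] for i in rows], conf, self.name)

    def residue_indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca.coords for r in self.residues], dtype=float)

    @property
    def mean_confidence(self) -> float:
        if self.confidence is None:
            return float("nan")
        return float(np.mean(self.confidence))


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive 1-based residue ranges, e.g. the fold-switching region."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"range start {start} > end {end}")
            if prev_end is not None and start <= prev_end:
                raise ValueError("ranges must be sorted and non-overlapping")
            prev_end = end

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``"10-45,80-102"`` (a single residue may be given as ``"7"``)."""
        ranges = []
        for part in text.split(","):
            part = part.strip()
            if "-" in part:
                a, b = part.split("-")
                ranges.append((int(a), int(b)))
            else:
                ranges.append((int(part), int(part)))
        return cls(tuple(sorted(ranges)))

    def contains(self, indices: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(indices), dtype=bool)
        for start, end in self.ranges:
            mask |= (indices >= start) & (indices <= end)
        return mask

    def __str__(self) -> str:
        return ",".join(f"{a}-{b}" for a, b in self.ranges)


@dataclass(frozen=True)
class ContactMap:
    """Unordered residue-index pairs in contact, with provenance parameters."""

    pairs: frozenset
    cutoff: float
    min_sep: int

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pairs must satisfy i < j, got ({i}, {j})")
            if j - i < self.min_sep:
                raise ValueError(
                    f"pair ({i}, {j}) violates min separation {self.min_sep}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def read_pdb(path, keep_hetatm: bool = False) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    HETATM records are skipped by default.  Alternate locations keep the
    highest-occupancy conformer per atom name; ties break to the
    alphabetically first altloc id (so 'A' wins over 'B').  Residues lacking
    a CA atom are dropped with a warning.  B-factors of CA atoms are read as
    per-residue confidence.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    residues: list[Residue] = []
    confidence: list[float] = []
    for chain in st[0]:
        for res in chain:
            if res.het_flag == "H" and not keep_hetatm:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                cur = best.get(atom.name)
                if (
                    cur is None
                    or atom.occ > cur.occ
                    or (atom.occ == cur.occ and atom.altloc < cur.altloc)
                ):
                    best[atom.name] = atom
            atoms = [
                Atom(a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z))
                for a in best.values()
            ]
            r = Residue(res.seqid.num, res.name, chain.name, atoms)
            if r.ca is None:
                warnings.warn(
                    f"{path}: residue {chain.name}/{res.seqid.num} has no CA; dropped"
                )
                continue
            residues.append(r)
            confidence.append(best["CA"].b_iso)
    if not residues:
        raise ValueError(f"{path}: no polymer residues with CA atoms")
    return StructureModel(residues, np.array(confidence), name=str(path))


def write_pdb(model: StructureModel, path) -> None:
    """Write ATOM records; confidence (if any) goes to the B-factor column."""
    st = gemmi.Structure()
    st.name = model.name or "model"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for ridx, res in enumerate(model.residues):
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.index, " ")
        b = 0.0
        if model.confidence is not None:
            b = float(model.confidence[ridx])
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.xyz)
            ga.occ = 1.0
            ga.b_iso = b
            gr.add_atom(ga)
        chains[res.chain].add_residue(gr)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(coords_mobile: np.ndarray, coords_target: np.ndarray):
    """Least-squares rigid superposition of ``coords_mobile`` onto ``coords_target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_mobile @ rotation.T + translation`` best fits ``coords_target``.
    The rotation is proper (det = +1).
    """
    A = np.asarray(coords_mobile, dtype=float)
    B = np.asarray(coords_target, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if len(A) < 3:
        raise ValueError("need at least 3 points for superposition")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("coordinates must be finite")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# TM-score

def tm_d0_raw(l_ref: int) -> float:
    """The bare TM-score normalisation distance 1.24*(L-15)^(1/3) - 1.8 (Å)."""
    if l_ref <= 15:
        return 0.5
    return 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8


def tm_d0(l_ref: int, floor: float = 0.5) -> float:
    """d0 with the conventional small-length floor (0.5 Å)."""
    return max(tm_d0_raw(l_ref), floor)


def _seed_slices(L: int, full_sweep: bool):
    """Fragment windows used to seed the superposition search."""
    lengths = sorted({L, max(4, L // 2), max(4, L // 4)}, reverse=True)
    seeds = []
    for fl in lengths:
        step = max(1, fl // 2) if full_sweep else max(fl, 1)
        start = 0
        while start + fl <= L:
            seeds.append((start, start + fl))
            if start + fl == L:
                break
            start = min(start + step, L - fl)
    return seeds


def _refine_tm(x: np.ndarray, y: np.ndarray, mask: np.ndarray, d0: float,
               max_iter: int = 20) -> float:
    """Iteratively re-superpose on close residues; return the best TM sum/L."""
    L = len(y)
    best = 0.0
    d_cut0 = max(d0, 1.5)
    for _ in range(max_iter):
        if mask.sum() < 3:
            break
        R, t, _ = kabsch_superpose(x[mask], y[mask])
        d = np.linalg.norm(x @ R.T + t - y, axis=1)
        best = max(best, float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
        d_cut = d_cut0
        new = d < d_cut
        while new.sum() < min(4, L):
            d_cut += 0.5
            new = d < d_cut
        if np.array_equal(new, mask):
            break
        mask = new
    return best


def _shared_ca(model: StructureModel, reference: StructureModel,
               region: RegionSpec | None):
    """Positionally corresponding CA coordinates restricted to shared indices."""
    mi = model.residue_indices()
    ri = reference.residue_indices()
    shared = np.intersect1d(mi, ri)
    if region is not None:
        shared = shared[region.contains(shared)]
    mpos = {idx: k for k, idx in enumerate(mi)}
    rpos = {idx: k for k, idx in enumerate(ri)}
    mca = model.ca_coords()
    rca = reference.ca_coords()
    x = np.array([mca[mpos[i]] for i in shared])
    y = np.array([rca[rpos[i]] for i in shared])
    return x, y, shared


def tm_score(model: StructureModel, reference: StructureModel,
             region: RegionSpec | None = None,
             superpose_scope: str = "region") -> float:
    """TM-score of ``model`` against ``reference``, normalised by reference length.

    Correspondence is positional by residue index.  With a ``region``, the
    score covers the region's residues only; ``superpose_scope='region'``
    (default) also restricts the superposition search to the region, while
    ``'global'`` searches superpositions over all shared residues and scores
    the region under the best global transform.
    """
    if superpose_scope not in ("region", "global"):
        raise ValueError("superpose_scope must be 'region' or 'global'")
    x, y, shared = _shared_ca(model, reference, region)
    if len(shared) < 3:
        raise ValueError("fewer than 3 corresponding residues in scored region")
    d0 = tm_d0(len(y))

    if region is None or superpose_scope == "region":
        L = len(y)
        best = 0.0
        for a, b in _seed_slices(L, full_sweep=True):
            mask = np.zeros(L, dtype=bool)
            mask[a:b] = True
            best = max(best, _refine_tm(x, y, mask, d0))
        return best

    # global superposition, region-restricted scoring
    xg, yg, shared_g = _shared_ca(model, reference, None)
    in_region = region.contains(shared_g)
    Lg = len(yg)
    d0_global = tm_d0(Lg)
    best = 0.0
    for a, b in _seed_slices(Lg, full_sweep=True):
        mask = np.zeros(Lg, dtype=bool)
        mask[a:b] = True
        # refine under the global objective, score the region residues
        m = mask
        for _ in range(20):
            if m.sum() < 3:
                break
            R, t, _ = kabsch_superpose(xg[m], yg[m])
            d = np.linalg.norm(xg @ R.T + t - yg, axis=1)
            score = float(np.mean(
                1.0 / (1.0 + (d[in_region] / d0) ** 2)))
            best = max(best, score)
            d_cut = max(d0_global, 1.5)
            new = d < d_cut
            while new.sum() < min(4, Lg):
                d_cut += 0.5
                new = d < d_cut
            if np.array_equal(new, m):
                break
            m = new
    return best


# ---------------------------------------------------------------------------
# lDDT

def lddt(model: StructureModel, reference: StructureModel,
         inclusion_radius: float = 15.0,
         thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
         min_sep: int = 2) -> float:
    """Superposition-free local distance difference test on CA atoms.

    Qualifying pairs are reference CA pairs within ``inclusion_radius`` and
    sequence separation >= ``min_sep``; the score is the fraction of pairs
    whose distance is preserved within each threshold, averaged over
    thresholds.
    """
    x, y, shared = _shared_ca(model, reference, None)
    n = len(shared)
    if n < 2:
        raise ValueError("need at least 2 corresponding residues")
    dref = np.linalg.norm(y[:, None, :] - y[None, :, :], axis=-1)
    dmod = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    sep = np.abs(shared[:, None] - shared[None, :])
    iu = np.triu_indices(n, 1)
    qual = (dref[iu] < inclusion_radius) & (sep[iu] >= min_sep)
    if qual.sum() < 2:
        raise ValueError("fewer than 2 qualifying pairs for lDDT")
    diff = np.abs(dmod[iu][qual] - dref[iu][qual])
    fractions = [float(np.mean(diff < t)) for t in thresholds]
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# contacts

def _heavy_atom_table(model: StructureModel, heavy_atoms: bool):
    coords, res_ids = [], []
    for r in model.residues:
        for a in r.atoms:
            if heavy_atoms and a.is_hydrogen:
                continue
            if not heavy_atoms and a.name != "CA":
                continue
            coords.append(a.xyz)
            res_ids.append(r.index)
    return np.asarray(coords, dtype=float), np.asarray(res_ids, dtype=int)


def contact_map(model: StructureModel, cutoff: float = 8.0, min_sep: int = 1,
                heavy_atoms: bool = True) -> ContactMap:
    """Residue contacts: (i, j) iff any heavy-atom pair is within ``cutoff`` Å."""
    from scipy.spatial import cKDTree

    coords, res_ids = _heavy_atom_table(model, heavy_atoms)
    tree = cKDTree(coords)
    pairs = set()
    for a, b in tree.query_pairs(cutoff):
        i, j = res_ids[a], res_ids[b]
        if i == j:
            continue
        lo, hi = (i, j) if i < j else (j, i)
        if hi - lo >= min_sep:
            pairs.add((int(lo), int(hi)))
    return ContactMap(frozenset(pairs), cutoff, min_sep)


def interchain_contacts(assembly: StructureModel, cutoff: float = 8.0,
                        heavy_atoms: bool = True) -> ContactMap:
    """Contacts between chain 1 and any other chain, in chain-1 residue indexing.

    Used to test whether contacts unique to a predicted alternative
    conformation coincide with a homolog's oligomeric interface.
    """
    from scipy.spatial import cKDTree

    chains = assembly.chain_ids
    if len(chains) < 2:
        raise ValueError("interchain contacts require at least 2 chains")
    c1, r1 = _heavy_atom_table(assembly.chain(chains[0]), heavy_atoms)
    tree1 = cKDTree(c1)
    pairs = set()
    for cid in chains[1:]:
        c2, r2 = _heavy_atom_table(assembly.chain(cid), heavy_atoms)
        tree2 = cKDTree(c2)
        for a, bs in enumerate(tree1.query_ball_tree(tree2, cutoff)):
            for b in bs:
                i, j = int(r1[a]), int(r2[b])
                if i == j:
                    continue
                pairs.add((min(i, j), max(i, j)))
    return ContactMap(frozenset(pairs), cutoff, 0)


# ---------------------------------------------------------------------------
# secondary structure (Kabsch-Sander style, collapsed to 3 states)

_HB_ENERGY_CUTOFF = -0.5   # kcal/mol
_HB_Q1Q2F = 0.084 * 332.0


def _backbone_arrays(model: StructureModel):
    L = len(model)
    names = ("N", "CA", "C", "O")
    coords = {n: np.full((L, 3), np.nan) for n in names}
    ok = np.ones(L, dtype=bool)
    for k, res in enumerate(model.residues):
        for n in names:
            a = res.atom(n)
            if a is not None:
                coords[n][k] = a.xyz
        if np.isnan(coords["N"][k]).any() or np.isnan(coords["CA"][k]).any() \
                or np.isnan(coords["C"][k]).any():
            ok[k] = False
            continue
        if np.isnan(coords["O"][k]).any():
            # reconstruct carbonyl O in the peptide plane, opposite next N
            c, ca = coords["C"][k], coords["CA"][k]
            if k + 1 < L:
                nn = coords["N"][k + 1]
                if np.isnan(nn).any():
                    ok[k] = False
                    continue
                direction = (c - ca) / np.linalg.norm(c - ca) \
                    + (c - nn) / np.linalg.norm(c - nn)
            else:
                direction = c - ca
            coords["O"][k] = c + 1.23 * direction / np.linalg.norm(direction)
    return coords, ok


def _ks_hbond_matrix(coords, ok, chain_break):
    """bond[i, j]: CO of residue i accepts an H-bond from NH of residue j."""
    L = len(ok)
    N, C, O = coords["N"], coords["C"], coords["O"]
    # amide H: 1.0 Å from N, anti-parallel to the preceding carbonyl
    H = N.copy()
    has_h = np.zeros(L, dtype=bool)
    for j in range(1, L):
        if ok[j] and ok[j - 1] and not chain_break[j]:
            v = C[j - 1] - O[j - 1]
            H[j] = N[j] + v / np.linalg.norm(v)
            has_h[j] = True

    def dist(P, Q):
        return np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        E = _HB_Q1Q2F * (1.0 / dist(O, N) + 1.0 / dist(C, H)
                         - 1.0 / dist(O, H) - 1.0 / dist(C, N))
    bond = E < _HB_ENERGY_CUTOFF
    bond &= ok[:, None] & ok[None, :] & has_h[None, :]
    idx = np.arange(L)
    bond &= np.abs(idx[:, None] - idx[None, :]) >= 2
    return bond


def secondary_structure(model: StructureModel) -> list[str]:
    """Per-residue 3-state assignment in {'H', 'E', 'C'}.

    Hydrogen bonds follow the Kabsch-Sander electrostatic criterion
    (E < -0.5 kcal/mol); helices come from consecutive i -> i+4 bond turns,
    strands from parallel/antiparallel bridge ladder patterns, and everything
    else (including residues with incomplete backbones) is coil.
    """
    L = len(model)
    coords, ok = _backbone_arrays(model)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} residue(s) with incomplete backbone labeled coil")
    chains = np.array([r.chain for r in model.residues])
    chain_break = np.zeros(L, dtype=bool)
    chain_break[1:] = chains[1:] != chains[:-1]

    bond = _ks_hbond_matrix(coords, ok, chain_break)
    labels = np.full(L, "C", dtype="<U1")

    # helices (3-10, alpha, pi all collapse to H): an n-turn at i is a bond
    # CO(i) -> NH(i+n); two consecutive n-turns make residues i+1..i+n helical
    for n in (4, 3, 5):
        turn = np.zeros(L, dtype=bool)
        for i in range(L - n):
            if bond[i, i + n] and chains[i] == chains[i + n]:
                turn[i] = True
        for i in range(L - n - 1):
            if turn[i] and turn[i + 1]:
                labels[i + 1:i + n + 1] = "H"

    # beta bridges
    is_bridge = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            parallel = (bond[i - 1, j] and bond[j, i + 1]) or \
                       (bond[j - 1, i] and bond[i, j + 1])
            anti = (bond[i, j] and bond[j, i]) or \
                   (bond[i - 1, j + 1] and bond[j - 1, i + 1])
            if parallel or anti:
                is_bridge[i] = is_bridge[j] = True
    labels[is_bridge & (labels != "H")] = "E"
    labels[~ok] = "C"
    return labels.tolist()


# ---------------------------------------------------------------------------
# batched pairwise scores for similarity matrices

def _batched_kabsch_rotations(X, Y, w):
    """Weighted rotations aligning each X[p] onto Y[p]; w is (P, L) weights."""
    wsum = w.sum(axis=1, keepdims=True)
    cx = (w[..., None] * X).sum(axis=1, keepdims=True) / wsum[..., None]
    cy = (w[..., None] * Y).sum(axis=1, keepdims=True) / wsum[..., None]
    Xc, Yc = X - cx, Y - cy
    Hm = np.einsum("pl,pli,plj->pij", w, Xc, Yc)
    U, _, Vt = np.linalg.svd(Hm)
    det = np.linalg.det(np.einsum("pij,pjk->pik", Vt.transpose(0, 2, 1),
                                  U.transpose(0, 2, 1)))
    D = np.repeat(np.eye(3)[None], len(X), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("pij,pjk,pkl->pil", Vt.transpose(0, 2, 1), D,
                  U.transpose(0, 2, 1))
    t = cy[:, 0, :] - np.einsum("pij,pj->pi", R, cx[:, 0, :])
    return R, t


def pairwise_tm_matrix(coords: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """All-against-all TM-scores for same-length, same-sequence models.

    ``coords`` is (n, L, 3) CA coordinates with positional correspondence.
    Uses the same iterative close-residue refinement as :func:`tm_score`
    with a reduced seed set (full chain, halves, quarters, no sliding),
    batched over all pairs.  Symmetric with unit diagonal (both
    normalisation directions coincide at equal length).
    """
    coords = np.asarray(coords, dtype=float)
    n, L, _ = coords.shape
    d0 = tm_d0(L)
    ii, jj = np.triu_indices(n, 1)
    X, Y = coords[ii], coords[jj]
    P = len(ii)
    best = np.zeros(P)
    half, quarter = max(4, L // 2), max(4, L // 4)
    seed_windows = {(0, L), (0, half), (L - half, L),
                    (0, quarter), (L - quarter, L)}
    d_cut0 = max(d0, 1.5)
    for a, b in seed_windows:
        active = np.arange(P)
        w = np.zeros((P, L))
        w[:, a:b] = 1.0
        for _ in range(n_iter):
            if len(active) == 0:
                break
            R, t = _batched_kabsch_rotations(X[active], Y[active], w[active])
            Xt = np.einsum("pij,plj->pli", R, X[active]) + t[:, None, :]
            d = np.linalg.norm(Xt - Y[active], axis=-1)
            best[active] = np.maximum(
                best[active], np.mean(1.0 / (1.0 + (d / d0) ** 2), axis=1))
            new = d < d_cut0
            # grow the cutoff for pairs with too few retained residues
            short = new.sum(axis=1) < min(4, L)
            cut = d_cut0
            while short.any():
                cut += 0.5
                new[short] = d[short] < cut
                short = new.sum(axis=1) < min(4, L)
            converged = (new == (w[active] > 0)).all(axis=1)
            w[active] = new.astype(float)
            active = active[~converged]
    S = np.eye(n)
    S[ii, jj] = best
    S[jj, ii] = best
    return S


def pairwise_lddt_matrix(coords: np.ndarray, inclusion_radius: float = 15.0,
                         thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
                         min_sep: int = 2, chunk: int = 2048) -> np.ndarray:
    """All-against-all symmetrised CA lDDT (average of both reference choices)."""
    coords = np.asarray(coords, dtype=float)
    n, L, _ = coords.shape
    D = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
    iu = np.triu_indices(L, 1)
    sep_ok = (iu[1] - iu[0]) >= min_sep
    Dp = D[:, iu[0], iu[1]][:, sep_ok]          # (n, n_pairs)
    thr = np.asarray(thresholds)
    S = np.eye(n)
    ii, jj = np.triu_indices(n, 1)
    for s in range(0, len(ii), chunk):
        a, b = ii[s:s + chunk], jj[s:s + chunk]
        da, db = Dp[a], Dp[b]
        diff = np.abs(da - db)[None, :, :] < thr[:, None, None]  # (T, P, pairs)
        vals = np.empty(len(a))
        for k in range(len(a)):
            qa = db[k] < inclusion_radius   # reference = b
            qb = da[k] < inclusion_radius   # reference = a
            la = diff[:, k, qa].mean(axis=1).mean() if qa.any() else 0.0
            lb = diff[:, k, qb].mean(axis=1).mean() if qb.any() else 0.0
            vals[k] = 0.5 * (la + lb)
        S[a, b] = vals
        S[b, a] = vals
    return S
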