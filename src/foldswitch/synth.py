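"""Synthetic desk-scale fixtures: ideal backbones, two-state ensembles, MSAs.

Structures are built by sequential internal-coordinate placement from ideal
bond geometry (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å) and canonical
dihedrals (helix phi/psi = -57/-47; strand -139/135).  Two-state ensembles
emulate a prediction run on a fold switcher: a dominant fold produced at the
deep sampling depth, an alternative fold plus unfolded decoys at shallow
depths, with ground-truth labels returned for assertions.  Decoys are
random-coil chains (not merely noisy folds) so composition filters have
unambiguous truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import (DEFAULT_SHALLOW, DepthPair, Msa, PredictionJob, SamplingPlan,
                  build_sampling_plan)
from .structure import Atom, Residue, StructureModel

__all__ = [
    "EnsembleSpec",
    "TwoStateEnsemble",
    "make_backbone",
    "perturb",
    "perturb_smooth",
    "make_two_state_ensemble",
    "make_synthetic_msa",
]

# ideal backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}
# 4-residue turn linking the two hairpin strands; dihedrals chosen so the
# flanking ideal strands pair antiparallel with Kabsch-Sander H-bonds
_TURN_PHIPSI = [(156.0, 177.0), (38.0, -124.0), (-78.0, -20.0), (139.0, 149.0)]
# 4-residue loop reversing the chain so two ideal helices pack antiparallel
# at ~10 Å without clashes
_HELIX_TURN_PHIPSI = [(144.7, 27.6), (-128.4, 44.8), (-6.2, -69.4), (65.0, 49.2)]
# 12-residue loop (polyproline-II flanks around the reversing hinge) for a
# helix-loop-helix fold whose helix content (~0.75) sits well below a
# straight helix (~0.96) but far above random coil
_HELIX_LOOP_PHIPSI = ([(-75.0, 145.0)] * 4 + _HELIX_TURN_PHIPSI
                      + [(-75.0, 145.0)] * 4)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _place_atom(p1, p2, p3, length, angle_deg, dihedral_deg) -> np.ndarray:
    """NeRF placement: new atom bonded to p3 with angle p2-p3-x, dihedral p1-p2-p3-x."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(dih),
        length * np.sin(ang) * np.sin(dih),
    ])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _build_chain(phi_psi: list[tuple[float, float]], chain: str = "A",
                 start_index: int = 1) -> StructureModel:
    """Build an all-backbone (N, CA, C, O) chain from a phi/psi list."""
    L = len(phi_psi)
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # first residue in a standard frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, L):
        psi_prev = phi_psi[i - 1][1]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N,
                           _A_CA_C_N, psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA,
                            _A_C_N_CA, 180.0)      # omega trans
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C,
                           _A_N_CA_C, phi_psi[i][0])
    residues = []
    for i in range(L):
        psi = phi_psi[i][1]
        O = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms = [
            Atom("N", "N", tuple(N[i])),
            Atom("CA", "C", tuple(CA[i])),
            Atom("C", "C", tuple(C[i])),
            Atom("O", "O", tuple(O)),
        ]
        residues.append(Residue(start_index + i, "ALA", chain, atoms))
    return StructureModel(residues)


def _coil_phi_psi(length: int, rng: np.random.Generator,
                  max_tries: int = 200) -> list[tuple[float, float]]:
    """Random dihedrals rejected until the CA trace is self-avoiding."""
    for _ in range(max_tries):
        phi = rng.uniform(-180.0, 180.0, size=length)
        psi = rng.uniform(-180.0, 180.0, size=length)
        pp = list(zip(phi.tolist(), psi.tolist()))
        ca = _build_chain(pp).ca_coords()
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        sep = np.abs(np.arange(length)[:, None] - np.arange(length)[None, :])
        if d[sep > 1].min() > 3.0:
            return pp
    return pp  # last attempt; near-clashes acceptable for a decoy


def make_backbone(kind: str, length: int, seed: int = 0) -> StructureModel:
    """Ideal-geometry backbone of a given secondary-structure archetype.

    ``kind``: ``helix`` | ``strand`` | ``hairpin`` (two antiparallel strands
    joined by a 4-residue turn) | ``helix_hairpin`` (two antiparallel packed
    helices, tight hinge) | ``helix_loop_helix`` (two helices around a
    12-residue loop) | ``coil`` (self-avoiding random dihedrals, seeded).
    """
    if length < 4:
        raise ValueError("length must be >= 4")
    if kind in ("helix", "strand"):
        pp = [_DIHEDRALS[kind]] * length
    elif kind in ("hairpin", "helix_hairpin", "helix_loop_helix"):
        turn = {"hairpin": _TURN_PHIPSI,
                "helix_hairpin": _HELIX_TURN_PHIPSI,
                "helix_loop_helix": _HELIX_LOOP_PHIPSI}[kind]
        arm = _DIHEDRALS["strand" if kind == "hairpin" else "helix"]
        n_turn = len(turn)
        if length < n_turn + 4:
            raise ValueError(f"{kind} needs length >= {n_turn + 4}")
        n_strand = (length - n_turn) // 2
        extra = length - n_turn - 2 * n_strand
        pp = [arm] * (n_strand + extra) + list(turn) + [arm] * n_strand
    elif kind == "coil":
        pp = _coil_phi_psi(length, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown backbone kind {kind!r}")
    return _build_chain(pp)


def perturb(model: StructureModel, sd: float, seed: int) -> StructureModel:
    """Add iid zero-mean Gaussian noise (sd Å per coordinate) to every atom."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []
    for res in model.residues:
        atoms = [
            Atom(a.name, a.element, tuple(a.coords + rng.normal(0.0, sd, 3)))
            for a in res.atoms
        ]
        residues.append(Residue(res.index, res.name, res.chain, atoms))
    conf = None if model.confidence is None else model.confidence.copy()
    return StructureModel(residues, conf, model.name)


def perturb_smooth(model: StructureModel, sd: float, seed: int,
                   corr_len: float = 4.0) -> StructureModel:
    """Chain-correlated Gaussian displacement (sd Å per coordinate).

    Residues displace coherently: an iid Gaussian field over residue index
    is smoothed with a Gaussian kernel of width ``corr_len`` residues and
    rescaled to per-coordinate sd, then applied rigidly to each residue's
    atoms.  This emulates the collective-motion variability of predicted
    ensembles — global RMSD grows with sd while local covalent geometry and
    hydrogen bonds stay realistic, unlike iid per-atom noise, which shreds
    secondary structure well before reaching comparable global deviation.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    L = len(model.residues)
    field = rng.normal(0.0, 1.0, size=(L, 3))
    if sd > 0:
        field = gaussian_filter1d(field, corr_len, axis=0, mode="nearest")
        scale = field.std()
        field = field / (scale if scale > 0 else 1.0) * sd
    else:
        field = np.zeros((L, 3))
    residues = []
    for k, res in enumerate(model.residues):
        atoms = [Atom(a.name, a.element, tuple(a.coords + field[k]))
                 for a in res.atoms]
        residues.append(Residue(res.index, res.name, res.chain, atoms))
    conf = None if model.confidence is None else model.confidence.copy()
    return StructureModel(residues, conf, model.name)


# ---------------------------------------------------------------------------
# two-state ensembles

@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a synthetic two-state prediction ensemble."""

    n_members: int = 200
    fraction_state_a: float = 0.6
    fraction_decoy: float = 0.1
    noise_sd: float = 0.3
    length: int = 60
    seed: int = 0
    alt_depth: DepthPair = DepthPair(2, 4)

    def __post_init__(self) -> None:
        if self.n_members < 4:
            raise ValueError("n_members must be >= 4")
        if not (0.0 <= self.fraction_state_a <= 1.0
                and 0.0 <= self.fraction_decoy <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_state_a + self.fraction_decoy > 1.0:
            raise ValueError("fractions must sum to <= 1")


@dataclass
class TwoStateEnsemble:
    """Generated ensemble with provenance and ground-truth labels."""

    models: list
    jobs: list
    labels: list          # per member: "A", "B", or "decoy"
    backbone_a: StructureModel
    backbone_b: StructureModel
    spec: EnsembleSpec

    def __len__(self) -> int:
        return len(self.models)


def _class_counts(spec: EnsembleSpec) -> tuple[int, int, int]:
    n = spec.n_members
    n_a = round(n * spec.fraction_state_a)
    n_decoy = round(n * spec.fraction_decoy)
    # every class with positive fraction keeps at least one member
    if spec.fraction_state_a > 0:
        n_a = max(1, n_a)
    if spec.fraction_decoy > 0:
        n_decoy = max(1, n_decoy)
    n_b = n - n_a - n_decoy
    if spec.fraction_state_a + spec.fraction_decoy < 1.0 and n_b < 1:
        n_b = 1
        n_a = n - n_decoy - n_b
    return n_a, n_b, n - n_a - n_b


def make_two_state_ensemble(spec: EnsembleSpec,
                            plan: SamplingPlan | None = None) -> TwoStateEnsemble:
    """Emulate a fold-switcher prediction run with known labels.

    State A (dominant) is a straight helix, state B (alternative) a helix-
    loop-helix — both well folded with distinct secondary-structure content
    (~0.96 vs ~0.75 helix fraction) and low mutual TM-score (~0.45 at
    length 60); decoys are random coils.  Deep-depth provenance goes to
    state-A
    members first — mirroring the expectation that full-depth sampling
    produces the dominant conformation — and state-B members are pinned to
    ``spec.alt_depth``.  Folded members get confidence > 80, decoys < 50.
    """
    n_a, n_b, n_decoy = _class_counts(spec)
    rng = np.random.default_rng(spec.seed)
    bb_a = make_backbone("helix", spec.length)
    bb_b = make_backbone("helix_loop_helix", spec.length)
    if plan is None:
        plan = build_sampling_plan()
    jobs_pool = list(plan)
    deep_jobs = [j for j in jobs_pool if j.depth == jobs_pool[0].depth]
    alt_jobs = [j for j in jobs_pool if j.depth == spec.alt_depth]
    other_jobs = [j for j in jobs_pool
                  if j not in deep_jobs and j not in alt_jobs]

    def draw_jobs(pool, fallback, k):
        out = []
        for i in range(k):
            if pool:
                out.append(pool.pop(0))
            elif fallback:
                out.append(fallback.pop(0))
            else:  # plan exhausted: extend the seed range deterministically
                base = out[-1] if out else jobs_pool[-1]
                out.append(PredictionJob(base.depth, base.model_index,
                                         base.seed + 1000 + i))
        return out

    jobs_a = draw_jobs(deep_jobs, other_jobs, n_a)
    jobs_b = draw_jobs(alt_jobs, other_jobs, n_b)
    jobs_d = draw_jobs(other_jobs, deep_jobs + alt_jobs, n_decoy)

    models, jobs, labels = [], [], []
    for label, job_list, template in (
        ("A", jobs_a, bb_a), ("B", jobs_b, bb_b), ("decoy", jobs_d, None),
    ):
        for job in job_list:
            member_seed = int(rng.integers(0, 2 ** 31))
            if template is None:
                m = make_backbone("coil", spec.length, seed=member_seed)
                conf = rng.uniform(20.0, 45.0, size=len(m))
            else:
                m = perturb_smooth(template, spec.noise_sd, member_seed)
                conf = rng.uniform(82.0, 95.0, size=len(m))
            m.confidence = np.asarray(conf)
            m.name = str(job)
            models.append(m)
            jobs.append(job)
            labels.append(label)
    return TwoStateEnsemble(models, jobs, labels, bb_a, bb_b, spec)


# ---------------------------------------------------------------------------
# synthetic MSAs

def make_synthetic_msa(query_length: int, n_rows: int, mutation_rate: float,
                       seed: int = 0) -> Msa:
    """Random query plus point-mutated homolog rows at the stated rate."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA20))
    query = aa[rng.integers(0, len(aa), size=query_length)]
    rows = [("query", "".join(query))]
    for k in range(1, n_rows):
        seq = query.copy()
        mutate = rng.random(query_length) < mutation_rate
        seq[mutate] = aa[rng.integers(0, len(aa), size=int(mutate.sum()))]
        rows.append((f"hom{k}", "".join(seq)))
    return Msa(rows)
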