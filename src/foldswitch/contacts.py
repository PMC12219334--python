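"""Contact classification between two conformations and coevolution overlay.

Heavy-atom contact maps of the dominant and alternative conformations are
partitioned into common, dominant-unique and alternative-unique classes;
class counts are normalised by their total so proteins of different sizes
compare evenly.  An externally computed residue-residue coupling matrix
(e.g. from an MSA transformer) can be overlaid on the classes to ask which
conformation the evolutionary signal supports.  The interchain-
misassignment check flags predicted alternative conformations whose unique
contacts coincide with a close homolog's oligomeric interface — such
predictions likely misassign interchain contacts as intrachain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import ContactMap, StructureModel, interchain_contacts

__all__ = [
    "ContactClasses",
    "CouplingMatrix",
    "classify_contacts",
    "normalized_intensities",
    "read_coupling_matrix",
    "coupling_class_strength",
    "interchain_misassignment_check",
    "contact_classes_matrix",
]


@dataclass(frozen=True)
class ContactClasses:
    """Disjoint partition of two conformations' contacts."""

    common: ContactMap
    dominant_unique: ContactMap
    alternative_unique: ContactMap

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.common), len(self.dominant_unique),
                len(self.alternative_unique))

    @property
    def total(self) -> int:
        return sum(self.counts)


def classify_contacts(map_dominant: ContactMap,
                      map_alternative: ContactMap) -> ContactClasses:
    """Split contacts into common / dominant-unique / alternative-unique."""
    if map_dominant.cutoff != map_alternative.cutoff \
            or map_dominant.min_sep != map_alternative.min_sep:
        raise ValueError(
            "contact maps must share cutoff and min separation to be compared")
    d, a = map_dominant.pairs, map_alternative.pairs
    mk = lambda s: ContactMap(frozenset(s), map_dominant.cutoff,
                              map_dominant.min_sep)
    return ContactClasses(mk(d & a), mk(d - a), mk(a - d))


def normalized_intensities(classes: ContactClasses) -> tuple[float, float, float]:
    """(common, dominant, alternative) counts as fractions of their total."""
    total = classes.total
    if total == 0:
        raise ValueError("no contacts in either conformation")
    c, d, a = classes.counts
    return (c / total, d / total, a / total)


# ---------------------------------------------------------------------------
# coupling overlay

@dataclass
class CouplingMatrix:
    """Symmetric residue-residue coupling scores; diagonal ignored."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("coupling matrix must be symmetric")
        self.scores = s

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def read_coupling_matrix(path, n: int | None = None) -> CouplingMatrix:
    """Read couplings from a square whitespace matrix or (i, j, score) triples.

    Triples use 1-based residue indices; ``n`` fixes the matrix size when it
    cannot be inferred from the largest index.
    """
    data = np.loadtxt(path, ndmin=2)
    if data.shape[0] == data.shape[1] and (n is None or data.shape[0] == n):
        return CouplingMatrix(0.5 * (data + data.T))
    if data.shape[1] != 3:
        raise ValueError(
            f"{path}: expected a square matrix or 3-column triples, "
            f"got shape {data.shape}")
    size = n or int(data[:, :2].max())
    s = np.zeros((size, size))
    for i, j, v in data:
        s[int(i) - 1, int(j) - 1] = v
        s[int(j) - 1, int(i) - 1] = v
    return CouplingMatrix(s)


def coupling_class_strength(couplings: CouplingMatrix,
                            classes: ContactClasses,
                            top_k: int | None = None,
                            min_sep: int = 6) -> dict:
    """Share of top-coupling score falling on each contact class.

    The strongest ``top_k`` couplings (default 2L, the conventional contact-
    prediction budget; pairs with i < j and separation >= ``min_sep``) are
    summed per class, and each class's share of the three-class total is
    reported — the quantity behind "couplings unique to unpredicted dominant
    conformations are stronger than those unique to predicted alternatives".
    """
    L = couplings.n
    if top_k is None:
        top_k = 2 * L
    iu = np.triu_indices(L, min_sep)
    pairs = list(zip(iu[0] + 1, iu[1] + 1))   # 1-based
    scores = couplings.scores[iu]
    if top_k > len(pairs):
        warnings.warn(
            f"top_k={top_k} exceeds {len(pairs)} available pairs; using all")
        top_k = len(pairs)
    # sort by descending score, ties toward the lexicographically first pair
    order = sorted(range(len(pairs)), key=lambda k: (-scores[k], pairs[k]))
    take = order[:top_k]
    sums = {"common": 0.0, "dominant": 0.0, "alternative": 0.0}
    for k in take:
        p = (int(pairs[k][0]), int(pairs[k][1]))
        if p in classes.common:
            sums["common"] += float(scores[k])
        elif p in classes.dominant_unique:
            sums["dominant"] += float(scores[k])
        elif p in classes.alternative_unique:
            sums["alternative"] += float(scores[k])
    total = sum(sums.values())
    if total == 0:
        warnings.warn("no top coupling falls on any contact class")
        return {k: 0.0 for k in sums}
    return {k: v / total for k, v in sums.items()}


# ---------------------------------------------------------------------------
# interchain misassignment quality check

def interchain_misassignment_check(alt_unique: ContactMap,
                                   homolog_assembly: StructureModel,
                                   identity: float,
                                   overlap_threshold: float = 0.25) -> dict:
    """Discard rule for spurious alternative conformations.

    If a close homolog (sequence identity >= 0.70) forms an oligomer whose
    interchain contacts overlap the contacts unique to the predicted
    alternative conformation, the prediction is presumed to misassign
    interchain contacts as intrachain.  ``overlap_threshold`` sets how much
    overlap (fraction of alternative-unique contacts) triggers the discard;
    0 gives a strict any-overlap rule.
    """
    if len(alt_unique) == 0:
        return {"flag": "keep", "overlap_fraction": 0.0}
    inter = interchain_contacts(homolog_assembly, cutoff=alt_unique.cutoff)
    overlap = len(alt_unique.pairs & inter.pairs) / len(alt_unique)
    discard = identity >= 0.70 and overlap > overlap_threshold
    return {"flag": "discard" if discard else "keep",
            "overlap_fraction": overlap}


# ---------------------------------------------------------------------------
# export

def contact_classes_matrix(classes: ContactClasses, n_residues: int) -> np.ndarray:
    """Two-triangle integer matrix presentation of the classes.

    Upper triangle marks dominant-side contacts, lower triangle alternative-
    side; 1 = common (mirrored into both triangles), 2 = unique to that side.
    """
    M = np.zeros((n_residues, n_residues), dtype=int)
    for i, j in classes.common.pairs:
        M[i - 1, j - 1] = 1
        M[j - 1, i - 1] = 1
    for i, j in classes.dominant_unique.pairs:
        M[i - 1, j - 1] = 2
    for i, j in classes.alternative_unique.pairs:
        M[j - 1, i - 1] = 2
    return M
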