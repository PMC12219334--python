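"""Default-mode evaluation against two reference conformations.

Every ensemble member is scored by TM-score against both experimental
references, globally and over the fold-switching region.  A run counts as a
success when some prediction matches reference 1 with TM >= threshold while
beating its score to reference 2, and vice versa for another prediction
(the dual-fold criterion, default threshold 0.6).  Region scores drive the
verdict by default because region-restricted TM-score discriminates fold
switchers better than the overall score; global scores are reported
alongside and can be selected instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import DEFAULT_DEEP, DepthPair
from .structure import RegionSpec, StructureModel, tm_score

__all__ = [
    "ScoreTable",
    "SuccessVerdict",
    "score_ensemble",
    "dual_fold_success",
    "assign_dominant",
    "depth_of_alternative",
    "folding_energy_difference",
]

#: column order of a score table
SCORE_COLUMNS = ["depth", "model", "seed", "tm1_global", "tm2_global",
                 "tm1_region", "tm2_region", "mean_plddt"]

ScoreTable = pd.DataFrame  # one row per ensemble member; SCORE_COLUMNS


@dataclass(frozen=True)
class SuccessVerdict:
    success: bool
    best_for_ref1: dict | None
    best_for_ref2: dict | None
    threshold: float
    use_region: bool


def score_ensemble(results, ref1: StructureModel, ref2: StructureModel,
                   region: RegionSpec | None = None,
                   superpose_scope: str = "region") -> ScoreTable:
    """TM-score every prediction against both references.

    ``results`` is an iterable of prediction results (objects with ``model``
    and ``job``).  Without a ``region`` the region columns duplicate the
    global columns.
    """
    results = list(results)
    if not results:
        raise ValueError("empty ensemble")
    rows = []
    for r in results:
        t1g = tm_score(r.model, ref1)
        t2g = tm_score(r.model, ref2)
        if region is None:
            t1r, t2r = t1g, t2g
        else:
            t1r = tm_score(r.model, ref1, region, superpose_scope)
            t2r = tm_score(r.model, ref2, region, superpose_scope)
        rows.append({
            "depth": r.job.depth,
            "model": r.job.model_index,
            "seed": r.job.seed,
            "tm1_global": t1g,
            "tm2_global": t2g,
            "tm1_region": t1r,
            "tm2_region": t2r,
            "mean_plddt": r.model.mean_confidence,
        })
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def _tm_columns(use_region: bool) -> tuple[str, str]:
    return ("tm1_region", "tm2_region") if use_region \
        else ("tm1_global", "tm2_global")


def dual_fold_success(table: ScoreTable, threshold: float = 0.6,
                      use_region: bool = True) -> SuccessVerdict:
    """Apply the dual-fold success criterion to a score table.

    Success iff some row has TM1 >= threshold with TM1 > TM2, and some row
    has TM2 >= threshold with TM2 > TM1.  ``best_for_refK`` maximises TMK
    among qualifying rows.  The threshold may be lowered per protein to
    absorb variability in disordered regions.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    c1, c2 = _tm_columns(use_region)
    q1 = table[(table[c1] >= threshold) & (table[c1] > table[c2])]
    q2 = table[(table[c2] >= threshold) & (table[c2] > table[c1])]
    best1 = q1.loc[q1[c1].idxmax()].to_dict() if len(q1) else None
    best2 = q2.loc[q2[c2].idxmax()].to_dict() if len(q2) else None
    return SuccessVerdict(
        success=best1 is not None and best2 is not None,
        best_for_ref1=best1, best_for_ref2=best2,
        threshold=threshold, use_region=use_region,
    )


def assign_dominant(table: ScoreTable, deep_depth: DepthPair = DEFAULT_DEEP,
                    use_region: bool = True,
                    override: str | None = None) -> dict:
    """Call the dominant conformation from deep-depth rows by majority vote.

    Each deep row votes for the reference it scores higher; ties in the vote
    break toward ref1 with a warning.  ``override`` ("ref1" or "ref2")
    forces the call for proteins where memorisation is known to overrule
    coevolutionary inference.
    """
    if override is not None:
        if override not in ("ref1", "ref2"):
            raise ValueError("override must be 'ref1' or 'ref2'")
        dom = override
        return {"dominant": dom, "alternative": "ref2" if dom == "ref1" else "ref1"}
    deep = table[table["depth"].map(lambda d: d == deep_depth)]
    if len(deep) == 0:
        raise ValueError("no deep-depth rows to vote on")
    c1, c2 = _tm_columns(use_region)
    votes1 = int((deep[c1] > deep[c2]).sum())
    votes2 = int((deep[c2] > deep[c1]).sum())
    if votes1 == votes2:
        warnings.warn("deep-depth vote tied; dominant defaults to ref1")
    dom = "ref1" if votes1 >= votes2 else "ref2"
    return {"dominant": dom, "alternative": "ref2" if dom == "ref1" else "ref1"}


def depth_of_alternative(table: ScoreTable, verdict: SuccessVerdict,
                         alternative: str = "ref2"):
    """Sampling depth of the best alternative-conformation prediction.

    Feeds the headline summary of how shallow alternative conformations are
    found (e.g. the fraction of successes at depths <= 4:8).
    """
    if not verdict.success:
        raise ValueError("no alternative depth: the verdict is a failure")
    best = verdict.best_for_ref2 if alternative == "ref2" else verdict.best_for_ref1
    return best["depth"]


def folding_energy_difference(e_dominant: float, e_alternative: float) -> float:
    """Folding-energy gap dE = E_dominant - E_alternative.

    Energies are externally computed (e.g. Rosetta Energy Units after
    relaxation); this is pure arithmetic on the two scalars.
    """
    if not (math.isfinite(e_dominant) and math.isfinite(e_alternative)):
        raise ValueError("energies must be finite")
    return e_dominant - e_alternative
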