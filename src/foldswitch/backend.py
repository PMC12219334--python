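"""Contract between the sampling plan and a structure predictor.

Real network inference (ColabFold/AlphaFold2) is out of scope for this
package: any object with ``capabilities`` and ``invoke(msa, job)`` can stand
behind the plan runner.  A deterministic mock backend realises jobs from a
rule-based fixture library, emulating the qualitative behaviour of a real
run on a fold switcher — dominant conformation at deep depth, alternative
conformation and unfolded low-confidence decoys at shallow depths.

Ensembles are interchanged on disk as one PDB per prediction named
``<depth>_<model>_<seed>.pdb`` (":" written as "-") plus a TSV manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .msa import SINGLE, DepthPair, Msa, PredictionJob, SamplingPlan, job_seed
from .structure import StructureModel, read_pdb, write_pdb
from .synth import make_backbone, perturb_smooth

__all__ = [
    "BackendCapabilities",
    "PredictorBackend",
    "PredictionJobResult",
    "EnsembleResult",
    "FixtureLibrary",
    "TwoStateFixtureLibrary",
    "MockBackend",
    "run_plan",
    "write_ensemble",
    "read_ensemble",
]


@dataclass(frozen=True)
class BackendCapabilities:
    supports_multimer: bool = False
    n_models: int = 5


@dataclass
class PredictionJobResult:
    """One predicted model with its job provenance and per-residue confidence."""

    model: StructureModel
    job: PredictionJob

    @property
    def confidence(self) -> np.ndarray:
        return self.model.confidence

    @property
    def mean_confidence(self) -> float:
        return self.model.mean_confidence


@runtime_checkable
class PredictorBackend(Protocol):
    capabilities: BackendCapabilities

    def invoke(self, msa: Msa, job: PredictionJob) -> PredictionJobResult: ...


@dataclass
class EnsembleResult:
    """Per-job results plus isolated failures from a plan run."""

    results: list
    failures: list  # list of (PredictionJob, error message)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def models(self) -> list:
        return [r.model for r in self.results]

    @property
    def jobs(self) -> list:
        return [r.job for r in self.results]


# ---------------------------------------------------------------------------
# mock backend

class FixtureLibrary:
    """Ordered (predicate, builder) rules mapping jobs to structures.

    ``predicate(job) -> bool`` selects the rule; ``builder(job, rng) ->
    (StructureModel, confidence array)`` realises it.  The first matching
    rule wins; no match raises ``LookupError``.
    """

    def __init__(self, rules=None, base_seed: int = 0):
        self.rules: list = list(rules or [])
        self.base_seed = base_seed

    def add_rule(self, predicate: Callable, builder: Callable) -> None:
        self.rules.append((predicate, builder))

    def realize(self, job: PredictionJob) -> StructureModel:
        rng = np.random.default_rng(job_seed(self.base_seed, job))
        for predicate, builder in self.rules:
            if predicate(job):
                model, conf = builder(job, rng)
                model.confidence = np.asarray(conf, dtype=float)
                model.name = str(job)
                return model
        raise LookupError(f"no fixture rule matches job {job}")


class TwoStateFixtureLibrary(FixtureLibrary):
    """Fixture rules emulating a fold-switcher run.

    Deep jobs always return the dominant fold.  Shallow (and single) jobs
    return the alternative fold with probability ``alt_prob``, an unfolded
    low-confidence decoy with probability ``unfold_prob``, and otherwise the
    dominant fold; draws are deterministic in the job seed.
    """

    def __init__(self, dominant: StructureModel, alternative: StructureModel,
                 deep_depth: DepthPair = DepthPair(512, 5120),
                 alt_prob: float = 0.5, unfold_prob: float = 0.1,
                 noise_sd: float = 0.3, base_seed: int = 0):
        super().__init__(base_seed=base_seed)
        if len(dominant) != len(alternative):
            raise ValueError("dominant and alternative folds must share length")
        self.dominant = dominant
        self.alternative = alternative
        self.noise_sd = noise_sd
        self.alt_prob = alt_prob
        self.unfold_prob = unfold_prob
        L = len(dominant)

        def folded(template):
            def build(job, rng):
                m = perturb_smooth(template, self.noise_sd,
                            int(rng.integers(0, 2 ** 31)))
                return m, rng.uniform(82.0, 95.0, size=L)
            return build

        def shallow_build(job, rng):
            u = rng.random()
            if u < self.alt_prob:
                return folded(self.alternative)(job, rng)
            if u < self.alt_prob + self.unfold_prob:
                m = make_backbone("coil", L, seed=int(rng.integers(0, 2 ** 31)))
                return m, rng.uniform(20.0, 45.0, size=L)
            return folded(self.dominant)(job, rng)

        self.add_rule(lambda job: job.depth == deep_depth,
                      folded(self.dominant))
        self.add_rule(lambda job: True, shallow_build)


@dataclass
class MockBackend:
    """Deterministic test double: realises jobs from a fixture library."""

    library: FixtureLibrary
    capabilities: BackendCapabilities = field(
        default_factory=BackendCapabilities)

    def invoke(self, msa: Msa, job: PredictionJob) -> PredictionJobResult:
        return PredictionJobResult(self.library.realize(job), job)


# ---------------------------------------------------------------------------
# plan runner

def run_plan(backend, msa: Msa, plan: SamplingPlan,
             n_copies: int = 1) -> EnsembleResult:
    """Invoke the backend for every job; failures are recorded, not fatal."""
    if backend is None:
        raise ValueError("no predictor backend configured")
    if len(plan) == 0:
        raise ValueError("empty sampling plan")
    if n_copies > 1 and not backend.capabilities.supports_multimer:
        raise ValueError(
            "n_copies > 1 requires a multimer-capable backend")
    results, failures = [], []
    for job in plan:
        try:
            results.append(backend.invoke(msa, job))
        except Exception as exc:  # per-job isolation
            failures.append((job, str(exc)))
    return EnsembleResult(results, failures)


# ---------------------------------------------------------------------------
# ensemble directory interchange

def _job_filename(job: PredictionJob) -> str:
    return f"{str(job.depth).replace(':', '-')}_{job.model_index}_{job.seed}.pdb"


def write_ensemble(results, out_dir) -> Path:
    """Write one PDB per result plus ``manifest.tsv`` (job fields + confidence)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in results:
        fname = _job_filename(r.job)
        write_pdb(r.model, out_dir / fname)
        rows.append({
            "depth": str(r.job.depth),
            "model": r.job.model_index,
            "seed": r.job.seed,
            "file": fname,
            "mean_plddt": round(r.mean_confidence, 2),
        })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_ensemble(ensemble_dir) -> list:
    """Read a manifest-described ensemble directory back into results."""
    ensemble_dir = Path(ensemble_dir)
    manifest = ensemble_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"{manifest} not found")
    table = pd.read_csv(manifest, sep="\t",
                        dtype={"depth": str, "model": int, "seed": int})
    results = []
    for row in table.itertuples():
        depth = SINGLE if row.depth == "single" else DepthPair.parse(row.depth)
        job = PredictionJob(depth, int(row.model), int(row.seed))
        model = read_pdb(ensemble_dir / row.file)
        model.name = str(job)
        results.append(PredictionJobResult(model, job))
    return results
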