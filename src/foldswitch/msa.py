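"""MSA handling and the random-subsampling schedule.

Alignments follow the a3m convention: uppercase letters and ``-`` are match
columns (relative to the query), lowercase letters are insertions.  A
sampling depth ``x:y`` means ``x`` sequences drawn as cluster centers
(``--max-seq``) plus ``y`` extra sequences (``--max-extra-seq``); the deep
default is 512:5120 and the shallow schedule spans 1:2 through 64:128 with
y = 2x.  Also implements the MSA registration/rebalancing procedure used to
coax a predictor toward a minority fold: terminal-gap reregistration of a
minor-fold alignment plus injection of the top few major-fold sequences.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DepthPair",
    "SINGLE",
    "PredictionJob",
    "SamplingPlan",
    "Msa",
    "PairwiseRegistration",
    "DEFAULT_DEEP",
    "DEFAULT_SHALLOW",
    "read_a3m",
    "write_a3m",
    "match_columns",
    "build_sampling_plan",
    "job_seed",
    "subsample_msa",
    "single_sequence_msa",
    "reregister_alignment",
    "rebalance_msa",
    "load_plan_config",
]


# ---------------------------------------------------------------------------
# depths and plans

@dataclass(frozen=True, order=True)
class DepthPair:
    """A subsampling depth x:y (max-seq : max-extra-seq)."""

    max_seq: int
    max_extra_seq: int

    def __post_init__(self) -> None:
        if self.max_seq < 1:
            raise ValueError("max_seq must be >= 1")
        if self.max_extra_seq < 0:
            raise ValueError("max_extra_seq must be >= 0")

    @property
    def total(self) -> int:
        """Sequences sampled per recycle, x + y."""
        return self.max_seq + self.max_extra_seq

    @classmethod
    def parse(cls, text: str):
        if text.strip().lower() == "single":
            return SINGLE
        x, y = text.split(":")
        return cls(int(x), int(y))

    def __str__(self) -> str:
        return f"{self.max_seq}:{self.max_extra_seq}"


class _SingleDepth:
    """Sentinel for single-sequence mode (query only, no subsampling)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "single"

    def __str__(self) -> str:
        return "single"


SINGLE = _SingleDepth()

DEFAULT_DEEP = DepthPair(512, 5120)
DEFAULT_SHALLOW = tuple(DepthPair(x, 2 * x) for x in (1, 2, 4, 8, 16, 32, 64))


@dataclass(frozen=True)
class PredictionJob:
    """One predictor invocation: a depth, a network model index, and a seed."""

    depth: object            # DepthPair or SINGLE
    model_index: int
    seed: int

    def __str__(self) -> str:
        return f"{self.depth}_{self.model_index}_{self.seed}"


@dataclass(frozen=True)
class SamplingPlan:
    jobs: tuple

    def __post_init__(self) -> None:
        if len(set(self.jobs)) != len(self.jobs):
            raise ValueError("plan contains duplicate jobs")

    def __len__(self) -> int:
        return len(self.jobs)

    def __iter__(self):
        return iter(self.jobs)


def build_sampling_plan(deep=DEFAULT_DEEP, shallow_depths=DEFAULT_SHALLOW,
                        n_models: int = 5, n_seeds: int = 5,
                        include_single: bool = False) -> SamplingPlan:
    """Enumerate every (depth, model, seed) combination, deep depth first.

    The default schedule (deep 512:5120; shallow 1:2 ... 64:128; 5 models;
    5 seeds) yields 8 x 5 x 5 = 200 jobs.  Ordering is deterministic:
    depths in listed order, then model index, then seed.
    """
    if n_models < 1 or n_seeds < 1:
        raise ValueError("n_models and n_seeds must be >= 1")
    depths: list = []
    if deep is not None:
        depths.append(deep)
    depths.extend(shallow_depths)
    if include_single:
        depths.append(SINGLE)
    if len(set(map(str, depths))) != len(depths):
        raise ValueError("duplicate depths in schedule")
    jobs = tuple(
        PredictionJob(d, m, s)
        for d in depths
        for m in range(1, n_models + 1)
        for s in range(n_seeds)
    )
    return SamplingPlan(jobs)


def job_seed(base_seed: int, job: PredictionJob) -> int:
    """Stable per-job RNG seed (< 2^31) derived from the base seed and job id."""
    key = f"{base_seed}|{job.depth}|{job.model_index}|{job.seed}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def load_plan_config(path) -> SamplingPlan:
    """Build a plan from a YAML document.

    Recognised keys: ``deep_depth`` ("512:5120"), ``shallow_depths`` (list of
    "x:y" strings), ``n_models``, ``n_seeds``, ``include_single``,
    ``base_seed`` (returned alongside via the plan's use site; ignored here).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    deep = DepthPair.parse(cfg["deep_depth"]) if "deep_depth" in cfg else DEFAULT_DEEP
    shallow = tuple(DepthPair.parse(s) for s in cfg.get("shallow_depths", [])) \
        or DEFAULT_SHALLOW
    return build_sampling_plan(
        deep=deep, shallow_depths=shallow,
        n_models=int(cfg.get("n_models", 5)),
        n_seeds=int(cfg.get("n_seeds", 5)),
        include_single=bool(cfg.get("include_single", False)),
    )


# ---------------------------------------------------------------------------
# alignments

def match_columns(seq: str) -> int:
    """Number of match-state columns (uppercase or '-') in an a3m row."""
    return sum(1 for c in seq if c == "-" or c.isupper())


@dataclass
class Msa:
    """An alignment in a3m convention; row 0 is the query."""

    rows: list  # list of (id, aligned_seq)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must contain at least the query row")
        qid, qseq = self.rows[0]
        if "-" in qseq:
            raise ValueError("query row must contain no gap characters")
        n_match = match_columns(qseq)
        for rid, seq in self.rows[1:]:
            if match_columns(seq) != n_match:
                raise ValueError(
                    f"row {rid!r}: {match_columns(seq)} match columns, "
                    f"query has {n_match}"
                )

    @property
    def query_id(self) -> str:
        return self.rows[0][0]

    @property
    def query_seq(self) -> str:
        return self.rows[0][1]

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def n_match_columns(self) -> int:
        return match_columns(self.rows[0][1])


def read_a3m(path) -> Msa:
    """Read an a3m (or aligned FASTA) file; the first record is the query."""
    rows = []
    current_id, current_seq, id_line = None, [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith(">"):
                if current_id is not None:
                    if not current_seq:
                        raise ValueError(
                            f"{path}:{id_line}: record {current_id!r} has no sequence")
                    rows.append((current_id, "".join(current_seq)))
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                current_seq, id_line = [], lineno
            else:
                if current_id is None:
                    raise ValueError(f"{path}:{lineno}: sequence before any '>' header")
                if "*" in line:
                    raise ValueError(f"{path}:{lineno}: '*' terminators not accepted")
                current_seq.append(line.strip())
    if current_id is not None:
        if not current_seq:
            raise ValueError(f"{path}:{id_line}: record {current_id!r} has no sequence")
        rows.append((current_id, "".join(current_seq)))
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return Msa(rows)


def write_a3m(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# subsampling

def subsample_msa(msa: Msa, depth, seed: int) -> Msa:
    """Uniformly subsample non-query rows to depth.total - 1, keeping the query.

    The query is always row 0 of the output.  If the MSA has fewer rows than
    the target, all rows are kept.  Identical (msa, depth, seed) give
    byte-identical output; sampled rows keep their original order.
    """
    if depth is SINGLE:
        return single_sequence_msa(msa)
    n_take = depth.total - 1
    others = msa.rows[1:]
    if len(others) <= n_take:
        return Msa(list(msa.rows))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(others), size=n_take, replace=False))
    return Msa([msa.rows[0]] + [others[i] for i in chosen])


def single_sequence_msa(msa: Msa) -> Msa:
    """Strip the alignment down to the query row (single-sequence mode)."""
    return Msa([msa.rows[0]])


# ---------------------------------------------------------------------------
# registration / rebalancing (sequence-association workflow)

@dataclass
class PairwiseRegistration:
    """A query-homolog pairwise alignment with explicit terminal gaps."""

    query_aln: str
    homolog_aln: str

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.homolog_aln):
            raise ValueError("aligned strings must have equal length")

    @property
    def length(self) -> int:
        return len(self.query_aln)

    @staticmethod
    def _terminal_gaps(seq: str) -> tuple[int, int]:
        lead = len(seq) - len(seq.lstrip("-"))
        trail = len(seq) - len(seq.rstrip("-"))
        return lead, trail

    @property
    def terminal_gaps(self) -> dict:
        return {
            "query": self._terminal_gaps(self.query_aln),
            "homolog": self._terminal_gaps(self.homolog_aln),
        }


def reregister_alignment(pairwise: PairwiseRegistration, target_length: int,
                         lead: int | None = None) -> PairwiseRegistration:
    """Pad terminal gap columns so the alignment spans ``target_length`` columns.

    ``lead`` fixes how many of the added gap columns go to the N-terminus
    (the remainder go C-terminal); by default all padding is N-terminal.
    Interior columns and the degapped sequences are unchanged.
    """
    extra = target_length - pairwise.length
    if extra < 0:
        raise ValueError(
            f"alignment length {pairwise.length} exceeds target {target_length}")
    if lead is None:
        lead = extra
    if not 0 <= lead <= extra:
        raise ValueError("lead gap count out of range")
    trail = extra - lead
    return PairwiseRegistration(
        "-" * lead + pairwise.query_aln + "-" * trail,
        "-" * lead + pairwise.homolog_aln + "-" * trail,
    )


def rebalance_msa(major: Msa, minor: Msa, top_k_minor: int = 3) -> Msa:
    """Merge a majority-fold MSA with the top few sequences of a minority MSA.

    Output = query + all non-query rows of ``major`` + the first
    ``top_k_minor`` non-query rows of ``minor``.  Both inputs must already be
    registered to the same query match columns.
    """
    if major.n_match_columns != minor.n_match_columns:
        raise ValueError(
            "major and minor MSAs disagree on match columns; reregister first")
    available = minor.rows[1:]
    if len(available) < top_k_minor:
        warnings.warn(
            f"minor MSA has only {len(available)} non-query rows; "
            f"requested top {top_k_minor}")
    take = available[:top_k_minor]
    return Msa([major.rows[0]] + list(major.rows[1:]) + list(take))
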