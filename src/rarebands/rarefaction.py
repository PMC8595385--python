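"""Random subsampling of sequence libraries to a normalized depth.

Rarefying draws a random subsample of ``depth`` reads from a sample's observed
library. Without replacement the draw follows the multivariate hypergeometric
distribution over the observed counts (a subset of the observed reads); with
replacement it follows the multinomial distribution at the observed
proportions, which can inflate a rare variant beyond its observed count.
Repeating the draw many times (default 1000) yields an ensemble that
characterizes the subsampling variability injected by normalization, instead
of a single arbitrary realization.

Random streams are derived deterministically from ``(seed, rep, sample)`` so
ensembles are bit-reproducible regardless of evaluation order or the number of
workers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .feature_table import FeatureTable, library_sizes

__all__ = [
    "RarefactionSpec",
    "RarefiedEnsemble",
    "DepthCandidate",
    "UndersizedSampleError",
    "rarefy_once",
    "rarefy_repeated",
    "rarefaction_curve",
    "expected_richness_analytic",
    "suggest_depths",
    "save_ensemble",
    "load_ensemble",
]

logger = logging.getLogger(__name__)

WITHOUT_REPLACEMENT = "without_replacement"
WITH_REPLACEMENT = "with_replacement"
_MODE_ALIASES = {
    "wor": WITHOUT_REPLACEMENT,
    "wr": WITH_REPLACEMENT,
    WITHOUT_REPLACEMENT: WITHOUT_REPLACEMENT,
    WITH_REPLACEMENT: WITH_REPLACEMENT,
}


class UndersizedSampleError(ValueError):
    """Raised when a library is smaller than the requested depth."""


@dataclass(frozen=True)
class RarefactionSpec:
    """Parameters of one repeated-rarefaction run.

    depth
        Normalized library size (reads) every retained sample is subsampled to.
    reps
        Number of independent rarefaction repetitions (default 1000).
    mode
        ``"without_replacement"`` (multivariate hypergeometric, the
        theoretically preferred default) or ``"with_replacement"``
        (multinomial); short aliases ``"wor"`` / ``"wr"`` are accepted.
    seed
        Base seed; per-(rep, sample) streams are derived from it.
    undersized_policy
        ``"drop"`` removes (and records) samples whose library is below
        ``depth``; ``"error"`` raises instead.
    """

    depth: int
    reps: int = 1000
    mode: str = WITHOUT_REPLACEMENT
    seed: int = 0
    undersized_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        mode = _MODE_ALIASES.get(str(self.mode).lower())
        if mode is None:
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if self.undersized_policy not in ("drop", "error"):
            raise ValueError(f"unknown undersized_policy {self.undersized_policy!r}")


@dataclass(frozen=True)
class RarefiedEnsemble:
    """A stack of rarefied count profiles: shape (reps, n_samples, n_features)."""

    spec: RarefactionSpec
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    dropped_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        expected = (self.spec.reps, len(self.sample_ids), len(self.feature_ids))
        if counts.shape != expected:
            raise ValueError(f"counts shape {counts.shape}, expected {expected}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "dropped_samples", tuple(self.dropped_samples))

    @property
    def reps(self) -> int:
        return self.spec.reps

    @property
    def depth(self) -> int:
        return self.spec.depth


def _stream(seed: int, rep: int, sample_index: int) -> np.random.Generator:
    # counter-style derivation: independent of evaluation order / worker count
    return np.random.default_rng([seed, rep, sample_index])


def rarefy_once(
    counts: np.ndarray,
    depth: int,
    mode: str = WITHOUT_REPLACEMENT,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Subsample one library to ``depth`` reads; the result sums to ``depth``.

    Without replacement the draw is multivariate hypergeometric with
    parameters (counts, depth); with replacement it is multinomial with
    p_i = counts_i / library size.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector for one sample")
    total = int(counts.sum())
    if total <= 0:
        raise ValueError("cannot rarefy an all-zero library")
    mode = _MODE_ALIASES.get(str(mode).lower())
    if mode is None:
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if mode == WITHOUT_REPLACEMENT:
        if depth > total:
            raise UndersizedSampleError(
                f"depth {depth} exceeds library size {total}; "
                "cannot draw without replacement"
            )
        # sequential conditional hypergeometric draws, one feature at a time
        return rng.multivariate_hypergeometric(counts, depth, method="marginals").astype(
            np.int64
        )
    return rng.multinomial(depth, counts / total).astype(np.int64)


def rarefy_repeated(
    table: FeatureTable, spec: RarefactionSpec, n_jobs: int = 1
) -> RarefiedEnsemble:
    """Repeatedly rarefy every sufficiently deep sample of a table.

    Samples whose library size is below ``spec.depth`` are dropped with a
    logged warning (``undersized_policy="drop"``) or raise
    (``undersized_policy="error"``). Each (rep, sample) cell is an independent
    :func:`rarefy_once` draw from its own deterministic random stream, so the
    result depends only on ``(table, spec)``, not on ``n_jobs``.
    """
    sizes = library_sizes(table).per_sample
    undersized = [s for s in table.sample_ids if sizes[s] < spec.depth]
    if undersized:
        if spec.undersized_policy == "error":
            raise UndersizedSampleError(
                f"samples below depth {spec.depth}: "
                + ", ".join(f"{s} ({sizes[s]} reads)" for s in undersized)
            )
        logger.warning(
            "dropping %d sample(s) below depth %d: %s",
            len(undersized),
            spec.depth,
            ", ".join(undersized),
        )
    kept = [s for s in table.sample_ids if sizes[s] >= spec.depth]
    if not kept:
        raise UndersizedSampleError(
            f"no sample reaches depth {spec.depth}; available library sizes: "
            + ", ".join(f"{s}={sizes[s]}" for s in table.sample_ids)
        )
    # sample index in the *original* table keys the random stream, so that
    # dropping a sample does not shift the streams of the others
    sample_index = {s: i for i, s in enumerate(table.sample_ids)}
    matrix = np.asarray(table.counts)
    columns = {s: matrix[:, sample_index[s]] for s in kept}

    out = np.empty((spec.reps, len(kept), table.n_features), dtype=np.int64)

    def fill(rep_lo: int, rep_hi: int) -> None:
        for r in range(rep_lo, rep_hi):
            for j, s in enumerate(kept):
                rng = _stream(spec.seed, r, sample_index[s])
                out[r, j] = rarefy_once(columns[s], spec.depth, spec.mode, rng)

    if n_jobs > 1 and spec.reps > 1:
        from joblib import Parallel, delayed

        bounds = np.linspace(0, spec.reps, n_jobs + 1).astype(int)
        Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(fill)(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])
        )
    else:
        fill(0, spec.reps)

    return RarefiedEnsemble(
        spec=spec,
        feature_ids=table.feature_ids,
        sample_ids=tuple(kept),
        counts=out,
        dropped_samples=tuple(undersized),
    )


def _auto_grid(library_size: int, n_points: int = 20) -> list[int]:
    grid = np.unique(np.linspace(1, library_size, n_points).round().astype(int))
    grid = grid[grid >= 1]
    if library_size not in grid:
        grid = np.append(grid, library_size)
    return [int(d) for d in grid]


def rarefaction_curve(
    table: FeatureTable,
    depths: list[int] | str = "auto",
    reps: int = 10,
    mode: str = WITHOUT_REPLACEMENT,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed richness as a function of subsampling depth.

    Returns a tidy frame with one row per (sample, depth, rep) where the depth
    does not exceed that sample's library size; ``richness`` is the number of
    features with a nonzero rarefied count. ``depths="auto"`` uses 20 linearly
    spaced depths from 1 to each sample's library size (the library size
    itself always included).
    """
    sizes = library_sizes(table).per_sample
    sample_index = {s: i for i, s in enumerate(table.sample_ids)}
    matrix = np.asarray(table.counts)
    rows = []
    for s in table.sample_ids:
        col = matrix[:, sample_index[s]]
        if sizes[s] == 0:
            continue
        grid = _auto_grid(sizes[s]) if isinstance(depths, str) else [
            int(d) for d in depths if d <= sizes[s]
        ]
        for d in grid:
            if d < 1:
                raise ValueError(f"depths must be positive, got {d}")
            for r in range(reps):
                rng = _stream(seed, r, sample_index[s])
                draw = rarefy_once(col, d, mode, rng)
                rows.append((s, d, r, int(np.count_nonzero(draw))))
    return pd.DataFrame(rows, columns=["sample", "depth", "rep", "richness"])


def expected_richness_analytic(counts: np.ndarray, depth: int) -> float:
    """Exact expected richness under without-replacement rarefying.

    For a library with feature counts n_i and total N, the expected number of
    features observed in a uniform subsample of size d is

        E[S_d] = sum_i [ 1 - C(N - n_i, d) / C(N, d) ],

    evaluated with log-gamma arithmetic so large libraries do not overflow.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds library size {total}")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def log_choose(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    log_p_absent = np.where(
        rest >= depth,
        log_choose(rest.astype(float), depth) - log_choose(float(total), depth),
        -np.inf,
    )
    return float(np.sum(1.0 - np.exp(log_p_absent)))


@dataclass(frozen=True)
class DepthCandidate:
    """A candidate normalized library size with the samples it would exclude."""

    depth: int
    dropped_samples: tuple[str, ...]
    inclusive: bool  # True iff no sample is dropped at this depth


def suggest_depths(table: FeatureTable) -> list[DepthCandidate]:
    """Candidate normalized library sizes for the inclusive-vs-exclusive choice.

    The smallest library size is the inclusive candidate (no sample dropped);
    every other sample's library size is listed with the samples that would be
    excluded at that depth, supporting a dual analysis at an inclusive smaller
    depth and a larger depth that omits shallow samples.
    """
    summary = library_sizes(table)
    sizes = summary.per_sample
    candidates = []
    for depth in sorted(set(sizes.values())):
        dropped = tuple(s for s in table.sample_ids if sizes[s] < depth)
        candidates.append(DepthCandidate(depth, dropped, inclusive=not dropped))
    return candidates


# ---------------------------------------------------------------------------
# Ensemble serialization: .npz archive + JSON sidecar
# ---------------------------------------------------------------------------


def save_ensemble(ensemble: RarefiedEnsemble, path: str) -> str:
    """Write the counts stack to ``path`` (.npz) plus a ``<path>.json`` sidecar."""
    np.savez_compressed(path, counts=np.asarray(ensemble.counts))
    sidecar = {
        "spec": asdict(ensemble.spec),
        "feature_ids": list(ensemble.feature_ids),
        "sample_ids": list(ensemble.sample_ids),
        "dropped_samples": list(ensemble.dropped_samples),
    }
    with open(f"{path}.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def load_ensemble(path: str) -> RarefiedEnsemble:
    import os

    if not str(path).endswith(".npz"):
        path = f"{path}.npz"
    with np.load(path) as archive:
        counts = archive["counts"]
    # np.savez appends .npz when missing; the sidecar sits next to the path
    # the caller originally passed, so try both spellings
    sidecar_path = f"{path[:-4]}.json"
    if not os.path.exists(sidecar_path):
        sidecar_path = f"{path}.json"
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    return RarefiedEnsemble(
        spec=RarefactionSpec(**sidecar["spec"]),
        feature_ids=tuple(sidecar["feature_ids"]),
        sample_ids=tuple(sidecar["sample_ids"]),
        counts=counts,
        dropped_samples=tuple(sidecar["dropped_samples"]),
    )
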