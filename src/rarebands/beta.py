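"""Beta diversity over repeated-rarefaction ensembles.

All repetitions of all samples are pooled into one distance matrix and one
ordination, so each sample appears as a patch of replicate points in a common
coordinate system; the size of a patch measures the variability that rarefying
injected into the between-sample analysis.

Bray-Curtis is computed on Hellinger-transformed profiles by default (square
root of proportions, which bounds distances and counters the arch effect in
ordinations of count data); Jaccard reduces profiles to presence/absence
first. The ordination is classical scaling (principal coordinates): Gower
double-centering of -1/2 d^2 followed by eigendecomposition. Bray-Curtis is a
semimetric, so negative eigenvalues can occur; they are truncated, counted,
and excluded from the explained-variance denominator, with an optional Lingoes
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

from .rarefaction import RarefiedEnsemble

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "hellinger",
    "bray_curtis",
    "jaccard_distance",
    "ensemble_distance_matrix",
    "pcoa",
    "patch_dispersion",
]

logger = logging.getLogger(__name__)

ENSEMBLE_METRICS = ("bray_curtis_hellinger", "bray_curtis_raw", "jaccard")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over (sample, rep) profiles."""

    labels: tuple[tuple[str, int], ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape}, expected ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        d.setflags(write=False)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", tuple((str(s), int(r)) for s, r in self.labels))

    @property
    def n_points(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a (sample, rep) distance matrix."""

    labels: tuple[tuple[str, int], ...]
    coordinates: np.ndarray  # (n_points, n_axes)
    explained: np.ndarray  # explained-variance proportion per retained axis
    n_negative_eigenvalues: int

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"axis{k + 1}": self.coordinates[:, k] for k in range(self.coordinates.shape[1])}
        frame = pd.DataFrame(
            {"sample": [s for s, _ in self.labels], "rep": [r for _, r in self.labels], **cols}
        )
        return frame


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: h_i = sqrt(counts_i / library size); sum h_i^2 = 1."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot Hellinger-transform an all-zero profile")
    return np.sqrt(counts / total)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum |x_i - y_i| / sum (x_i + y_i), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.min(initial=0) < 0 or y.min(initial=0) < 0:
        raise ValueError("profiles must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("both profiles are all-zero")
    return float(_ssd.braycurtis(x, y))


def jaccard_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard distance 1 - |A∩B|/|A∪B| on the presence sets of two profiles."""
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (x.any() or y.any()):
        raise ValueError("both presence sets are empty")
    return float(_ssd.jaccard(x, y))


def ensemble_distance_matrix(
    ensemble: RarefiedEnsemble, metric: str = "bray_curtis_hellinger"
) -> DistanceMatrix:
    """Pairwise dissimilarities over every (sample, rep) rarefied profile.

    All repetitions are pooled into a single matrix so replicate points share
    one ordination space. Rows are ordered sample-major: for samples (A, B)
    and 2 reps the labels run (A,0), (A,1), (B,0), (B,1).
    """
    if metric not in ENSEMBLE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {ENSEMBLE_METRICS}")
    stack = np.asarray(ensemble.counts, dtype=float)  # (reps, samples, features)
    reps, n_samples, _ = stack.shape
    # sample-major pooling
    profiles = stack.transpose(1, 0, 2).reshape(n_samples * reps, -1)
    labels = tuple((s, r) for s in ensemble.sample_ids for r in range(reps))
    if metric == "bray_curtis_hellinger":
        profiles = hellinger(profiles)
        condensed = _ssd.pdist(profiles, metric="braycurtis")
    elif metric == "bray_curtis_raw":
        condensed = _ssd.pdist(profiles, metric="braycurtis")
    else:
        condensed = _ssd.pdist(profiles > 0, metric="jaccard")
    return DistanceMatrix(labels, _ssd.squareform(condensed))


def pcoa(
    dist: DistanceMatrix,
    n_axes: int = 2,
    negative_correction: str | None = None,
    eig_tol: float = 1e-10,
) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis) of a distance matrix.

    Coordinates are eigenvectors of the Gower-centered matrix scaled by the
    square roots of their (positive) eigenvalues. Negative eigenvalues —
    expected for semimetrics such as Bray-Curtis — are truncated, counted in
    ``n_negative_eigenvalues``, and excluded from the explained-variance
    denominator. ``negative_correction="lingoes"`` instead adds the Lingoes
    constant to off-diagonal squared dissimilarities before re-embedding. Axis
    signs are fixed so each axis's largest-magnitude coordinate is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    eigvals, eigvecs = _gower_eigen(d)
    scale = max(abs(eigvals[0]), 1.0)
    if negative_correction == "lingoes" and eigvals[-1] < -eig_tol * scale:
        c = -eigvals[-1]
        d2 = d**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        eigvals, eigvecs = _gower_eigen(np.sqrt(d2))
    elif negative_correction not in (None, "lingoes"):
        raise ValueError(f"unknown negative_correction {negative_correction!r}")

    tol = eig_tol * max(abs(eigvals[0]), 1.0)
    n_negative = int(np.sum(eigvals < -tol))
    positive = eigvals[eigvals > tol]
    n_keep = min(n_axes, positive.size)
    if n_keep < n_axes:
        logger.info(
            "requested %d axes but only %d positive eigenvalues; returning %d",
            n_axes,
            positive.size,
            n_keep,
        )
    if n_keep == 0:
        coords = np.zeros((n, 0))
        explained = np.zeros(0)
    else:
        coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
        # deterministic sign convention
        for k in range(n_keep):
            pivot = np.argmax(np.abs(coords[:, k]))
            if coords[pivot, k] < 0:
                coords[:, k] = -coords[:, k]
        explained = eigvals[:n_keep] / positive.sum()
    return OrdinationResult(
        labels=dist.labels,
        coordinates=coords,
        explained=explained,
        n_negative_eigenvalues=n_negative,
    )


def _gower_eigen(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def patch_dispersion(ordination: OrdinationResult) -> pd.DataFrame:
    """Mean distance of each sample's replicate points to their centroid.

    A scalar per sample quantifying the spread of its "patch" in the retained
    ordination axes; zero when all repetitions coincide (e.g. a sample that
    was not actually rarefied because its library equals the depth).
    """
    frame = ordination.to_dataframe()
    axes = [c for c in frame.columns if c.startswith("axis")]
    rows = []
    for sample, grp in frame.groupby("sample", sort=False):
        pts = grp[axes].to_numpy()
        centroid = pts.mean(axis=0)
        dispersion = float(np.linalg.norm(pts - centroid, axis=1).mean()) if axes else 0.0
        rows.append((sample, len(grp), dispersion, *centroid))
    cols = ["sample", "n_reps", "dispersion", *(f"centroid_{a}" for a in axes)]
    return pd.DataFrame(rows, columns=cols)
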