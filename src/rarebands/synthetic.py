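"""Synthetic amplicon communities with controlled structure.

Generates feature tables with known true compositions so that every analysis
stage can be exercised and validated without sequencing data: configurable
richness, rank-abundance skew (uniform / geometric series / Dirichlet),
per-sample library sizes, and optional group structure in which a chosen
fraction of features swap abundance ranks between groups.

The ``paperlike`` preset builds six samples (A-F) of varying diversity and
initial library size — geometric rank-abundance curves with richness from 60
to 500 features and libraries from 500 to 35,000 reads, split into two
compositional groups — the configuration used throughout this package's own
validation and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = [
    "SyntheticCommunitySpec",
    "generate_community",
    "generate_fifty_fifty",
    "spike_rare_variants",
    "paperlike_spec",
    "generate_paperlike",
]

ABUNDANCE_MODELS = ("uniform", "geometric", "dirichlet")


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """Recipe for a synthetic multi-sample community.

    n_features
        Size of the shared feature pool.
    abundance_model / model_params
        Rank-abundance shape of the base composition: ``uniform`` (even),
        ``geometric`` (params: ``ratio`` in (0, 1), long-tailed), or
        ``dirichlet`` (params: ``concentration`` > 0). ``model_params`` may
        also carry ``sample_richness`` (map sample_id -> int) restricting each
        sample to its top-r most abundant features, renormalized.
    sample_library_sizes
        Reads per sample; with ``exact_totals`` the generated column sums
        equal these exactly.
    group_assignment / between_group_divergence
        Optional group labels; within a group samples share a true
        composition, between groups a ``between_group_divergence`` fraction of
        features have their abundances permuted.
    """

    n_features: int
    sample_library_sizes: dict[str, int]
    abundance_model: str = "geometric"
    model_params: dict = field(default_factory=dict)
    group_assignment: dict[str, str] | None = None
    between_group_divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not self.sample_library_sizes:
            raise ValueError("at least one sample is required")
        if any(v < 1 for v in self.sample_library_sizes.values()):
            raise ValueError("library sizes must be >= 1")
        if self.abundance_model not in ABUNDANCE_MODELS:
            raise ValueError(
                f"unknown abundance_model {self.abundance_model!r}; "
                f"expected one of {ABUNDANCE_MODELS}"
            )
        if not 0.0 <= self.between_group_divergence <= 1.0:
            raise ValueError("between_group_divergence must be in [0, 1]")
        if self.group_assignment is not None:
            missing = set(self.sample_library_sizes) - set(self.group_assignment)
            if missing:
                raise ValueError(f"samples without a group: {sorted(missing)}")


def _base_composition(spec: SyntheticCommunitySpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_features
    if spec.abundance_model == "uniform":
        base = np.full(n, 1.0 / n)
    elif spec.abundance_model == "geometric":
        ratio = float(spec.model_params.get("ratio", 0.98))
        if not 0.0 < ratio < 1.0:
            raise ValueError(f"geometric ratio must be in (0, 1), got {ratio}")
        base = ratio ** np.arange(n)
        base /= base.sum()
    else:  # dirichlet
        conc = float(spec.model_params.get("concentration", 1.0))
        if conc <= 0:
            raise ValueError(f"dirichlet concentration must be > 0, got {conc}")
        base = np.sort(rng.dirichlet(np.full(n, conc)))[::-1]
    return base


def _diverge(base: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Permute the abundances of a ``divergence`` fraction of features."""
    comp = base.copy()
    k = int(np.ceil(divergence * comp.size))
    if k >= 2:
        chosen = rng.choice(comp.size, size=k, replace=False)
        shuffled = rng.permutation(chosen)
        comp[chosen] = base[shuffled]
    return comp


def generate_community(
    spec: SyntheticCommunitySpec, exact_totals: bool = True
) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw a count table plus the true compositions it was sampled from.

    Per sample, the group's base composition (optionally truncated to that
    sample's richness and renormalized) is sampled at the sample's library
    size: multinomially when ``exact_totals`` (column sums match the spec
    exactly), otherwise with independent Poisson counts of the same
    expectation, whose totals fluctuate as real library sizes do.

    Returns ``(table, truth)`` where ``truth`` is a features x samples
    DataFrame of true proportions.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = list(spec.sample_library_sizes)
    feature_ids = [f"ASV{i + 1}" for i in range(spec.n_features)]
    base = _base_composition(spec, rng)

    group_comps: dict[str, np.ndarray] = {}
    if spec.group_assignment is not None:
        groups = sorted(set(spec.group_assignment.values()))
        group_comps[groups[0]] = base
        for g in groups[1:]:
            group_comps[g] = _diverge(base, spec.between_group_divergence, rng)

    richness_map = spec.model_params.get("sample_richness", {})
    truth = np.zeros((spec.n_features, len(sample_ids)))
    counts = np.zeros((spec.n_features, len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        comp = base
        if spec.group_assignment is not None:
            comp = group_comps[spec.group_assignment[s]]
        r = int(richness_map.get(s, spec.n_features))
        if not 1 <= r <= spec.n_features:
            raise ValueError(f"sample_richness[{s!r}] = {r} out of range")
        if r < spec.n_features:
            comp = comp.copy()
            # keep the r most abundant features of this sample's composition
            drop = np.argsort(comp)[: spec.n_features - r]
            comp[drop] = 0.0
            comp /= comp.sum()
        truth[:, j] = comp
        size = spec.sample_library_sizes[s]
        if exact_totals:
            counts[:, j] = rng.multinomial(size, comp)
        else:
            counts[:, j] = rng.poisson(size * comp)
    table = FeatureTable(tuple(feature_ids), tuple(sample_ids), counts)
    truth_df = pd.DataFrame(truth, index=feature_ids, columns=sample_ids)
    return table, truth_df


def generate_fifty_fifty(library_size: int) -> FeatureTable:
    """One sample with two features at an exact 50:50 ratio.

    The benchmark library for demonstrating pure subsampling noise: rarefying
    it never returns an exact 50:50 split except by chance.
    """
    if library_size < 2 or library_size % 2:
        raise ValueError(f"library_size must be a positive even integer, got {library_size}")
    half = library_size // 2
    return FeatureTable(
        ("ASV1", "ASV2"), ("S1",), np.array([[half], [half]], dtype=np.int64)
    )


def spike_rare_variants(table: FeatureTable, n_rare: int, count: int = 1) -> FeatureTable:
    """Append ``n_rare`` new features carrying ``count`` reads in every sample.

    Test fodder for rare-variant loss: rarefying regularly discards such
    variants, which is the main caveat of rarefaction-based normalization for
    rare-sequence detection.
    """
    if n_rare < 1:
        raise ValueError("n_rare must be >= 1")
    if count < 1:
        raise ValueError("count must be >= 1")
    existing = set(table.feature_ids)
    new_ids, k = [], 0
    while len(new_ids) < n_rare:
        k += 1
        candidate = f"rare{k}"
        if candidate not in existing:
            new_ids.append(candidate)
    block = np.full((n_rare, table.n_samples), count, dtype=np.int64)
    counts = np.vstack([np.asarray(table.counts), block]) if table.n_features else block
    taxonomy = dict(table.taxonomy) if table.taxonomy is not None else None
    return FeatureTable(
        table.feature_ids + tuple(new_ids), table.sample_ids, counts, taxonomy
    )


# ---------------------------------------------------------------------------
# The six-sample preset
# ---------------------------------------------------------------------------

#: library sizes (reads) and richness (features) for the six preset samples;
#: A is the deepest and most diverse library, F the shallowest and least
_PAPERLIKE_SIZES = {"A": 35000, "B": 20000, "C": 12000, "D": 8000, "E": 3000, "F": 500}
_PAPERLIKE_RICHNESS = {"A": 500, "B": 400, "C": 300, "D": 200, "E": 120, "F": 60}
_PAPERLIKE_GROUPS = {"A": "g1", "B": "g1", "C": "g1", "D": "g2", "E": "g2", "F": "g2"}


def paperlike_spec(seed: int = 0) -> SyntheticCommunitySpec:
    """Six samples A-F of varying diversity and initial library size.

    Geometric rank-abundance curves (ratio 0.98 over a 1000-feature pool) give
    the long-tailed structure under which rarefaction visibly suppresses the
    Shannon index; two compositional groups (A-C vs D-F, 25% rank divergence)
    give separable ordination patches.
    """
    return SyntheticCommunitySpec(
        n_features=1000,
        sample_library_sizes=dict(_PAPERLIKE_SIZES),
        abundance_model="geometric",
        model_params={"ratio": 0.98, "sample_richness": dict(_PAPERLIKE_RICHNESS)},
        group_assignment=dict(_PAPERLIKE_GROUPS),
        between_group_divergence=0.25,
        seed=seed,
    )


def generate_paperlike(seed: int = 0) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate the six-sample preset community at the given seed."""
    return generate_community(paperlike_spec(seed))
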