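"""Figures for repeated-rarefaction analyses, with tidy-TSV twins.

Three figure families: rarefaction curves (mean richness vs depth with
inter-repetition ribbons), alpha-diversity bands (quantile envelopes of the
Shannon index or Hill numbers across repetitions), and ordination patches (one
point per sample x repetition in principal-coordinate space). Every plot
writes the exact numbers it draws to a TSV next to the image, so figures are
views over data and can be regenerated without recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alpha import summarize_alpha
from .beta import OrdinationResult

__all__ = [
    "PlotSpec",
    "plot_rarefaction_curves",
    "plot_alpha_bands",
    "plot_ordination_patches",
]

PLOT_KINDS = ("curve", "alpha_fixed_depths", "alpha_vs_depth", "ordination_patches")


@dataclass(frozen=True)
class PlotSpec:
    """Where and how to render one figure."""

    kind: str
    output: str
    colors: dict[str, str] | None = None
    image_format: str | None = None  # inferred from output suffix when None
    lower_q: float = 0.025
    upper_q: float = 0.975
    guide_depths: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}; expected one of {PLOT_KINDS}")


def _color_map(sample_ids: list[str], overrides: dict[str, str] | None) -> dict[str, str]:
    # deterministic palette from sorted sample ids
    cmap = plt.get_cmap("tab10")
    colors = {s: cmap(i % 10) for i, s in enumerate(sorted(sample_ids))}
    if overrides:
        colors.update(overrides)
    return colors


def _twin_path(output: str) -> str:
    return str(Path(output).with_suffix(".tsv"))


def _save(fig: plt.Figure, spec: PlotSpec) -> str:
    fig.savefig(spec.output, format=spec.image_format, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return spec.output


def plot_rarefaction_curves(records: pd.DataFrame, spec: PlotSpec) -> tuple[str, str]:
    """Mean richness vs depth per sample with an inter-repetition ribbon.

    ``records`` is the tidy output of :func:`rarebands.rarefaction_curve`
    (columns sample, depth, rep, richness). Vertical guide lines are drawn at
    ``spec.guide_depths`` (candidate normalized library sizes). Returns the
    image path and the tidy-TSV twin path (one row per sample x depth).
    """
    if records.empty:
        raise ValueError("no rarefaction-curve records to plot")
    grouped = records.groupby(["sample", "depth"], sort=True)["richness"]
    series = grouped.agg(
        mean="mean",
        lower=lambda v: float(np.quantile(v, spec.lower_q)),
        upper=lambda v: float(np.quantile(v, spec.upper_q)),
        n_reps="size",
    ).reset_index()
    colors = _color_map(series["sample"].unique().tolist(), spec.colors)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sample, grp in series.groupby("sample", sort=True):
        grp = grp.sort_values("depth")
        ax.plot(grp["depth"], grp["mean"], label=sample, color=colors[sample])
        ax.fill_between(
            grp["depth"], grp["lower"], grp["upper"], color=colors[sample], alpha=0.25, lw=0
        )
    for d in spec.guide_depths:
        ax.axvline(d, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("normalized library size (reads)")
    ax.set_ylabel("observed richness (features)")
    ax.legend(title="sample", fontsize="small")
    image = _save(fig, spec)
    twin = _twin_path(spec.output)
    series.to_csv(twin, sep="\t", index=False)
    return image, twin


def plot_alpha_bands(records: pd.DataFrame, spec: PlotSpec) -> tuple[str, str]:
    """Quantile envelopes of a diversity metric across repetitions.

    ``kind="alpha_vs_depth"`` draws mean lines with quantile ribbons as a
    function of depth (requires >= 2 depths); ``kind="alpha_fixed_depths"``
    draws per-sample distribution strips at each depth. When records carry a
    ``mode`` column, with- and without-replacement series are drawn
    separately. Returns image path and tidy-TSV twin (the plotted summaries).
    """
    if records.empty:
        raise ValueError("no alpha records to plot")
    has_mode = "mode" in records.columns
    keys = ["mode"] if has_mode else []

    def summarize(frame: pd.DataFrame) -> pd.DataFrame:
        out = summarize_alpha(frame, spec.lower_q, spec.upper_q)
        return out

    if has_mode:
        pieces = []
        for mode, grp in records.groupby("mode", sort=True):
            piece = summarize(grp.drop(columns=["mode"]))
            piece.insert(0, "mode", mode)
            pieces.append(piece)
        summary = pd.concat(pieces, ignore_index=True)
    else:
        summary = summarize(records)

    n_depths = summary["depth"].nunique()
    if spec.kind == "alpha_vs_depth" and n_depths < 2:
        raise ValueError("alpha_vs_depth needs records spanning >= 2 depths")

    colors = _color_map(summary["sample"].unique().tolist(), spec.colors)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    linestyles = {m: ls for m, ls in zip(sorted(summary["mode"].unique()), ["-", "--"])} if has_mode else {}
    if spec.kind == "alpha_vs_depth":
        for key, grp in summary.groupby(["sample", *keys], sort=True):
            sample = key[0] if isinstance(key, tuple) else key
            label = sample if not has_mode else f"{sample} ({key[1]})"
            grp = grp.sort_values("depth")
            ls = linestyles.get(key[1], "-") if has_mode else "-"
            ax.plot(grp["depth"], grp["mean"], label=label, color=colors[sample], ls=ls)
            ax.fill_between(
                grp["depth"], grp["lower"], grp["upper"], color=colors[sample], alpha=0.2, lw=0
            )
        ax.set_xlabel("normalized library size (reads)")
    else:  # alpha_fixed_depths: one vertical band per (sample, depth)
        depths = sorted(summary["depth"].unique())
        samples = sorted(summary["sample"].unique())
        width = 0.8 / max(len(samples), 1)
        for si, sample in enumerate(samples):
            for di, depth in enumerate(depths):
                sel = summary[(summary["sample"] == sample) & (summary["depth"] == depth)]
                for _, row in sel.iterrows():
                    x = di + si * width - 0.4
                    ax.vlines(x, row["lower"], row["upper"], color=colors[sample], lw=3)
                    ax.plot([x], [row["median"]], "o", color=colors[sample], ms=3)
        ax.set_xticks(range(len(depths)), [str(d) for d in depths])
        ax.set_xlabel("normalized library size (reads)")
        handles = [plt.Line2D([0], [0], color=colors[s], lw=3) for s in samples]
        ax.legend(handles, samples, title="sample", fontsize="small")
    metric = records["metric"].iloc[0]
    ax.set_ylabel("Shannon index" if metric == "shannon" else "Hill number")
    if spec.kind == "alpha_vs_depth":
        ax.legend(fontsize="small")
    image = _save(fig, spec)
    twin = _twin_path(spec.output)
    summary.to_csv(twin, sep="\t", index=False)
    return image, twin


def plot_ordination_patches(
    ordination: OrdinationResult | pd.DataFrame,
    spec: PlotSpec,
    explained: np.ndarray | None = None,
    hulls: bool = True,
) -> str:
    """Scatter of all (sample, rep) points in the first two ordination axes.

    Each sample's repetitions form a colored patch (optional convex hull); a
    sample that is not actually rarefied collapses to a single visible point.
    Axis labels carry explained-variance percentages when available.
    """
    if isinstance(ordination, OrdinationResult):
        frame = ordination.to_dataframe()
        explained = ordination.explained
    else:
        frame = ordination
    axes = [c for c in frame.columns if c.startswith("axis")]
    if len(axes) < 2:
        raise ValueError("ordination patches need >= 2 axes")
    if frame.empty:
        raise ValueError("no ordination points to plot")
    colors = _color_map(frame["sample"].unique().tolist(), spec.colors)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for sample, grp in frame.groupby("sample", sort=True):
        pts = grp[[axes[0], axes[1]]].to_numpy()
        ax.scatter(pts[:, 0], pts[:, 1], s=8, color=colors[sample], label=sample, alpha=0.7)
        if hulls and len(pts) >= 3 and not np.allclose(pts, pts[0]):
            try:
                from scipy.spatial import ConvexHull

                hull = ConvexHull(pts)
                cycle = np.append(hull.vertices, hull.vertices[0])
                ax.plot(pts[cycle, 0], pts[cycle, 1], color=colors[sample], lw=0.8, alpha=0.6)
            except Exception:  # degenerate (collinear) patches have no hull
                pass

    def axis_label(k: int) -> str:
        if explained is not None and len(explained) > k:
            return f"PCo{k + 1} ({100 * explained[k]:.1f}%)"
        return f"PCo{k + 1}"

    ax.set_xlabel(axis_label(0))
    ax.set_ylabel(axis_label(1))
    ax.legend(title="sample", fontsize="small")
    return _save(fig, spec)
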