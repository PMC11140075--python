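"""Faceted bar/box plots of percent root length colonization.

Two layouts mirror the downstream-analysis workflow:

* ``Facets`` — one panel per structure, with additional facet variables
  (if present in the filtered table) as panel rows; conditions on the
  x axis.
* ``Single`` — one panel; conditions on the x axis and structures side
  by side, distinguished by fill color.

Bars show the group mean with a standard-error-of-the-mean whisker;
boxes show median, interquartile range and 1.5xIQR whiskers.  Rendering
is deterministic: datapoint jitter is seeded, and the sidecar JSON
written next to the image records the configuration used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .model import TOTAL

__all__ = ["PlotConfig", "resolve_colors", "make_plot"]

#: Display order of structure panels / fills.
_STRUCTURE_ORDER = (TOTAL, "EH", "H", "IH", "A", "V", "S")


@dataclass
class PlotConfig:
    """Aesthetic and output controls for :func:`make_plot`."""

    graph_type: str = "Facets"  # Facets | Single
    graph_object: str = "bars"  # bars | boxes
    show_datapoints: bool = False
    condition_order: Optional[Sequence[str]] = None
    facet_orders: dict[str, Sequence[str]] = field(default_factory=dict)
    stat_display: str = "none"  # letters | asterisks | none
    reference_condition: Optional[str] = None
    manual_colors: Optional[dict[str, str]] = None
    palette: str = "viridis"
    palette_begin: float = 0.0
    palette_end: float = 0.85
    text_color: str = "black"
    background_color: str = "white"
    hline_color: str = "0.85"
    size_right_label: float = 10.0
    size_top_label: float = 10.0
    size_y_axis: float = 10.0
    size_x_axis: float = 10.0
    size_legend: float = 10.0
    size_legend_text: float = 9.0
    size_percentages: float = 9.0
    size_statistics: float = 10.0
    size_datapoints: float = 12.0
    show_sample_sizes: bool = False
    show_legend: bool = True
    output: Optional[str] = None
    resolution: int = 300
    width: float = 7.0
    height: float = 4.5
    jitter_seed: int = 0

    def validate(self) -> None:
        if self.graph_type not in ("Facets", "Single"):
            raise ValueError("graph_type must be 'Facets' or 'Single'")
        if self.graph_object not in ("bars", "boxes"):
            raise ValueError("graph_object must be 'bars' or 'boxes'")
        if not 0.0 <= self.palette_begin <= self.palette_end <= 1.0:
            raise ValueError("palette begin/end must satisfy 0 <= begin <= end <= 1")
        for name in (
            "size_right_label", "size_top_label", "size_y_axis", "size_x_axis",
            "size_legend", "size_legend_text", "size_percentages",
            "size_statistics", "size_datapoints", "width", "height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def resolve_colors(
    groups: Sequence[str], config: PlotConfig
) -> dict[str, str]:
    """Map each group to a hex color: manual map or evenly sampled palette."""
    groups = list(groups)
    if config.manual_colors is not None:
        missing = [g for g in groups if g not in config.manual_colors]
        if missing:
            raise ValueError(
                "manual color map is missing group(s): " + ", ".join(missing)
            )
        return {g: to_hex(config.manual_colors[g]) for g in groups}
    cmap = colormaps[config.palette]
    if len(groups) == 1:
        positions = [config.palette_begin]
    else:
        positions = np.linspace(
            config.palette_begin, config.palette_end, len(groups)
        )
    return {g: to_hex(cmap(p)) for g, p in zip(groups, positions)}


def _ordered(values: Sequence[str], order: Optional[Sequence[str]]) -> list[str]:
    observed = list(dict.fromkeys(values))
    if order is None:
        return observed
    order = list(order)
    if sorted(order) != sorted(observed):
        raise ValueError(
            f"order {order} is not a permutation of observed levels {observed}"
        )
    return order


def _draw_cell(
    ax,
    cell: pd.DataFrame,
    x_levels: list[str],
    hue_levels: list[str],
    hue_col: str,
    colors: dict[str, str],
    config: PlotConfig,
    annotations: Optional[dict[str, str]],
    rng: np.random.Generator,
) -> None:
    n_hue = max(len(hue_levels), 1)
    slot = 0.8 / n_hue
    for hi, hue in enumerate(hue_levels or [None]):
        for xi, level in enumerate(x_levels):
            sub = cell[cell["condition"] == level]
            if hue is not None:
                sub = sub[sub[hue_col] == hue]
            vals = sub["value"].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            x = xi - 0.4 + slot * (hi + 0.5)
            color = colors[hue if hue is not None else level]
            if config.graph_object == "bars":
                mean = vals.mean()
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                ax.bar(
                    x, mean, width=slot * 0.9, color=color,
                    edgecolor=config.text_color, linewidth=0.5,
                    label=hue if xi == 0 else None,
                )
                if sem > 0:
                    ax.errorbar(
                        x, mean, yerr=sem, fmt="none",
                        ecolor=config.text_color, capsize=3, linewidth=1,
                    )
            else:
                bp = ax.boxplot(
                    vals, positions=[x], widths=slot * 0.9, whis=1.5,
                    patch_artist=True, showfliers=not config.show_datapoints,
                    medianprops={"color": config.text_color},
                )
                for patch in bp["boxes"]:
                    patch.set_facecolor(color)
                if hue is not None and xi == 0:
                    ax.bar(x, 0, width=0, color=color, label=hue)
            if config.show_datapoints:
                jitter = rng.uniform(-0.1, 0.1, size=len(vals)) * slot / 0.8
                ax.scatter(
                    x + jitter, vals, s=config.size_datapoints,
                    color=config.text_color, zorder=3, alpha=0.8,
                )
            if config.show_sample_sizes:
                ax.text(
                    x, 1.0, f"n={len(vals)}", ha="center", va="bottom",
                    fontsize=config.size_percentages * 0.8,
                    color=config.text_color,
                )
            if annotations is not None and hue is None:
                label = annotations.get(level, "")
                if label:
                    top = vals.max()
                    if config.graph_object == "bars":
                        top = vals.mean() + (
                            vals.std(ddof=1) / np.sqrt(len(vals))
                            if len(vals) > 1 else 0.0
                        )
                    ax.text(
                        x, top + 3, label, ha="center", va="bottom",
                        fontsize=config.size_statistics, color=config.text_color,
                    )
    ax.set_xticks(range(len(x_levels)))
    ax.set_xticklabels(x_levels, fontsize=config.size_x_axis)
    ax.set_xlim(-0.6, len(x_levels) - 0.4)
    ax.set_ylim(0, 105)
    ax.set_yticks(range(0, 101, 20))
    ax.tick_params(axis="y", labelsize=config.size_y_axis)
    ax.grid(axis="y", color=config.hline_color, linewidth=0.6, zorder=0)
    ax.set_axisbelow(True)
    ax.set_facecolor(config.background_color)


def make_plot(
    table: pd.DataFrame,
    annotations: Optional[dict[tuple, dict[str, str]]] = None,
    config: Optional[PlotConfig] = None,
):
    """Render the filtered long table; returns the matplotlib Figure.

    ``annotations`` maps (structure, facet values...) cell keys to
    per-condition label maps (letters or asterisks), as produced by the
    analysis layer.  If ``config.output`` is set, the figure is saved
    there (PNG honors ``resolution``; PDF/SVG are vector) together with
    a ``<output>.json`` sidecar echoing the configuration.
    """
    config = config or PlotConfig()
    config.validate()
    if table.empty:
        raise ValueError("nothing to plot: the filtered table is empty")

    facet_cols = [
        c for c in table.columns
        if c not in ("replicate", "condition", "structure", "value")
    ]
    conditions = _ordered(table["condition"], config.condition_order)
    structures = [
        s for s in _STRUCTURE_ORDER if s in set(table["structure"])
    ]
    if annotations is not None:
        for key, ann in annotations.items():
            unknown = set(ann) - set(conditions)
            if unknown:
                raise ValueError(
                    f"annotation cell {key}: groups {sorted(unknown)} absent "
                    "from the plotted conditions"
                )

    facet_levels = [
        _ordered(table[c], config.facet_orders.get(c)) for c in facet_cols
    ]
    import itertools as _it

    row_keys = list(_it.product(*facet_levels)) if facet_cols else [()]
    rng = np.random.default_rng(config.jitter_seed)

    if config.graph_type == "Facets":
        nrows, ncols = len(row_keys), len(structures)
        fig, axes = plt.subplots(
            nrows, ncols,
            figsize=(config.width, config.height),
            squeeze=False, sharey=True,
        )
        for ri, rkey in enumerate(row_keys):
            for ci, struct in enumerate(structures):
                ax = axes[ri][ci]
                cell = table[table["structure"] == struct]
                for col, val in zip(facet_cols, rkey):
                    cell = cell[cell[col] == val]
                ann = None
                if annotations is not None:
                    ann = annotations.get((struct, *rkey))
                colors = resolve_colors(conditions, config)
                _draw_cell(
                    ax, cell, conditions, [], "", colors, config, ann, rng
                )
                if ri == 0:
                    ax.set_title(struct, fontsize=config.size_top_label)
                if ci == ncols - 1 and rkey:
                    ax.yaxis.set_label_position("right")
                    ax.set_ylabel(
                        " / ".join(rkey), rotation=270, labelpad=12,
                        fontsize=config.size_right_label,
                    )
        axes[0][0].figure.supylabel(
            "Root length colonization (%)", fontsize=config.size_y_axis
        )
    else:  # Single
        fig, axes = plt.subplots(
            1, 1, figsize=(config.width, config.height), squeeze=False
        )
        ax = axes[0][0]
        colors = resolve_colors(structures, config)
        ann = annotations.get(("Single",)) if annotations else None
        _draw_cell(
            ax, table, conditions, structures, "structure", colors,
            config, ann, rng,
        )
        ax.set_ylabel(
            "Root length colonization (%)", fontsize=config.size_y_axis
        )
        if config.show_legend:
            ax.legend(
                fontsize=config.size_legend_text,
                title="Structure", title_fontsize=config.size_legend,
            )

    fig.patch.set_facecolor(config.background_color)
    fig.tight_layout()

    if config.output:
        save_kwargs = {}
        if str(config.output).lower().endswith(".png"):
            save_kwargs["dpi"] = config.resolution
        fig.savefig(config.output, **save_kwargs)
        sidecar = dataclasses.asdict(config)
        sidecar["condition_order"] = list(conditions)
        with open(str(config.output) + ".json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True, default=list)
    return fig
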