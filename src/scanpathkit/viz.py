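"""Rendering: distance-matrix panels, web diagrams, grid heatmaps, chords.

Every renderer writes three things: the figure (SVG or PNG, from the output
suffix), a CSV of the exact values plotted, and a JSON metadata sidecar
recording the parameters that make the figure auditable (color-scale bounds,
normalization constants, width-per-count ratios).  All quantitative test
assertions live on this data layer; image bytes are never compared.

Group panels always share one color scale — cross-group comparison is
meaningless otherwise.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import FancyArrowPatch

from .gridding import DwellGrid
from .io import AoiSet, GroupAssignment, GROUP_LABELS
from .scanpath import DistanceMatrix, normalize
from .transitions import Edge

__all__ = [
    "RenderSpec",
    "render_distance_matrix",
    "render_web_diagram",
    "render_grid_heatmap",
    "render_chord",
]

logger = logging.getLogger("scanpathkit.viz")

SUPPORTED_FORMATS = ("svg", "png")


@dataclass(frozen=True)
class RenderSpec:
    """Where and how to render a figure.

    The format is taken from the path suffix (``.svg`` or ``.png``).  The
    CSV/JSON sidecars are written next to the figure with the same stem.
    """

    path: Path
    cmap: str = "Greys"
    title: str = ""
    normalize: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", Path(self.path))
        fmt = self.path.suffix.lstrip(".").lower()
        if fmt not in SUPPORTED_FORMATS:
            raise ValueError(f"unsupported figure format {fmt!r}; use one of {SUPPORTED_FORMATS}")

    @property
    def format(self) -> str:
        return self.path.suffix.lstrip(".").lower()

    def sidecar(self, suffix: str) -> Path:
        return self.path.with_suffix(suffix)


def _finish(fig, spec: RenderSpec, meta: dict) -> dict:
    spec.path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(spec.path, format=spec.format)
    plt.close(fig)
    spec.sidecar(".json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return meta


def render_distance_matrix(
    matrix: DistanceMatrix,
    groups: GroupAssignment | None,
    spec: RenderSpec,
    stimulus_id: str | None = None,
) -> dict:
    """One distance-matrix panel per group, darker cells = larger distance.

    The matrix is max-normalized first (with a logged notice if the caller
    did not do so), so panels share the [0, 1] scale.  The plotted values
    are written as a labelled CSV sidecar; the metadata sidecar records the
    normalization constant and per-panel participant order.
    """
    norm_const = float(matrix.values.max(initial=0.0))
    if not matrix.normalized:
        logger.info("auto-normalizing distance matrix (max=%s)", norm_const)
        matrix = normalize(matrix)

    if groups is None:
        panels = {"all": list(matrix.labels)}
    else:
        if stimulus_id is None:
            stimuli = {s for (p, s) in groups.assignments if p in matrix.labels}
            if len(stimuli) != 1:
                raise ValueError("pass stimulus_id: groups span multiple stimuli")
            stimulus_id = stimuli.pop()
        panels = {
            g: [p for p in matrix.labels
                if (p, stimulus_id) in groups and groups.group_of(p, stimulus_id) == g]
            for g in GROUP_LABELS
        }
        panels = {g: members for g, members in panels.items() if members}

    fig, axes = plt.subplots(
        1, len(panels), figsize=(5.2 * len(panels), 5), squeeze=False
    )
    plotted: dict[str, np.ndarray] = {}
    for ax, (gname, members) in zip(axes[0], panels.items()):
        idx = [matrix.labels.index(p) for p in members]
        sub = matrix.values[np.ix_(idx, idx)]
        plotted[gname] = sub
        im = ax.imshow(sub, cmap=spec.cmap, vmin=0.0, vmax=1.0)
        ax.set_xticks(range(len(members)), members, rotation=90, fontsize=6)
        ax.set_yticks(range(len(members)), members, fontsize=6)
        ax.set_title(gname)
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="normalized Levenshtein distance")
    if spec.title:
        fig.suptitle(spec.title)

    frames = []
    for gname, sub in plotted.items():
        df = pd.DataFrame(sub, index=panels[gname], columns=panels[gname])
        df.insert(0, "group", gname)
        frames.append(df)
    pd.concat(frames).to_csv(spec.sidecar(".csv"))

    meta = {
        "kind": "distance_matrix",
        "normalization_max_distance": norm_const,
        "scale": [0.0, 1.0],
        "panels": {g: members for g, members in panels.items()},
        "argmax_row": {
            g: panels[g][int(np.argmax(sub.sum(axis=1)))] for g, sub in plotted.items()
        },
    }
    return _finish(fig, spec, meta)


def render_web_diagram(
    summaries: Mapping[str, Mapping[str, float]],
    spec: RenderSpec,
) -> dict:
    """Radar chart of per-stimulus summary values, one polygon per group.

    ``summaries`` maps group -> stimulus -> value (typically the mean
    truncated scanpath length).  At least three stimulus axes are required
    for the polygon to be meaningful.
    """
    stimuli = sorted({s for per_group in summaries.values() for s in per_group})
    if len(stimuli) < 3:
        raise ValueError(f"web diagram needs >= 3 stimulus axes, got {len(stimuli)}")
    angles = np.linspace(0, 2 * math.pi, len(stimuli), endpoint=False)

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    values: dict[str, list[float]] = {}
    for gname, per_group in summaries.items():
        vals = [float(per_group.get(s, np.nan)) for s in stimuli]
        values[gname] = vals
        closed = np.concatenate([vals, vals[:1]])
        closed_angles = np.concatenate([angles, angles[:1]])
        ax.plot(closed_angles, closed, label=gname)
        ax.fill(closed_angles, closed, alpha=0.15)
    ax.set_xticks(angles, stimuli, fontsize=7)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    if spec.title:
        ax.set_title(spec.title)

    pd.DataFrame(values, index=stimuli).rename_axis("stimulus").to_csv(spec.sidecar(".csv"))
    meta = {"kind": "web_diagram", "stimuli": stimuli, "values": values}
    return _finish(fig, spec, meta)


def render_grid_heatmap(
    dwell_grid: DwellGrid,
    spec: RenderSpec,
    annotate: bool = True,
    aoiset: AoiSet | None = None,
    scale: tuple[float, float] | None = None,
) -> dict:
    """Heatmap of per-cell dwell totals, optionally annotated and overlaid.

    ``scale`` fixes the (vmin, vmax) color bounds so correct/incorrect
    panels rendered separately stay comparable; it defaults to this grid's
    own range.  ``annotate`` prints each cell's dwell value (ms).  Passing
    an ``aoiset`` overlays the AOI rectangle boundaries.
    """
    g = dwell_grid.grid
    vmin, vmax = scale if scale is not None else (0.0, float(dwell_grid.values.max(initial=0.0)))
    fig, ax = plt.subplots(figsize=(8, 8 * g.height / g.width))
    ax.imshow(
        dwell_grid.values,
        cmap=spec.cmap,
        vmin=vmin,
        vmax=vmax,
        extent=(0, g.width, g.height, 0),
        aspect="auto",
    )
    if annotate:
        for r in range(g.n_rows):
            for c in range(g.n_cols):
                ax.text(
                    (c + 0.5) * g.cell_width,
                    (r + 0.5) * g.cell_height,
                    f"{dwell_grid.values[r, c]:.0f}",
                    ha="center", va="center", fontsize=5,
                )
    if aoiset is not None:
        for a in aoiset:
            ax.add_patch(
                plt.Rectangle((a.x0, a.y0), a.x1 - a.x0, a.y1 - a.y0,
                              fill=False, edgecolor="tab:blue", linewidth=0.8)
            )
            ax.text(a.x0 + 4, a.y0 + 12, a.label, color="tab:blue", fontsize=7)
    if spec.title:
        ax.set_title(spec.title)

    pd.DataFrame(dwell_grid.values).to_csv(spec.sidecar(".csv"), index_label="row")
    meta = {
        "kind": "grid_heatmap",
        "scale": [float(vmin), float(vmax)],
        "grid": {
            "n_rows": g.n_rows, "n_cols": g.n_cols,
            "cell_width": g.cell_width, "cell_height": g.cell_height,
            "base_dimension": g.base_dimension,
        },
        "annotated_values": dwell_grid.values.tolist() if annotate else None,
        "argmax_cell": list(dwell_grid.argmax_cell),
        "excluded_duration_ms": dwell_grid.excluded_duration,
    }
    return _finish(fig, spec, meta)


def render_chord(
    edges: Sequence[Edge],
    spec: RenderSpec,
    max_width_pts: float = 12.0,
) -> dict:
    """Directed chord diagram of transition counts.

    Nodes sit on a circle; each directed edge is a curved ribbon whose line
    width is proportional to its count (``max_width_pts`` for the largest
    count), with an arrow head at the target and the count printed beside
    it.  Self-loops are drawn as small loops outside the node.
    """
    if not edges:
        raise ValueError("render_chord requires a non-empty edge list")
    nodes = sorted({e.source for e in edges} | {e.target for e in edges})
    angles = {n: 2 * math.pi * i / len(nodes) for i, n in enumerate(nodes)}
    pos = {n: (math.cos(a), math.sin(a)) for n, a in angles.items()}
    max_count = max(e.count for e in edges)
    width_per_count = max_width_pts / max_count

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    for n, (x, y) in pos.items():
        ax.plot(x, y, "o", color="black", markersize=6)
        ax.annotate(n, (1.18 * x, 1.18 * y), ha="center", va="center")
    for e in edges:
        lw = e.count * width_per_count
        if e.source == e.target:
            x, y = pos[e.source]
            loop = plt.Circle((1.32 * x, 1.32 * y), 0.12, fill=False, lw=lw)
            ax.add_patch(loop)
            ax.annotate(str(e.count), (1.32 * x, 1.32 * y), ha="center",
                        va="center", fontsize=7)
        else:
            arrow = FancyArrowPatch(
                pos[e.source], pos[e.target],
                connectionstyle="arc3,rad=0.2",
                arrowstyle="-|>", mutation_scale=10 + lw,
                lw=lw, color="tab:gray", shrinkA=8, shrinkB=8,
            )
            ax.add_patch(arrow)
            mx = 0.55 * (pos[e.source][0] + pos[e.target][0]) / 2 + 0.45 * pos[e.target][0]
            my = 0.55 * (pos[e.source][1] + pos[e.target][1]) / 2 + 0.45 * pos[e.target][1]
            ax.annotate(str(e.count), (mx, my), fontsize=7)
    if spec.title:
        ax.set_title(spec.title)

    pd.DataFrame(edges, columns=["from", "to", "count"]).to_csv(
        spec.sidecar(".csv"), index=False
    )
    meta = {
        "kind": "chord",
        "nodes": nodes,
        "width_per_count_pts": width_per_count,
        "widths_pts": {f"{e.source}->{e.target}": e.count * width_per_count for e in edges},
        "total_transitions": int(sum(e.count for e in edges)),
    }
    return _finish(fig, spec, meta)
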