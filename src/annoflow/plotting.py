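"""Static figure rendering (matplotlib, Agg backend, deterministic SVG).

Figures are a faithful rendering of the CSV payloads written next to them;
the CSVs, not the SVGs, are the canonical numeric record.  SVG output is
made reproducible by fixing the hash salt and suppressing the embedded
creation date.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

matplotlib.rcParams["svg.hashsalt"] = "annoflow"

#: color slots for selections; slot 0 is background grey
COLOR_SLOTS = ["#bbbbbb", "#d95f02", "#1b9e77", "#7570b3", "#e7298a"]


def _save(fig, path: str | Path) -> None:
    path = Path(path)
    fig.savefig(path, format=path.suffix.lstrip("."), metadata={"Date": None})
    plt.close(fig)


def rose_figure(rose: pd.DataFrame, path: str | Path) -> None:
    """Radial bar ('rose') plots of scaled marker expression, one per selection."""
    n_sel = rose.shape[1]
    n_feat = rose.shape[0]
    theta = np.linspace(0, 2 * np.pi, n_feat, endpoint=False)
    width = 2 * np.pi / max(n_feat, 1) * 0.9
    fig, axes = plt.subplots(
        1, n_sel, figsize=(4.5 * n_sel, 4.5), subplot_kw={"projection": "polar"}
    )
    axes = np.atleast_1d(axes)
    for ax, (name, col) in zip(axes, rose.items()):
        ax.bar(theta, col.to_numpy(), width=width,
               color=COLOR_SLOTS[1 + list(rose.columns).index(name) % (len(COLOR_SLOTS) - 1)],
               alpha=0.8)
        ax.set_xticks(theta)
        ax.set_xticklabels(rose.index, fontsize=7)
        ax.set_ylim(0, 1.05)
        ax.set_yticks([0.5, 1.0])
        ax.set_title(str(name), fontsize=9)
    fig.tight_layout()
    _save(fig, path)


def bars_figure(bars: pd.DataFrame, path: str | Path) -> None:
    """Side-by-side mean-expression bars for the two selections."""
    n_feat = bars.shape[0]
    x = np.arange(n_feat)
    width = 0.8 / max(bars.shape[1], 1)
    fig, ax = plt.subplots(figsize=(max(6.0, 0.6 * n_feat), 4.0))
    for j, (name, col) in enumerate(bars.items()):
        ax.bar(x + j * width, col.to_numpy(), width=width,
               color=COLOR_SLOTS[1 + j % (len(COLOR_SLOTS) - 1)], label=str(name))
    ax.set_xticks(x + width / 2)
    ax.set_xticklabels(bars.index, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("mean normalized expression")
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def umap_figure(frame: pd.DataFrame, path: str | Path, title: str = "UMAP") -> None:
    """Embedding scatter; background cells first, tagged cells on top."""
    tag_color = {
        "background": COLOR_SLOTS[0],
        "sel1": COLOR_SLOTS[1],
        "sel2": COLOR_SLOTS[2],
        "both": COLOR_SLOTS[3],
    }
    fig, ax = plt.subplots(figsize=(5.0, 5.0))
    for tag in ["background", "sel1", "sel2", "both"]:
        sub = frame[frame["tag"] == tag]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], s=6, c=tag_color[tag],
                       label=tag if tag != "background" else None, linewidths=0)
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    ax.set_title(title, fontsize=10)
    if frame["tag"].nunique() > 1:
        ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def sankey_figure(payload: dict, path: str | Path) -> None:
    """Static two-column Sankey: nodes as stacked bars, links as bezier bands."""
    from matplotlib.path import Path as MplPath
    import matplotlib.patches as patches

    nodes = payload["nodes"]
    links = payload["links"]
    left = [n for n in nodes if n["side"] == "left"]
    right = [n for n in nodes if n["side"] == "right"]
    total = max(sum(n["total"] for n in left), 1)
    gap = 0.02 * total

    def positions(side_nodes):
        pos, y = {}, 0.0
        for n in side_nodes:
            pos[n["label"]] = (y, y + n["total"])
            y += n["total"] + gap
        return pos

    lpos, rpos = positions(left), positions(right)
    label_of = {i: n["label"] for i, n in enumerate(nodes)}
    fig, ax = plt.subplots(figsize=(7.0, 5.0))
    for n in left:
        y0, y1 = lpos[n["label"]]
        ax.fill_betweenx([y0, y1], 0.0, 0.05, color="#444444")
        ax.text(-0.02, (y0 + y1) / 2, n["label"], ha="right", va="center", fontsize=8)
    for n in right:
        y0, y1 = rpos[n["label"]]
        ax.fill_betweenx([y0, y1], 0.95, 1.0, color="#444444")
        ax.text(1.02, (y0 + y1) / 2, n["label"], ha="left", va="center", fontsize=8)

    loff = {n["label"]: lpos[n["label"]][0] for n in left}
    roff = {n["label"]: rpos[n["label"]][0] for n in right}
    for link in links:
        src, dst, val = label_of[link["source"]], label_of[link["target"]], link["value"]
        y0 = loff[src]; loff[src] += val
        y1 = roff[dst]; roff[dst] += val
        color = COLOR_SLOTS[link.get("color_tag", 0) % len(COLOR_SLOTS)]
        verts = [(0.05, y0), (0.5, y0), (0.5, y1), (0.95, y1),
                 (0.95, y1 + val), (0.5, y1 + val), (0.5, y0 + val), (0.05, y0 + val),
                 (0.05, y0)]
        codes = [MplPath.MOVETO, MplPath.CURVE4, MplPath.CURVE4, MplPath.CURVE4,
                 MplPath.LINETO, MplPath.CURVE4, MplPath.CURVE4, MplPath.CURVE4,
                 MplPath.CLOSEPOLY]
        ax.add_patch(patches.PathPatch(MplPath(verts, codes), facecolor=color,
                                       alpha=0.55, edgecolor="none"))
    ax.set_xlim(-0.35, 1.35)
    ax.axis("off")
    ax.set_title(
        f"{payload['left_annotation']} vs {payload['right_annotation']} "
        f"(min cells = {payload['min_cells']})",
        fontsize=10,
    )
    fig.tight_layout()
    _save(fig, path)
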