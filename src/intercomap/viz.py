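"""Publication-style rendering of contact and consensus maps.

Four styles mirror the classic map types: ``classical`` (black dots at every
contact), ``property`` (dots colored by the physicochemical pair class),
``range`` (colored by distance-range bin) and ``consensus-gray`` (linear gray
ramp, rate 0 → white, rate 1 → black: the more conserved the contact, the
darker the dot). Axes are labeled by residue key; matplotlib's Agg backend is
forced so rendering works headless. All tabular outputs elsewhere in the
package are independent of this module.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .consensus import ConsensusMap, consensus_matrix  # noqa: E402
from .contacts import ContactMap, PROPERTY_CLASSES  # noqa: E402

__all__ = ["render_map"]

_PROPERTY_COLORS = {
    "hydrophobic-hydrophobic": "#d62728",
    "hydrophilic-hydrophilic": "#1f77b4",
    "charged-charged": "#2ca02c",
    "mixed": "#7f7f7f",
}
_RANGE_CMAP = "viridis"
_MAX_TICKS = 40


def _key_str(key) -> str:
    c, n, ic = key
    return f"{c}:{n}{ic}"


def _decorate_axes(ax, axis1, axis2):
    n1, n2 = len(axis1), len(axis2)
    ax.set_xlim(-0.5, n2 - 0.5)
    ax.set_ylim(n1 - 0.5, -0.5)
    step1 = max(1, n1 // _MAX_TICKS)
    step2 = max(1, n2 // _MAX_TICKS)
    ax.set_xticks(range(0, n2, step2))
    ax.set_xticklabels([_key_str(k) for k in axis2[::step2]], rotation=90, fontsize=6)
    ax.set_yticks(range(0, n1, step1))
    ax.set_yticklabels([_key_str(k) for k in axis1[::step1]], fontsize=6)
    ax.set_xlabel("interactor 2")
    ax.set_ylabel("interactor 1")
    ax.set_aspect("equal")


def render_map(
    cmap: Union[ContactMap, ConsensusMap],
    style: str,
    path: Union[str, Path],
    title: str = "",
) -> Path:
    """Render a contact or consensus map to an image file (PNG/SVG by suffix)."""
    if style not in ("classical", "property", "range", "consensus-gray"):
        raise ValueError(f"unknown style {style!r}")
    axis1, axis2 = cmap.axis1, cmap.axis2
    if not axis1 or not axis2:
        raise ValueError("cannot render a map with an empty axis")
    idx1 = {k: i for i, k in enumerate(axis1)}
    idx2 = {k: i for i, k in enumerate(axis2)}
    fig, ax = plt.subplots(figsize=(7, 7))

    if style == "consensus-gray":
        if not isinstance(cmap, ConsensusMap):
            raise TypeError("consensus-gray style needs a ConsensusMap")
        mat = consensus_matrix(cmap).to_numpy()
        ax.imshow(mat, cmap="Greys", vmin=0.0, vmax=1.0, interpolation="nearest")
        sm = plt.cm.ScalarMappable(cmap="Greys", norm=plt.Normalize(0, 1))
        fig.colorbar(sm, ax=ax, fraction=0.04, label="conservation rate")
    else:
        if not isinstance(cmap, ContactMap):
            raise TypeError(f"{style} style needs a ContactMap")
        xs, ys, colors = [], [], []
        for (k1, k2), rec in cmap.records.items():
            ys.append(idx1[k1])
            xs.append(idx2[k2])
            if style == "property":
                colors.append(_PROPERTY_COLORS[rec.property_class])
            elif style == "range":
                colors.append(rec.range_bin)
            else:
                colors.append("black")
        if style == "range":
            sc = ax.scatter(xs, ys, c=colors, cmap=_RANGE_CMAP, s=14, marker="s")
            if xs:
                fig.colorbar(sc, ax=ax, fraction=0.04, label="distance-range bin")
        else:
            ax.scatter(xs, ys, c=colors, s=14, marker="s")
        if style == "property":
            handles = [
                plt.Line2D([], [], marker="s", linestyle="", color=_PROPERTY_COLORS[c], label=c)
                for c in PROPERTY_CLASSES
            ]
            ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=7)

    _decorate_axes(ax, axis1, axis2)
    if title:
        ax.set_title(title, fontsize=9)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
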