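"""Display conventions for neurotaxonomic expression matrices.

Signature heatmaps show row-normalized type-mean CPM (each gene row
scaled to its own maximum), rows ordered by descending delta, columns
headed by a taxonomy color mosaic with a magenta boundary line between
the GABAergic and glutamatergic classes, and per-row side swatches for
log10(rowmax) and delta.  Co-expression histograms annotate the modal
count numerically and color GABAergic red, glutamatergic blue.

Vector (SVG) output is rendered deterministically (fixed hash salt, no
timestamps) so figures can be compared byte-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import Normalize

from .coexpress import CoexpressionResult
from .core import Taxonomy
from .signatures import DeltaTable, SignatureMatrix, order_by_delta

__all__ = [
    "MatrixDisplaySpec",
    "row_normalize",
    "render_signature_figure",
    "render_histograms",
]

#: class colors used in histogram splits
CLASS_COLORS = {"GABAergic": "tab:red", "glutamatergic": "tab:blue"}

matplotlib.rcParams["svg.hashsalt"] = "neurosig"


@dataclass
class MatrixDisplaySpec:
    """Knobs of the signature-matrix display."""

    cmap_mean: str = "viridis"
    cmap_delta: str = "coolwarm_r"  # red = high delta, blue = low
    cmap_rowmax: str = "magma"
    show_labels: bool = True
    boundary_color: str = "magenta"
    figsize: tuple[float, float] = (10.0, 6.0)
    extra: dict = field(default_factory=dict)


def row_normalize(signature: SignatureMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each gene row by its maximum; all-zero rows stay zero and
    are flagged.  Invariant to positive rescaling of the input."""
    means = signature.means
    mu_max = means.max(axis=1)
    flagged = mu_max == 0
    denom = mu_max.replace(0, 1.0)
    return means.div(denom, axis=0), flagged


def _savefig(fig, out_path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    metadata = {"Date": None} if out_path.suffix == ".svg" else None
    fig.savefig(out_path, metadata=metadata)
    plt.close(fig)


def render_signature_figure(
    signature: SignatureMatrix,
    delta_table: DeltaTable,
    taxonomy: Taxonomy,
    out_path,
    display: MatrixDisplaySpec | None = None,
):
    """Heatmap of a signature matrix in the standard display format.

    Rows are reordered to descending delta; the taxonomy mosaic strip
    runs above the matrix and a vertical boundary line separates the
    two neurotransmitter classes.  Writes SVG/PDF/PNG by extension and
    returns the row order used.
    """
    display = display or MatrixDisplaySpec()
    order = [g for g in order_by_delta(delta_table) if g in signature.means.index]
    normalized, _ = row_normalize(signature.subset_genes(order))
    values = normalized.to_numpy()
    types = signature.type_ids
    n_genes, n_types = values.shape

    fig, axes = plt.subplots(
        2,
        3,
        figsize=display.figsize,
        gridspec_kw={
            "height_ratios": [1, max(n_genes, 1)],
            "width_ratios": [max(n_types, 1), 1, 1],
            "hspace": 0.02,
            "wspace": 0.05,
        },
    )
    (ax_mosaic, ax_blank1, ax_blank2), (ax_mat, ax_rowmax, ax_delta) = axes
    for ax in (ax_blank1, ax_blank2):
        ax.axis("off")

    # taxonomy color mosaic above the matrix columns
    mosaic_colors = [
        taxonomy.colors.get(t, "#888888") for t in types
    ]
    rgb = np.array([matplotlib.colors.to_rgb(c) for c in mosaic_colors])
    ax_mosaic.imshow(rgb[None, :, :], aspect="auto", interpolation="nearest")
    ax_mosaic.set_xticks([])
    ax_mosaic.set_yticks([])

    ax_mat.imshow(
        values,
        aspect="auto",
        interpolation="nearest",
        cmap=display.cmap_mean,
        vmin=0,
        vmax=1,
    )
    # boundary between neurotransmitter classes
    nts = [taxonomy.nt_class(t) for t in types]
    for i in range(1, n_types):
        if nts[i] != nts[i - 1]:
            for ax in (ax_mat, ax_mosaic):
                ax.axvline(i - 0.5, color=display.boundary_color, linewidth=1.5)

    if display.show_labels:
        ax_mat.set_yticks(range(n_genes))
        ax_mat.set_yticklabels(order, fontsize=5)
        ax_mat.set_xticks(range(n_types))
        ax_mat.set_xticklabels(types, rotation=90, fontsize=5)
    else:
        ax_mat.set_xticks([])
        ax_mat.set_yticks([])

    stats = delta_table.table.loc[order]
    rowmax = stats["log10_rowmax"].to_numpy()[:, None]
    finite = rowmax[np.isfinite(rowmax)]
    norm = Normalize(
        vmin=float(finite.min()) if finite.size else 0.0,
        vmax=float(finite.max()) if finite.size else 1.0,
    )
    ax_rowmax.imshow(
        rowmax, aspect="auto", interpolation="nearest",
        cmap=display.cmap_rowmax, norm=norm,
    )
    ax_delta.imshow(
        stats["delta"].to_numpy()[:, None],
        aspect="auto",
        interpolation="nearest",
        cmap=display.cmap_delta,
        vmin=0,
        vmax=1,
    )
    for ax, title in ((ax_rowmax, "log(rowmax)"), (ax_delta, "delta")):
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(title, fontsize=6)

    _savefig(fig, out_path)
    return order


def render_histograms(
    result: CoexpressionResult,
    out_path,
    title: str = "co-expressed genes per cell",
):
    """One panel per grouping with the modal count annotated."""
    groups = list(result.histograms)
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(6, 2.2 * len(groups)), squeeze=False
    )
    for ax, group in zip(axes[:, 0], groups):
        hist = result.histograms[group]
        color = CLASS_COLORS.get(group, "tab:gray")
        if hist:
            ks = sorted(hist)
            ax.bar(ks, [hist[k] for k in ks], width=1.0, color=color)
            mode = result.modes[group]
            ax.annotate(
                f"mode = {mode}",
                xy=(0.98, 0.9),
                xycoords="axes fraction",
                ha="right",
                fontsize=9,
            )
        else:
            ax.annotate(
                "no cells",
                xy=(0.5, 0.5),
                xycoords="axes fraction",
                ha="center",
            )
        ax.set_ylabel(group, fontsize=8)
    axes[0, 0].set_title(title, fontsize=10)
    axes[-1, 0].set_xlabel("genes above threshold")
    _savefig(fig, out_path)
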