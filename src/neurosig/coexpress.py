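"""Per-cell co-expression tallies.

For a gene panel and an expression threshold, each cell is scored by
the number of distinct panel genes it expresses strictly above the
threshold.  Distributions of these counts are summarized as unit-width
integer histograms with a modal value, overall and split by
neurotransmitter class (GABAergic vs glutamatergic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CellAnnotation,
    ExpressionMatrix,
    FormatError,
    GenePanel,
    Taxonomy,
)

__all__ = ["CoexpressionResult", "coexpression_counts", "count_histogram", "merge_panels"]


@dataclass
class CoexpressionResult:
    """Histograms and modes of per-cell co-expression counts.

    ``histograms`` maps a grouping name (``all`` plus one per
    neurotransmitter class) to a count -> frequency mapping;
    ``modes`` to the modal count (smallest count attaining the maximal
    frequency).  ``counts`` retains the per-cell values.
    """

    counts: pd.Series
    histograms: dict[str, dict[int, int]]
    modes: dict[str, int | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, hist in self.histograms.items():
            for value, freq in sorted(hist.items()):
                rows.append({"group": group, "count": value, "frequency": freq})
        return pd.DataFrame(rows, columns=["group", "count", "frequency"])


def coexpression_counts(
    matrix: ExpressionMatrix, panel: GenePanel, threshold: float = 10.0
) -> pd.Series:
    """Number of distinct panel genes with CPM strictly above threshold,
    per cell.  Genes in the panel but absent from the matrix count as
    unexpressed."""
    if matrix.unit != "CPM":
        raise FormatError("coexpression_counts expects a CPM matrix")
    if len(panel) == 0:
        raise FormatError("empty gene panel")
    present = [s for s in panel.symbols if s in set(matrix.gene_symbols)]
    if not present:
        return pd.Series(0, index=matrix.cell_ids, dtype=int)
    sub = matrix.subset_genes(present)
    counts = (sub.values > threshold).sum(axis=0)
    return pd.Series(counts.astype(int), index=matrix.cell_ids)


def _mode(hist: dict[int, int]) -> int | None:
    if not hist:
        return None
    best = max(hist.values())
    return min(k for k, v in hist.items() if v == best)


def count_histogram(
    counts: pd.Series,
    annotation: CellAnnotation | None = None,
    taxonomy: Taxonomy | None = None,
) -> CoexpressionResult:
    """Integer-binned histograms of co-expression counts.

    Always reports an ``all`` grouping; when annotation and taxonomy
    are given, adds one grouping per neurotransmitter class so the
    GABAergic and glutamatergic distributions sum cell-wise to the
    overall one.
    """
    groups: dict[str, pd.Series] = {"all": counts}
    if annotation is not None and taxonomy is not None:
        classes = annotation.table.loc[counts.index, "type_id"].map(taxonomy.nt_class)
        for cls in pd.unique(classes):
            groups[str(cls)] = counts[classes == cls]
    histograms, modes = {}, {}
    for name, vals in groups.items():
        hist = {int(k): int(v) for k, v in vals.value_counts().sort_index().items()}
        histograms[name] = hist
        modes[name] = _mode(hist)
    return CoexpressionResult(counts=counts, histograms=histograms, modes=modes)


def merge_panels(panels: list[GenePanel], name: str = "merged") -> GenePanel:
    """Union of panels; duplicate symbols collapse, but a symbol carried
    with two different categories is a conflict and raises."""
    frames = [p.table for p in panels]
    merged = pd.concat(frames, ignore_index=True)
    cats = merged.groupby("symbol")["category"].nunique()
    conflicts = cats[cats > 1].index.tolist()
    if conflicts:
        raise FormatError(f"conflicting categories for symbols: {conflicts[:10]}")
    merged = merged.drop_duplicates(subset="symbol", keep="first")
    return GenePanel(merged.reset_index(drop=True), name=name)
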