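"""Within-type distribution diagnostics and subsampling stability.

Single-cell CPM distributions within a (gene, type) subset can hide
two kinds of trouble behind a clean type mean: an excess of zero/low
values (e.g. dropout or a genuinely bimodal subpopulation) and
isolated very-high-CPM cells that pull the untrimmed mean upward.
These are flagged with explicit, parameterized rules — an
interquartile-range fence on the log scale for high outliers, and a
zero-fraction rule for low anomalies — so the by-eye judgements one
makes on histograms become reproducible.

Type-mean signatures themselves are checked for statistical stability
by repeated disjoint half-splits of the cells within each type: a gene
whose two half-signatures correlate strongly across types is robust to
subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellAnnotation, ExpressionMatrix, FormatError
from .signatures import type_means

__all__ = [
    "OutlierConfig",
    "DistributionDiagnostics",
    "StabilityReport",
    "within_type_histograms",
    "select_display_types",
    "flag_outliers",
    "subsample_stability",
]


@dataclass
class OutlierConfig:
    """Parameters of the diagnostic rules.

    High outlier: cell with log2(CPM+1) above Q3 + ``iqr_factor`` x IQR
    of the subset (quartiles by linear interpolation).  Low anomaly:
    zero fraction above ``zero_fraction`` while the median of the
    nonzero values still exceeds ``expression_threshold`` — i.e. the
    gene is clearly on in the type, yet many cells report nothing.
    """

    iqr_factor: float = 3.0
    zero_fraction: float = 0.25
    expression_threshold: float = 10.0
    min_cells: int = 16


@dataclass
class DistributionDiagnostics:
    """Flags for one (gene, type) subset."""

    gene: str
    type_id: str
    n_cells: int
    zero_fraction: float
    low_anomaly: bool
    high_outlier_cells: list[str] = field(default_factory=list)
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "type_id": self.type_id,
            "n_cells": self.n_cells,
            "zero_fraction": self.zero_fraction,
            "low_anomaly": self.low_anomaly,
            "n_high_outliers": len(self.high_outlier_cells),
            "high_outlier_cells": "|".join(self.high_outlier_cells),
            "notes": self.notes,
        }


@dataclass
class StabilityReport:
    """Per-gene half-split correlation summaries.

    ``table`` has, per gene, the median and interquartile range of the
    Pearson correlation (across types) between type-mean signatures
    computed on disjoint random halves, over ``n_reps`` replicates.
    Constant genes have undefined correlation and NaN entries.
    """

    table: pd.DataFrame
    n_reps: int
    seed: int

    def category_summary(self, categories: pd.Series) -> pd.DataFrame:
        joined = self.table.join(categories.rename("category"), how="left")
        return joined.groupby("category")["median_r"].median().to_frame()


def within_type_histograms(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    gene: str,
    types: list[str],
) -> dict[str, np.ndarray]:
    """Raw per-cell CPM vectors for one gene in each requested type."""
    if matrix.unit != "CPM":
        raise FormatError("within_type_histograms expects a CPM matrix")
    gi = matrix.gene_index([gene])[0]
    type_of = annotation.table.loc[matrix.cell_ids, "type_id"]
    out = {}
    for t in types:
        idx = np.flatnonzero((type_of == t).to_numpy())
        if idx.size == 0:
            raise FormatError(f"type {t!r} has no cells")
        out[t] = matrix.values[gi, idx]
    return out


def select_display_types(signature_row: pd.Series) -> tuple[str, str]:
    """The max-mean type and the mid-range type whose mean is nearest
    25% of the maximum — the pair highlighted in within-type
    distribution displays."""
    mu_max = signature_row.max()
    if mu_max <= 0:
        raise FormatError("gene has no expression in any type")
    top = signature_row.idxmax()
    rest = signature_row.drop(top)
    mid = (rest - 0.25 * mu_max).abs().idxmin()
    return top, mid


def flag_outliers(
    values,
    config: OutlierConfig | None = None,
    gene: str = "",
    type_id: str = "",
    cell_ids: list[str] | None = None,
) -> DistributionDiagnostics:
    """Apply the high-outlier and low-anomaly rules to one subset."""
    config = config or OutlierConfig()
    v = np.asarray(values, dtype=float)
    if v.size < config.min_cells:
        raise FormatError(
            f"need at least {config.min_cells} cells, got {v.size}"
        )
    if cell_ids is None:
        cell_ids = [str(i) for i in range(v.size)]
    log_v = np.log2(v + 1.0)
    q1, q3 = np.percentile(log_v, [25, 75])  # linear interpolation
    fence = q3 + config.iqr_factor * (q3 - q1)
    high_idx = np.flatnonzero(log_v > fence)
    zero_fraction = float(np.mean(v == 0))
    nonzero = v[v > 0]
    nonzero_median = float(np.median(nonzero)) if nonzero.size else 0.0
    low_anomaly = (
        zero_fraction > config.zero_fraction
        and nonzero_median > config.expression_threshold
    )
    notes = []
    if high_idx.size:
        notes.append(f"{high_idx.size} high-CPM outlier(s)")
    if low_anomaly:
        notes.append(
            f"zero fraction {zero_fraction:.2f} with nonzero median "
            f"{nonzero_median:.1f}"
        )
    return DistributionDiagnostics(
        gene=gene,
        type_id=type_id,
        n_cells=int(v.size),
        zero_fraction=zero_fraction,
        low_anomaly=bool(low_anomaly),
        high_outlier_cells=[cell_ids[i] for i in high_idx],
        notes="; ".join(notes),
    )


def subsample_stability(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    genes: list[str] | None = None,
    n_reps: int = 50,
    seed: int = 0,
    split_labels: pd.Series | None = None,
) -> StabilityReport:
    """Half-split stability of type-mean signatures.

    Per replicate, the cells of every type are split into two disjoint
    random halves; signatures are recomputed on each half and, per
    gene, the Pearson correlation across types between the two half
    signatures is recorded.  Types with fewer than 2 cells are
    excluded (with a note in the report's attrs).

    ``split_labels`` overrides the random split with a fixed per-cell
    assignment to half "A" or "B" (one replicate); useful for designed
    splits such as separating duplicated cells.
    """
    if matrix.unit != "CPM":
        raise FormatError("subsample_stability expects a CPM matrix")
    if genes is not None:
        matrix = matrix.subset_genes(genes)
    rng = np.random.default_rng(seed)
    type_of = annotation.table.loc[matrix.cell_ids, "type_id"]
    by_type = {
        t: np.flatnonzero((type_of == t).to_numpy())
        for t in pd.unique(type_of)
    }
    usable = {t: idx for t, idx in by_type.items() if idx.size >= 2}
    skipped = sorted(set(by_type) - set(usable))
    if len(usable) < 2:
        raise FormatError("need at least 2 types with >= 2 cells each")
    types = list(usable)

    if split_labels is not None:
        n_reps = 1
        labels = split_labels.loc[matrix.cell_ids].to_numpy()
    corrs = np.empty((matrix.n_genes, n_reps))
    for rep in range(n_reps):
        mean_a = np.empty((matrix.n_genes, len(types)))
        mean_b = np.empty((matrix.n_genes, len(types)))
        for ti, t in enumerate(types):
            idx = usable[t]
            if split_labels is not None:
                half_a = idx[labels[idx] == "A"]
                half_b = idx[labels[idx] == "B"]
                if half_a.size == 0 or half_b.size == 0:
                    raise FormatError(f"type {t!r}: empty half under split_labels")
            else:
                perm = rng.permutation(idx)
                half = idx.size // 2
                half_a, half_b = perm[:half], perm[half : 2 * half]
            mean_a[:, ti] = matrix.values[:, half_a].mean(axis=1)
            mean_b[:, ti] = matrix.values[:, half_b].mean(axis=1)
        corrs[:, rep] = _rowwise_pearson(mean_a, mean_b)

    import warnings

    with warnings.catch_warnings():
        # constant genes yield all-NaN correlation rows by design
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pd.DataFrame(
            {
                "median_r": np.nanmedian(corrs, axis=1),
                "iqr_r": np.nanpercentile(corrs, 75, axis=1)
                - np.nanpercentile(corrs, 25, axis=1),
                "n_defined": np.sum(~np.isnan(corrs), axis=1),
            },
            index=matrix.gene_symbols,
        )
    table.attrs["skipped_types"] = skipped
    return StabilityReport(table=table, n_reps=n_reps, seed=seed)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows; NaN for zero-variance rows."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r
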