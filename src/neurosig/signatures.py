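"""CPM normalization, cell/gene filtering, type-mean signatures and the
delta type-specificity statistic.

A gene's *type-mean expression signature* is the vector of its mean CPM
values across the retained leaf neuron types.  Type specificity is
quantified per gene by

    delta = (n - sum_i mu_i / mu_max) / (n - 1)

where ``mu_i`` is the gene's mean CPM in type ``i``, ``mu_max`` the
largest of the ``n`` type means.  delta is 0 when all type means are
equal and 1 when expression is confined to a single type; it is
invariant to positive rescaling and to permutation of types, and is
mathematically the tissue-specificity index tau applied to neuron
types.  Genes with ``mu_max == 0`` have no defined delta and are
flagged rather than coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellAnnotation, ExpressionMatrix, FormatError, GenePanel, Taxonomy

__all__ = [
    "FilterSpec",
    "SignatureMatrix",
    "DeltaTable",
    "to_cpm",
    "select_cells",
    "type_means",
    "delta",
    "delta_profile",
    "filter_genes",
    "order_by_delta",
]


@dataclass
class FilterSpec:
    """Cell- and gene-level filtering thresholds.

    ``min_cells_per_type`` is inclusive (a type with exactly the
    minimum is kept); ``expression_threshold`` is strict (a gene is
    "expressed" only when some type mean is strictly greater).
    """

    region: str = "CA1"
    min_cells_per_type: int = 16
    expression_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.min_cells_per_type < 1 or self.expression_threshold < 0:
            raise FormatError("filter thresholds must be positive")


@dataclass
class SignatureMatrix:
    """Gene x type matrix of type-mean CPM values."""

    means: pd.DataFrame  # index gene symbol, columns type_id
    cells_per_type: pd.Series

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.means.index)

    @property
    def type_ids(self) -> list[str]:
        return list(self.means.columns)

    @property
    def n_types(self) -> int:
        return self.means.shape[1]

    def subset_genes(self, symbols) -> "SignatureMatrix":
        return SignatureMatrix(self.means.loc[list(symbols)], self.cells_per_type)


@dataclass
class DeltaTable:
    """Per-gene delta statistic with the row maximum it was computed from.

    Columns: ``delta``, ``mu_max``, ``log10_rowmax``, ``defined`` and
    (when a panel was supplied) ``category``.  ``delta`` is NaN and
    ``defined`` False for all-zero signatures.
    """

    table: pd.DataFrame
    cascade: dict[str, int] = field(default_factory=dict)

    @property
    def symbols(self) -> list[str]:
        return list(self.table.index)

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["defined"]]


def to_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize each cell to counts per million over all genes present.

    Every cell column of the result sums to 1e6.  The denominator is
    the cell's total over *all* genes in the input matrix, so any
    panel subsetting must happen after normalization, never before.
    Idempotent on CPM input; raises listing the offenders if any cell
    has zero total counts.
    """
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [matrix.cell_ids[i] for i in zero[:10]]
        raise FormatError(f"cells with zero total counts: {bad}")
    values = matrix.values * (1e6 / totals[None, :])
    return ExpressionMatrix(values, matrix.gene_symbols, matrix.cell_ids, unit="CPM")


def select_cells(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    taxonomy: Taxonomy,
    spec: FilterSpec,
):
    """Keep cells from the target region in sufficiently sampled types.

    A leaf type is retained when at least ``min_cells_per_type`` of the
    region's cells map to it (inclusive boundary).  Returns the reduced
    ``(matrix, annotation, retained_types)`` with types in taxonomy
    order.
    """
    tab = annotation.table.loc[[c for c in matrix.cell_ids if c in annotation.table.index]]
    if len(tab) != matrix.n_cells:
        missing = sorted(set(matrix.cell_ids) - set(annotation.table.index))
        raise FormatError(f"cells without annotation: {missing[:10]}")
    in_region = tab[tab["region"] == spec.region]
    counts = in_region["type_id"].value_counts()
    retained_types = [
        t
        for t in taxonomy.type_ids
        if counts.get(t, 0) >= spec.min_cells_per_type
    ]
    if not retained_types:
        raise FormatError(
            f"no type has >= {spec.min_cells_per_type} cells in region "
            f"{spec.region!r}"
        )
    keep = in_region.index[in_region["type_id"].isin(retained_types)]
    return (
        matrix.subset_cells(list(keep)),
        CellAnnotation(tab.loc[keep].copy()),
        retained_types,
    )


def type_means(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    retained_types: list[str],
) -> SignatureMatrix:
    """Untrimmed arithmetic mean CPM per gene per leaf type.

    Trimmed or winsorized means are deliberately not offered: type
    means must remain sensitive to genuine within-type heterogeneity,
    and outlying cells are surfaced separately by the robustness
    diagnostics.
    """
    if matrix.unit != "CPM":
        raise FormatError("type_means expects a CPM matrix; call to_cpm first")
    types = annotation.table.loc[matrix.cell_ids, "type_id"]
    means = {}
    n_cells = {}
    for t in retained_types:
        idx = np.flatnonzero((types == t).to_numpy())
        if idx.size == 0:
            raise FormatError(f"retained type {t!r} has no cells")
        means[t] = matrix.values[:, idx].mean(axis=1)
        n_cells[t] = int(idx.size)
    df = pd.DataFrame(means, index=matrix.gene_symbols)[retained_types]
    return SignatureMatrix(df, pd.Series(n_cells)[retained_types])


def delta(signature_row) -> float:
    """The delta type-specificity statistic for one signature vector.

    Returns ``(n - sum_i mu_i/mu_max) / (n - 1)``; NaN when all means
    are zero (mu_max = 0 leaves the statistic undefined).
    """
    mu = np.asarray(signature_row, dtype=float)
    if mu.ndim != 1 or mu.size < 2:
        raise FormatError("delta needs a 1-D vector of at least 2 type means")
    if np.any(mu < 0):
        raise FormatError("type means must be non-negative")
    mu_max = mu.max()
    if mu_max == 0:
        return float("nan")
    n = mu.size
    # divide before summing: uniform and one-hot profiles then hit the
    # 0 and 1 endpoints exactly in floating point
    return float((n - np.sum(mu / mu_max)) / (n - 1))


def delta_profile(means: pd.DataFrame) -> pd.DataFrame:
    """Vectorized delta over the rows of a gene x type mean matrix."""
    values = means.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise FormatError("delta needs at least 2 types")
    if np.any(values < 0):
        raise FormatError("type means must be non-negative")
    mu_max = values.max(axis=1)
    n = values.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (n - (values / mu_max[:, None]).sum(axis=1)) / (n - 1)
        log_rowmax = np.log10(mu_max)
    defined = mu_max > 0
    d = np.where(defined, d, np.nan)
    log_rowmax = np.where(defined, log_rowmax, np.nan)
    return pd.DataFrame(
        {
            "delta": d,
            "mu_max": mu_max,
            "log10_rowmax": log_rowmax,
            "defined": defined,
        },
        index=means.index,
    )


def filter_genes(
    signature: SignatureMatrix,
    panel: GenePanel | None = None,
    spec: FilterSpec | None = None,
) -> tuple[SignatureMatrix, DeltaTable]:
    """Keep genes expressed above threshold in at least one type.

    A gene is retained when its maximum type mean is strictly greater
    than ``spec.expression_threshold``.  When a panel is supplied the
    candidate set is the panel (symbols absent from the signature are
    reported in the cascade, not fatal) and the panel's category is
    carried into the delta table.  The cascade records
    candidates -> detected -> retained counts.
    """
    spec = spec or FilterSpec()
    if panel is not None:
        candidates = panel.symbols
        present = [s for s in candidates if s in signature.means.index]
        missing = [s for s in candidates if s not in signature.means.index]
    else:
        candidates = list(signature.means.index)
        present, missing = candidates, []
    sub = signature.means.loc[present]
    stats = delta_profile(sub) if len(sub) else pd.DataFrame(
        columns=["delta", "mu_max", "log10_rowmax", "defined"]
    )
    keep = stats.index[stats["mu_max"] > spec.expression_threshold]
    retained = SignatureMatrix(sub.loc[keep], signature.cells_per_type)
    table = stats.loc[keep].copy()
    if panel is not None:
        cat = panel.table.set_index("symbol")["category"]
        table["category"] = cat.reindex(table.index)
    cascade = {
        "candidates": len(candidates),
        "detected": len(present),
        "retained": int(len(keep)),
        "missing_symbols": len(missing),
    }
    return retained, DeltaTable(table, cascade=cascade)


def order_by_delta(table: DeltaTable) -> list[str]:
    """Gene symbols in descending-delta display order.

    Stable sort; ties broken by descending ``mu_max`` then ascending
    symbol.  Genes with undefined delta are excluded.
    """
    df = table.defined()
    ordered = df.sort_values(
        by=["delta", "mu_max"],
        ascending=[False, False],
        kind="mergesort",
    )
    # resolve residual ties on (delta, mu_max) lexicographically
    ordered = ordered.assign(_sym=ordered.index).sort_values(
        by=["delta", "mu_max", "_sym"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return list(ordered.index)
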