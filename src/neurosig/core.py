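"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on four objects: a gene-by-cell expression matrix
(raw counts or CPM), a four-level neuron taxonomy (class -> subclass ->
supertype -> type), a per-cell annotation tying each cell to a brain
region and a root-to-leaf taxonomic path, and curated gene panels
(categories of neuromodulatory genes with optional transduction
preference and cognate-group keys linking neuropeptide precursors to
their receptors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "Taxonomy",
    "CellAnnotation",
    "GenePanel",
    "LEVELS",
    "PANEL_CATEGORIES",
    "PEPTIDERGIC_CATEGORIES",
    "TRANSDUCTION_PREFERENCES",
    "NT_CLASSES",
]

#: taxonomy levels from root to leaf, as annotation column names
LEVELS = ("class_id", "subclass_id", "supertype_id", "type_id")

#: recognised gene-panel categories
PANEL_CATEGORIES = frozenset(
    {
        "monoamine_GPCR",
        "small_molecule_GPCR",
        "NP_GPCR",
        "NPP",
        "G_protein",
        "Na_channel",
        "Ca_channel",
        "K_channel",
        "ligand_gated_channel",
        "other",
    }
)

#: categories for which a cognate_group key is meaningful
PEPTIDERGIC_CATEGORIES = frozenset({"NPP", "NP_GPCR"})

#: G-protein coupling preferences of GPCRs
TRANSDUCTION_PREFERENCES = frozenset({"Gi/o", "Gs", "Gq/11"})

#: the two top-level neurotransmitter classes
NT_CLASSES = ("GABAergic", "glutamatergic")


class FormatError(ValueError):
    """Raised when an input file or container violates its contract."""


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """A gene x cell matrix of non-negative expression values.

    ``unit`` is always explicit: ``"counts"`` for raw (integer) read
    counts, ``"CPM"`` for counts-per-million-normalized values where
    every cell column sums to 1e6.
    """

    values: np.ndarray
    gene_symbols: list[str]
    cell_ids: list[str]
    unit: str

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=float)
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_symbols):
            raise FormatError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} rows"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(f"{len(self.cell_ids)} cell IDs for {n_cells} columns")
        _check_unique(self.gene_symbols, "gene symbols")
        _check_unique(self.cell_ids, "cell IDs")
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.gene_symbols[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )
        if self.unit not in ("counts", "CPM"):
            raise FormatError(f"unknown unit {self.unit!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        """Row indices of ``symbols``; raises on unknown symbols."""
        lookup = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def subset_genes(self, symbols) -> "ExpressionMatrix":
        idx = self.gene_index(symbols)
        return ExpressionMatrix(
            self.values[idx, :], list(symbols), list(self.cell_ids), self.unit
        )

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:10]}")
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_symbols), list(cell_ids), self.unit
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_symbols, columns=self.cell_ids
        )


@dataclass
class Taxonomy:
    """A four-level neuron taxonomy described by its leaves.

    ``leaves`` is indexed by leaf ``type_id`` with columns
    ``supertype_id``, ``subclass_id``, ``class_id`` and
    ``neurotransmitter`` (GABAergic or glutamatergic).  ``colors`` maps
    any taxon identifier (at any level) to a display color.
    """

    leaves: pd.DataFrame
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"supertype_id", "subclass_id", "class_id", "neurotransmitter"}
        missing = required - set(self.leaves.columns)
        if missing:
            raise FormatError(f"taxonomy missing columns: {sorted(missing)}")
        _check_unique(self.leaves.index, "leaf type IDs")
        # each non-leaf taxon must have a unique parent
        for child, parent in (
            ("supertype_id", "subclass_id"),
            ("subclass_id", "class_id"),
        ):
            parents = self.leaves.groupby(child, sort=False)[parent].nunique()
            bad = parents[parents > 1].index.tolist()
            if bad:
                raise FormatError(
                    f"taxa with more than one parent at {child}: {bad}"
                )
        bad_nt = set(self.leaves["neurotransmitter"]) - set(NT_CLASSES)
        if bad_nt:
            raise FormatError(f"unknown neurotransmitter classes: {sorted(bad_nt)}")

    @property
    def type_ids(self) -> list[str]:
        return list(self.leaves.index)

    @property
    def n_types(self) -> int:
        return len(self.leaves)

    def taxa_at(self, level: str) -> list[str]:
        if level == "type_id":
            return self.type_ids
        return list(pd.unique(self.leaves[level]))

    def path(self, type_id: str) -> dict[str, str]:
        """Root-to-leaf path for one leaf, keyed by level name."""
        row = self.leaves.loc[type_id]
        return {
            "class_id": row["class_id"],
            "subclass_id": row["subclass_id"],
            "supertype_id": row["supertype_id"],
            "type_id": type_id,
        }

    def nt_class(self, type_id: str) -> str:
        return self.leaves.loc[type_id, "neurotransmitter"]


@dataclass
class CellAnnotation:
    """Per-cell region and taxonomic assignment.

    ``table`` is indexed by cell ID with columns ``region`` plus the
    four taxonomy levels.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region", *LEVELS}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "cell IDs")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def validate_against(self, taxonomy: Taxonomy) -> None:
        """Reject cells whose taxonomic path is inconsistent with ``taxonomy``."""
        for cell, row in self.table.iterrows():
            t = row["type_id"]
            if t not in taxonomy.leaves.index:
                raise FormatError(f"cell {cell!r}: unknown type {t!r}")
            expected = taxonomy.path(t)
            for level in ("supertype_id", "subclass_id", "class_id"):
                if row[level] != expected[level]:
                    raise FormatError(
                        f"cell {cell!r}: {level} {row[level]!r} is not the "
                        f"ancestor of type {t!r} (expected {expected[level]!r})"
                    )

    def cells_in(self, region: str | None = None, type_id: str | None = None):
        mask = pd.Series(True, index=self.table.index)
        if region is not None:
            mask &= self.table["region"] == region
        if type_id is not None:
            mask &= self.table["type_id"] == type_id
        return list(self.table.index[mask])


@dataclass
class GenePanel:
    """A curated gene list with category metadata.

    ``table`` has columns ``symbol``, ``category``, ``subcategory``,
    ``transduction_preference`` and ``cognate_group``; the latter two
    may be empty.  ``cognate_group`` links neuropeptide precursor (NPP)
    genes to the NP-GPCR genes encoding their receptors.
    """

    table: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        if "symbol" not in self.table.columns or "category" not in self.table.columns:
            raise FormatError("gene panel needs 'symbol' and 'category' columns")
        tab = self.table.copy()
        for col in ("subcategory", "transduction_preference", "cognate_group"):
            if col not in tab.columns:
                tab[col] = ""
            tab[col] = tab[col].fillna("").astype(str)
        tab["symbol"] = tab["symbol"].astype(str)
        tab["category"] = tab["category"].astype(str)
        _check_unique(tab["symbol"], f"symbols in panel {self.name!r}")
        bad = set(tab["category"]) - PANEL_CATEGORIES
        if bad:
            raise FormatError(f"unknown panel categories: {sorted(bad)}")
        bad_td = set(tab["transduction_preference"]) - TRANSDUCTION_PREFERENCES - {""}
        if bad_td:
            raise FormatError(f"unknown transduction preferences: {sorted(bad_td)}")
        offenders = tab[
            (tab["cognate_group"] != "")
            & (~tab["category"].isin(PEPTIDERGIC_CATEGORIES))
        ]
        if len(offenders):
            raise FormatError(
                "cognate_group set on non-peptidergic genes: "
                f"{offenders['symbol'].tolist()[:10]}"
            )
        self.table = tab.reset_index(drop=True)

    @property
    def symbols(self) -> list[str]:
        return list(self.table["symbol"])

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, category: str) -> "GenePanel":
        sub = self.table[self.table["category"] == category]
        return GenePanel(sub.copy(), name=f"{self.name or 'panel'}:{category}")
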