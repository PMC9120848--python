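"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel either as MatrixMarket coordinate files
(with side-car gene and cell ID lists) or as dense CSV with genes as
rows.  Annotations, taxonomies and gene panels are plain CSV/TSV.
Everything is validated on read; malformed records raise
:class:`~neurosig.core.FormatError` naming the offender.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .core import (
    LEVELS,
    CellAnnotation,
    ExpressionMatrix,
    FormatError,
    GenePanel,
    Taxonomy,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_gene_panel",
    "write_gene_panel",
    "read_taxonomy",
    "write_taxonomy",
]

_ANNOT_COLS = ["region", "type_id", "supertype_id", "subclass_id", "class_id"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_expression(
    path,
    format: str = "csv",
    unit: str = "counts",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a gene x cell matrix from ``csv`` or ``mtx`` format.

    For ``mtx``, ``path`` is the ``.mtx`` file and gene/cell identifier
    lists are expected beside it as ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` (one ID per line).  ``transpose=True`` accepts
    cell x gene orientation on disk and transposes on read.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        values = df.to_numpy()
        genes, cells = list(df.index), list(df.columns)
    elif format == "mtx":
        try:
            mat = spio.mmread(path)
        except ValueError as err:
            detail = _locate_bad_mtx_entry(path) or str(err)
            raise FormatError(f"{path}: malformed MatrixMarket file: {detail}") from err
        genes = _read_id_list(path.parent / (path.stem + ".genes.txt"))
        cells = _read_id_list(path.parent / (path.stem + ".cells.txt"))
        values = np.asarray(sp.coo_matrix(mat).todense())
    else:
        raise FormatError(f"unknown expression format {format!r}")
    if transpose:
        values = values.T
        genes, cells = cells, genes
    if values.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{path}: matrix shape {values.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return ExpressionMatrix(values, genes, cells, unit=unit)


def _locate_bad_mtx_entry(path: Path) -> str | None:
    """Find the first coordinate entry outside the declared shape, if any."""
    shape = None
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("%") or not line.strip():
                    continue
                fields = line.split()
                if shape is None:
                    shape = (int(fields[0]), int(fields[1]))
                    continue
                i, j = int(fields[0]), int(fields[1])
                if not (1 <= i <= shape[0] and 1 <= j <= shape[1]):
                    return (
                        f"line {lineno}: coordinate ({i}, {j}) exceeds "
                        f"declared shape {shape}"
                    )
    except (OSError, ValueError, IndexError):
        return None
    return None


def _read_id_list(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing identifier list {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_expression(matrix: ExpressionMatrix, path, format: str = "csv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        matrix.to_frame().to_csv(path, sep=_sep_for(path))
    elif format == "mtx":
        coo = sp.coo_matrix(matrix.values)
        spio.mmwrite(str(path), coo)
        (path.parent / (path.stem + ".genes.txt")).write_text(
            "\n".join(matrix.gene_symbols) + "\n"
        )
        (path.parent / (path.stem + ".cells.txt")).write_text(
            "\n".join(matrix.cell_ids) + "\n"
        )
    else:
        raise FormatError(f"unknown expression format {format!r}")


def read_annotation(path, taxonomy: Taxonomy | None = None):
    """Read a per-cell annotation CSV; returns ``(Taxonomy, CellAnnotation)``.

    The table must carry ``cell_id``, ``region`` and the four taxonomy
    level columns, plus ``neurotransmitter``.  The taxonomy is derived
    from the unique root-to-leaf paths; a leaf appearing with two
    different ancestors is an inconsistency and raises.  If a
    ``taxonomy`` is supplied the annotation is validated against it
    instead of deriving one.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"cell_id", "region", *LEVELS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    df = df.set_index("cell_id")
    annotation = CellAnnotation(df[_ANNOT_COLS].copy())
    if taxonomy is None:
        if "neurotransmitter" not in df.columns:
            raise FormatError(
                f"{path}: need a 'neurotransmitter' column to derive a taxonomy"
            )
        taxonomy = _derive_taxonomy(df)
    annotation.validate_against(taxonomy)
    return taxonomy, annotation


def _derive_taxonomy(df: pd.DataFrame) -> Taxonomy:
    cols = ["supertype_id", "subclass_id", "class_id", "neurotransmitter"]
    paths = df[["type_id", *cols]].drop_duplicates()
    dup = paths["type_id"].duplicated()
    if dup.any():
        bad = paths.loc[dup, "type_id"].tolist()
        raise FormatError(f"inconsistent taxonomic paths for types: {bad}")
    leaves = paths.set_index("type_id")[cols]
    return Taxonomy(leaves)


def write_annotation(
    annotation: CellAnnotation, taxonomy: Taxonomy, path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = annotation.table.copy()
    out["neurotransmitter"] = [
        taxonomy.nt_class(t) for t in out["type_id"]
    ]
    out.index.name = "cell_id"
    out.to_csv(path, sep=_sep_for(path))


def read_taxonomy(path) -> Taxonomy:
    """Read a taxonomy leaf table (one row per leaf type, with colors)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "type_id" not in df.columns:
        raise FormatError(f"{path}: taxonomy table needs a 'type_id' column")
    leaves = df.set_index("type_id")
    colors = {}
    if "color" in leaves.columns:
        colors = {t: c for t, c in leaves["color"].items() if isinstance(c, str)}
        leaves = leaves.drop(columns=["color"])
    return Taxonomy(leaves, colors=colors)


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = taxonomy.leaves.copy()
    if taxonomy.colors:
        out["color"] = [taxonomy.colors.get(t, "") for t in out.index]
    out.index.name = "type_id"
    out.to_csv(path, sep=_sep_for(path))


def read_gene_panel(path, name: str | None = None) -> GenePanel:
    """Read a curated gene panel CSV (symbol, category, subcategory,
    transduction_preference, cognate_group)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return GenePanel(df, name=name or path.stem)


def write_gene_panel(panel: GenePanel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.table.to_csv(path, sep=_sep_for(path), index=False)


def write_signature(signature, path) -> None:
    """Signature matrix as genes x types CSV; cell counts in the header
    row are stored beside it as ``<stem>.cells_per_type.csv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = signature.means.copy()
    out.index.name = "symbol"
    out.to_csv(path, sep=_sep_for(path))
    cpt = signature.cells_per_type.rename("n_cells")
    cpt.index.name = "type_id"
    cpt.to_csv(path.parent / (path.stem + ".cells_per_type.csv"))


def read_signature(path):
    from .signatures import SignatureMatrix

    path = Path(path)
    means = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    cpt_path = path.parent / (path.stem + ".cells_per_type.csv")
    if cpt_path.exists():
        cpt = pd.read_csv(cpt_path, index_col=0)["n_cells"]
    else:
        cpt = pd.Series(np.nan, index=means.columns)
    return SignatureMatrix(means, cpt)


def write_delta_table(delta_table, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = delta_table.table.copy()
    out.index.name = "symbol"
    out.to_csv(path, sep=_sep_for(path))


def read_delta_table(path):
    from .signatures import DeltaTable

    path = Path(path)
    return DeltaTable(pd.read_csv(path, sep=_sep_for(path), index_col=0))


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
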