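import numpy as np
import pandas as pd
import pytest

import neurosig as ns


@pytest.fixture(scope="session")
def small_cfg():
    """An 8-type hierarchy small enough for fast unit tests."""
    return ns.SimConfig(
        n_classes=2,
        n_subclasses=3,
        n_supertypes=5,
        n_types=8,
        cells_per_type=(16, 40),
        n_genes={
            "one_type_marker": 8,
            "supertype_program": 5,
            "class_restricted": 4,
            "ubiquitous": 10,
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    taxonomy = ns.simulate_taxonomy(small_cfg)
    matrix, annotation, truth = ns.simulate_cells(small_cfg, taxonomy)
    return taxonomy, matrix, annotation, truth


@pytest.fixture(scope="session")
def recovery_dataset():
    """Full-size planted dataset: 42 types, 100 cells per type."""
    cfg = ns.SimConfig(cells_per_type=(100, 100), dispersion=0.5, seed=11)
    taxonomy = ns.simulate_taxonomy(cfg)
    matrix, annotation, truth = ns.simulate_cells(cfg, taxonomy)
    return taxonomy, matrix, annotation, truth


@pytest.fixture(scope="session")
def recovery_signature(recovery_dataset):
    taxonomy, matrix, annotation, truth = recovery_dataset
    cpm = ns.to_cpm(matrix)
    cpm, annotation, retained = ns.select_cells(
        cpm, annotation, taxonomy, ns.FilterSpec()
    )
    signature = ns.type_means(cpm, annotation, retained)
    filtered, delta_table = ns.filter_genes(signature)
    return cpm, annotation, signature, filtered, delta_table


def make_panel(rows, name="test"):
    """Build a GenePanel from (symbol, category[, subcat, transduction,
    cognate]) tuples."""
    columns = [
        "symbol",
        "category",
        "subcategory",
        "transduction_preference",
        "cognate_group",
    ]
    records = []
    for row in rows:
        padded = list(row) + [""] * (5 - len(row))
        records.append(dict(zip(columns, padded)))
    return ns.GenePanel(pd.DataFrame(records, columns=columns), name=name)


@pytest.fixture()
def npp_panel():
    """18 NPP genes paired one-to-one with 18 cognate receptors."""
    rows = []
    for i in range(18):
        rows.append((f"Npp{i}", "NPP", "", "", f"G{i}"))
        rows.append((f"Npr{i}", "NP_GPCR", "", "Gi/o", f"G{i}"))
    return make_panel(rows, name="npp")
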