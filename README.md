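# neurosig

Neurotaxonomic expression signatures and the delta type-specificity
statistic for single-cell RNA-seq.

Deep transcriptomic surveys of mouse hippocampal CA1 assign each
sampled neuron to a leaf type of a hierarchical neurotaxonomy
(class → subclass → supertype → type). `neurosig` is for analysts who
have such a taxonomy plus a gene × cell count matrix and want to ask:
which neuromodulatory genes — GPCRs, G proteins, ion channel subunits,
neuropeptide precursors (NPPs) — are expressed in which neuron types,
how type-specific is each gene, how many of them do single cells
co-express, and are expressed neuropeptide genes accompanied by
expressed cognate receptor genes?

The pipeline: CPM normalization → region/type cell filtering →
per-type mean **expression signatures** → strict >10 CPM gene
filtering → the **delta** statistic

```
delta = (n − Σᵢ μᵢ/μ_max) / (n − 1)
```

where μᵢ is a gene's mean CPM in type *i* of *n* retained types and
μ_max the largest of them. delta ranges from 0 (uniform across types)
to 1 (expressed in a single type) and is the tissue-specificity index
τ applied to neuron types. Around this core: per-cell co-expression
tallies with GABAergic/glutamatergic splits, cognate NPP↔NP-GPCR
pairing, within-type outlier/zero-anomaly diagnostics, half-split
subsampling stability, standard-format heatmap/histogram figures, and
a synthetic generator with planted ground truth that makes every stage
testable without external downloads. See `docs/methods.md` for the
full model description.

## Worked example

Simulate a 42-type dataset with planted specificity classes and run
the signature stage:

```python
import neurosig as ns
from scipy.stats import spearmanr

cfg = ns.SimConfig(cells_per_type=(100, 100), seed=11)
taxonomy = ns.simulate_taxonomy(cfg)
matrix, annotation, truth = ns.simulate_cells(cfg, taxonomy)

cpm = ns.to_cpm(matrix)
cpm, annotation, retained = ns.select_cells(cpm, annotation, taxonomy,
                                            ns.FilterSpec())
signature = ns.type_means(cpm, annotation, retained)
filtered, deltas = ns.filter_genes(signature)

print("cascade:", deltas.cascade)
for cls in ("one_type_marker", "supertype_program",
            "class_restricted", "ubiquitous"):
    d = deltas.table.loc[truth.symbols_of(cls), "delta"]
    print(f"{cls:18s} mean delta = {d.mean():.3f}")
rank = truth.specificity_rank().loc[deltas.table.index]
print("Spearman(planted rank, delta) =",
      round(spearmanr(rank, deltas.table["delta"]).statistic, 3))
```

prints

```
cascade: {'candidates': 112, 'detected': 112, 'retained': 112, 'missing_symbols': 0}
one_type_marker    mean delta = 1.000
supertype_program  mean delta = 0.908
class_restricted   mean delta = 0.544
ubiquitous         mean delta = 0.159
Spearman(planted rank, delta) = 0.981
```

All 112 planted genes pass the >10 CPM filter; genes planted as
one-type markers recover delta = 1.000 (their profiles are one-hot),
broader planted programs land at intermediate delta, flat ubiquitous
genes near 0, and the estimated delta ranks the planted specificity
classes almost perfectly (Spearman 0.98).

The same workflow is available from the shell:

```sh
neurosig simulate --seed 11 --out run/sim
neurosig signatures --matrix run/sim/matrix.csv \
    --annotation run/sim/annotation.csv --out run/sig
neurosig coexpress --matrix run/sim/matrix.csv \
    --annotation run/sim/annotation.csv --panel panel.csv --out run/coex
neurosig pair --signature run/sig/signature.csv --panel panel.csv \
    --out run/pair
neurosig robustness --matrix run/sim/matrix.csv \
    --annotation run/sim/annotation.csv --out run/rob
neurosig plot --signature run/sig/signature.csv --delta run/sig/delta.csv \
    --taxonomy run/sim/taxonomy.csv --out run/figs
```

Every stage writes plain CSV/JSON plus a `manifest.json` recording its
parameters and seed; `plot` regenerates figures from the saved tables
alone.

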