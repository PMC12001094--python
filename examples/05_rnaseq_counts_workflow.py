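"""RNA-seq counts workflow: dispersion, precision weights, files on disk.

Counts are simulated with negative-binomial noise, written to disk in the
three input formats (matrix TSV, metadata TSV, GMT), read back, and
analyzed: the pipeline estimates per-gene NB dispersion, converts counts
to precision-weighted log2-CPM and fits the weighted mixed models.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from pathdose import (
    GeneSetSim,
    RunConfig,
    SimulationSpec,
    align_dataset,
    read_expression_matrix,
    read_gmt,
    read_metadata,
    results_table,
    run_pipeline,
    simulate_dataset,
    write_gmt,
)

# A broad flat background matters for counts: library-size (CPM)
# normalization divides by total counts, so with too few background genes
# the responsive genes' signal would bleed a spurious inverse trend into
# everything else (a compositional artifact real matrices dilute away).
spec = SimulationSpec(
    genesets=(
        GeneSetSim("dose_responsive", 10, "sigmoid", 2.0),
        GeneSetSim("unaffected", 10, "flat", 0.0),
        GeneSetSim("background", 300, "flat", 0.0),
    ),
    omics_type="counts", nb_dispersion=0.08, beta0=7.0, seed=29,
)
dataset, collection, _ = simulate_dataset(spec)

workdir = Path(tempfile.mkdtemp())
dataset.expression.astype(int).to_csv(workdir / "counts.tsv", sep="\t")
pd.DataFrame({"sample": dataset.samples, "dose": np.asarray(dataset.doses)}).to_csv(
    workdir / "meta.tsv", sep="\t", index=False
)
write_gmt(collection, workdir / "sets.gmt")

matrix = read_expression_matrix(workdir / "counts.tsv", omics_type="counts")
meta = read_metadata(workdir / "meta.tsv")
sets = read_gmt(workdir / "sets.gmt")
ds = align_dataset(matrix, meta, omics_type="counts")

result = run_pipeline(
    ds, sets, RunConfig(omics_type="counts", log10_dose=True, n_boot=100, seed=2)
)
phi = result.transformed.dispersion
print(f"median estimated NB dispersion: {np.median(phi):.3f} "
      f"(simulated with 0.08)")
df = results_table(result)
show = df[df.geneset.isin(["dose_responsive", "unaffected"])]
print(show[["geneset", "status", "best_model", "adj_p", "bmd"]]
      .round(4).to_string(index=False))
print("\nThe dose-responsive set is detected from raw counts; the flat set")
print("stays at the null model. BMD is in the original concentration units.")
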