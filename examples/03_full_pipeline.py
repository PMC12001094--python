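"""End-to-end analysis of a synthetic multi-pathway experiment.

Five dose-responsive pathways of different shapes plus twenty flat ones,
analyzed with the complete workflow: pre-filters, model fitting and
selection, Benjamini-Hochberg correction, and BMD/TCD estimation with
bootstrap CIs for the significant pathways.
"""

from pathdose import (
    GeneSetSim,
    RunConfig,
    SimulationSpec,
    results_table,
    run_pipeline,
    simulate_dataset,
)

sets = tuple(
    [
        GeneSetSim("sigmoid_up", 12, "sigmoid", 2.0),
        GeneSetSim("bell_mid", 12, "bell", 2.0),
        GeneSetSim("u_dip", 12, "u_shape", 2.0),
        GeneSetSim("linear_up", 12, "linear", 2.0),
        GeneSetSim("antagonistic", 12, "antagonistic", 2.0),
    ]
    + [GeneSetSim(f"flat{i:02d}", 12, "flat", 0.0) for i in range(20)]
)
spec = SimulationSpec(genesets=sets, seed=11)
dataset, collection, _ = simulate_dataset(spec)

config = RunConfig(
    omics_type="log_intensity", log10_dose=True, n_boot=200, seed=5
)
result = run_pipeline(dataset, collection, config)

df = results_table(result)
cols = ["geneset", "status", "best_model", "p", "adj_p", "rmse", "bmd", "tcd1"]
print(df[df.status != "ok"][["geneset", "status"]].to_string(index=False))
print()
print(df[df.best_model != "null"][cols].round(4).to_string(index=False))
print(f"\n{result.summary['n_significant']} of {result.summary['n_fitted']} "
      "fitted gene sets respond to dose (BH-adjusted p < 0.05).")
print("The four coherent effect pathways are recovered; the antagonistic one")
print("is removed by the opposite-profiles filter; of the 20 flat pathways a")
print("few are dropped as invariant and at most one slips through the FDR")
print("gate, as expected at the 5% level. BMD/TCD1 are in dose units.")
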