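"""Fit the candidate dose-response models to one simulated pathway.

Generates a 12-gene pathway whose shared response to 8 half-log doses is
sigmoid, fits the four candidate mixed models (null, linear, spline fixed,
spline mixed), and prints the selection table.
"""

import numpy as np

from pathdose import (
    GeneSetSim,
    SimulationSpec,
    fit_pathway,
    simulate_dataset,
    transform_dataset,
)

spec = SimulationSpec(
    genesets=(GeneSetSim("estrogen_response", 12, "sigmoid", effect_size=2.0),),
    sigma=0.3,
    seed=42,
)
dataset, sets, _ = simulate_dataset(spec)
print(f"dataset: {dataset.n_features} genes x {dataset.n_samples} samples, "
      f"{dataset.n_dose_levels} dose levels")

transformed = transform_dataset(dataset, use_log10=True)
fitted = fit_pathway(transformed, sets["estrogen_response"])

print(f"\n{'model':<18}{'logLik':>10}{'AIC':>10}{'params':>8}{'LRT p':>12}")
for c in fitted.all_candidates:
    p = "" if c.lrt_p is None else f"{c.lrt_p:.2e}"
    print(f"{c.kind:<18}{c.log_likelihood:>10.2f}{c.aic:>10.2f}"
          f"{c.n_params:>8}{p:>12}")
print(f"\nselected: {fitted.best.kind}  (RMSE {fitted.rmse:.3f})")
print("The selected model is the lowest-AIC candidate whose likelihood-ratio")
print("test against the no-dose-effect null clears p < 0.05.")
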