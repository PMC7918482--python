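"""Compare pathway coverage of the proteome and acetylome between phases.

Coverage of a pathway is the fraction of its genome-encoded proteins
detected in a phase (quantified proteins for the proteome layer; proteins
with any acetylation site seen in at least one replicate for the acetylome
layer).  The log2 fold change compares stationary against exponential
coverage; an acetylome pathway with zero exponential coverage reports 0.
Stars come from two-tailed homoscedastic t-tests on per-replicate coverages
(* p<0.05, ** p<0.01, *** p<0.001).
"""

import pandas as pd

from acetylfq import RunConfig, SimulationConfig, build_truth, run_pipeline, simulate_experiment

truth = build_truth(SimulationConfig(n_proteins=400, n_pathways=8), seed=3)
experiment = simulate_experiment(truth, seed=4)
result = run_pipeline(
    RunConfig(),
    proteome_psms=experiment.proteome_psms,
    kac_psms=experiment.kac_psms,
    annotations=experiment.annotations,
)

for layer, table in result.pathway_tables.items():
    print(f"\n=== {layer} layer ===")
    show = table[["pathway", "n_genome", "coverage_exp", "coverage_stat", "log2fc", "p_value", "stars"]]
    with pd.option_context("display.float_format", "{:.3f}".format, "display.width", 120):
        print(show.to_string(index=False))
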