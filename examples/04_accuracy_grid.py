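"""A reduced pool-count x cell-fraction grid of restoration accuracies.

The full-scale default grid (p in {40, 27}, k in 10-30%, 3 replicates) is
what scripts/acceptance.py runs; this example uses one replicate per cell
of the grid to stay fast while showing the same trends.
"""

import poolcnv

res = poolcnv.run_grid(
    poolcnv.GeneratorConfig(),
    poolcnv.PipelineConfig(),
    p_list=[40, 27],
    k_list=[0.10, 0.20, 0.30],
    replicates=1,
    base_seed=1,
)
print(res.runs[["p", "k", "accuracy", "objective", "status"]].to_string(index=False))
print("\nmean accuracy by pool count:")
print(res.by_p.to_string(index=False))
# More pools (p=40, half the libraries of one-per-cell sequencing) restore
# more cells than fewer pools (p=27, a third of the libraries); the weakest
# setting is p=27 with k=10%, where pools carry too little overlap.
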