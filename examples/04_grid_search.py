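"""Grid search over the fusion weights alpha and beta.

alpha splits disease-neighborhood against miRNA-neighborhood evidence
inside the (1 - beta) share; beta is the weight of the pair-neighborhood
(SDMA) evidence. Each grid point re-runs the full leave-one-out protocol.
"""

from hcfmda import PipelineConfig, SyntheticSpec, grid_search, make_dataset

data = make_dataset(SyntheticSpec(n_diseases=30, n_mirnas=40, density=0.08, seed=2))
cfg = PipelineConfig(n_neighbors=8, k_pairs=8)

table, best = grid_search(
    data.assoc, data.dag, data.fm,
    alpha_grid=[0.1, 0.3, 0.5, 0.7, 0.9], beta_grid=[0.1], config=cfg,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nbest (alpha, beta) = {best}")
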