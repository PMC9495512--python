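"""Print the multiscale encoder's layer ledger and parameter totals.

Reproduces the published architecture arithmetic: per-layer output shapes
and trainable-parameter counts for the default three-stream network
(stem kernels 5, 7, 9), plus the totals of the other kernel combinations.
"""

from msres import MsResConfig, build_model, count_parameters, model_graph

graph = model_graph(MsResConfig())
print(graph.to_text())
print()

# Totals for the published kernel combinations; the default three-stream
# network closes at 158,401 trainable parameters.
for kernels in [(5, 7, 9), (3, 5), (5, 9), (3, 5, 7), (3, 5, 7, 9),
                (3, 5, 7, 9, 11), (5, 7, 9, 11, 13)]:
    total = count_parameters(MsResConfig(kernel_sizes=kernels))
    print(f"kernels {str(kernels):<20} -> {total:>8,} parameters")

# The executable network carries exactly the same number of weights.
model = build_model(MsResConfig(), seed=0)
print(f"\nexecutable model weight count: {model.num_parameters:,}")
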