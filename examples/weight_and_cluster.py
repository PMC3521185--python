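"""Full pipeline on a synthetic benchmark: weight, cluster, evaluate.

Generates a benchmark with planted complexes, learns the naive-Bayes edge
weights from a training split, keeps the top-weighted edges, clusters with
MCL and CMC, aggregates with the voting strategy, and reports precision-
recall AUC against the held-out complexes — alongside the unweighted
baseline for contrast.
"""

import swcnet as s
from swcnet.clustering import CMCParams, MCLParams, cmc, combine, mcl
from swcnet.evaluation import CVConfig, MatchCriterion, cluster_pr_curve, cv_split
from swcnet.synthgen import DEFAULT_SOURCES, SourceSpec, SynthParams

params = SynthParams(
    seed=11,
    n_proteins=600,
    n_complexes=50,
    sources=tuple(
        SourceSpec(x.name, bg_edges=3000, hub_presence=x.hub_presence)
        for x in DEFAULT_SOURCES
    ),
    n_transient_hubs=8,
)
reference, tables, _ = s.generate_benchmark(params)
network = s.assemble_composite(tables)
print(f"benchmark: {len(reference)} planted complexes, {network.n_edges} edges")

config = CVConfig(seed=11, rounds=1, k_grid=(2000,))
train, test = cv_split(reference, config, 0)
print(f"split: {len(train)} training / {len(test)} test complexes")

s.label_edges(network, train)
model = s.fit_naive_bayes(network, s.discretize_network(network))
s.weight_edges(network, model)
top = s.top_k_edges(network, 2000)

clusters = combine([mcl(top, MCLParams()), cmc(top, CMCParams())], top)
curve = cluster_pr_curve(clusters, test, train, MatchCriterion(0.5))
print(f"weighted pipeline:   {len(clusters)} clusters, PR AUC = {curve.auc:.3f}")

baseline = network.copy()
for _, data in baseline.edges():
    data["weight"] = 1.0
base_clusters = combine([mcl(baseline, MCLParams()), cmc(baseline, CMCParams())], baseline)
base_curve = cluster_pr_curve(base_clusters, test, train, MatchCriterion(0.5))
print(f"unweighted baseline: {len(base_clusters)} clusters, PR AUC = {base_curve.auc:.3f}")

# The supervised weights concentrate the top edges inside planted complexes,
# so clustering recovers far more held-out complexes than on the raw network.
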