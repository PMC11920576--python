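"""Over-representation analysis of the candidate genes.

Hypergeometric upper-tail test of the candidate SE genes against the
bundle's gene-set collection, BH-adjusted; rows with raw p <= 0.05 are
flagged significant.
"""

from secircuit import SimulationConfig, ora_test, simulate_bundle

bundle = simulate_bundle(SimulationConfig(seed=0))
candidates = list(bundle.manifest.roles.candidates)
universe = [g.gene_id for g in bundle.genes]

res = ora_test(candidates, bundle.gene_sets, universe, alpha=0.05)
print(res.to_string(index=False))
# overlap/set_size/query_size/universe_size are the hypergeometric
# parameters k, K, n, N; small p means the candidate set hits the gene
# set far more often than chance.
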