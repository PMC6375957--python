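"""Predict hosts for phage contigs by CRISPR spacers and k-mer likelihood.

CRISPR spacers are near-literal records of infection and take precedence;
contigs without spacer evidence fall back to an order-8 Markov model
likelihood with a decoy-based p-value gate.
"""

from viralrp import PipelineConfig, SimulationConfig, generate_dataset, predict_hosts

dataset = generate_dataset(SimulationConfig(n_hosts=10, n_contigs=50,
                                            rng_seed=7))
config = PipelineConfig()

predictions = predict_hosts(dataset.contigs, dataset.hosts, dataset.spacers,
                            config, decoy_genomes=dataset.decoy_hosts)

truth = dict(zip(dataset.truth_contigs.contig_id,
                 dataset.truth_contigs.host_id))
by_method = {"spacer": 0, "kmer": 0}
correct = 0
for cid, pred in predictions.items():
    by_method[pred.method] += 1
    correct += pred.host_id == truth[cid]

print(f"{len(predictions)}/{len(dataset.contigs)} contigs assigned a host "
      f"({by_method['spacer']} by spacer, {by_method['kmer']} by k-mer)")
print(f"{correct}/{len(predictions)} assignments match the true host")
example = next(iter(predictions.values()))
print(f"example: {example.contig_id} -> {example.host_id} "
      f"(method={example.method}, score={example.score:.4g}, "
      f"p={example.p_value if example.p_value is not None else 'n/a'})")
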