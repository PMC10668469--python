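"""Protein concordance and the tripartite miRNA -> mRNA -> protein network.

Proteins detected in every sample of both age groups are tested with a
Welch t on log2 abundances; proteins whose shift agrees in direction with
their mRNA's age slope extend anti-correlated edges into tripartite paths
(down-miRNA -> up-mRNA -> enriched protein, or the mirror image).
"""

from cardiomir import SimulationConfig, simulate_study, de, network
from cardiomir.io import filter_unique_features

study = simulate_study(SimulationConfig(seed=1))
small = filter_unique_features(study.smallrna)
de_small = de.fit_nb_continuous(small, study.samples)
de_mrna = de.fit_nb_continuous(study.mrna, study.samples)

sig = lambda t: list(t.index[(t["padj"].astype(float) < 0.05) & t["padj"].notna()])
de_mirnas = [f for f in sig(de_small)
             if small.annotations.at[f, "subtype"] == "miRNA"]
norm_s = de.normalize_counts(small, de.estimate_size_factors(small), log2=True)
norm_m = de.normalize_counts(study.mrna, de.estimate_size_factors(study.mrna),
                             log2=True)
pairs = network.candidate_pairs(de_mirnas, sig(de_mrna), study.target_map)
kept = network.filter_anticorrelated(network.correlate_pairs(
    pairs, norm_s, norm_m, study.shared_samples))

common = network.common_protein_filter(*study.protein_groups.values())
pde = de.fit_two_group(common, study.protein_group_labels)
n_diff = int((pde["p"].astype(float) < 0.05).sum())
print(f"proteins detected in all six samples: {len(common)} "
      f"(of {len(study.truth.proteins)} measured)")
print(f"differentially abundant between weeks 10 and 18 (p<0.05): {n_diff}")

id_map = {p: p.removeprefix("prot_") for p in common.index}
conc = network.concordant_pairs(pde, de_mrna, alpha=0.05, id_map=id_map)
print(f"direction-concordant with their mRNA: {len(conc)} "
      f"({(conc['direction'] == 'up').sum()} enriched, "
      f"{(conc['direction'] == 'down').sum()} depleted)")

for polarity, story in (
        ("down-miR:up-mRNA:enriched",
         "released targets accumulate as their miRNAs fade"),
        ("up-miR:down-mRNA:depleted",
         "rising miRNAs drive their targets and proteins down")):
    nodes, edges = network.build_tripartite(kept, conc, de_small, polarity)
    n_paths = (edges["kind"] == "encodes").sum() if len(edges) else 0
    print(f"\n{polarity}: {len(nodes)} nodes, {len(edges)} edges "
          f"({story}).")
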