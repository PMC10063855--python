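"""Over-representation analysis of a signature against GMT gene sets.

One set is planted to contain the informative genes; the hypergeometric
upper-tail test with BH FDR should rank it first.
"""

from ahrfsig import generate_gene_sets, ora, pathway_gene_counts

universe = [f"G{i:04d}" for i in range(1, 1001)]
signature = universe[:25]  # pretend these came out of the pipeline
gsc = generate_gene_sets(universe, n_sets=25, size_range=(10, 120),
                         planted_set=universe[:20], seed=10)

table = ora(signature, universe, gsc)
print(table.head(5).round(5).to_string(index=False))
counts = pathway_gene_counts(signature, gsc)
print(f"\nmost hit set: {counts.loc[0, 'name']} "
      f"({counts.loc[0, 'found']} of the {len(signature)} signature genes)")
# 'entities_ratio' is the set's share of the universe; 'p' the one-sided
# hypergeometric tail; 'fdr' the BH-adjusted value across all 25 sets.
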