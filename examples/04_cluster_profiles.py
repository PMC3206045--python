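"""Cluster residues by substitution profile on the published lipid-facing rates.

Each residue's profile is its vector of rates toward the other 19 residues.
Single-linkage clustering of the published lipid-facing (TM_out) rates
groups residues by physico-chemical role: the aromatic-girdle pair W/Y
joins together, as do the branched aliphatics V/I/L, before either group
reaches the ionizable residues.
"""

from bbtm.profile_clustering import cluster_rate_matrix, load_reported_tm_out_rates

M = load_reported_tm_out_rates()
dendro = cluster_rate_matrix(M)

print("dendrogram (Newick, merge heights as node heights):")
print(dendro.to_newick())
print()
print(f"W-Y merge height:        {dendro.merge_height('W', 'Y'):.1f}")
print(f"V-I merge height:        {dendro.merge_height('V', 'I'):.1f}")
for res in "KRDEH":
    print(f"W-{res} merge height:        {dendro.merge_height('W', res):.1f}")
print("lower = merged earlier = more similar substitution behavior")
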