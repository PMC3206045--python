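"""Aggregate the packaged per-protein template statistics.

Loads the shipped table of 11 beta-barrel template proteins (TM residue
counts, barrel-interior vs lipid-facing partition, GES hydrophobicity per
class) and prints the mean row. The three hydrophobicity means tell the
structural story: the TM region as a whole is mildly polar, the
barrel-interior face strongly polar, and the lipid face strongly
hydrophobic.
"""

from bbtm.tm_dataset import aggregate_stats, load_template_stats

rows = load_template_stats()
mean = aggregate_stats(rows)

print(f"{'PDB':6} {'TM':>4} {'Total':>6} {'Strands':>8} {'In':>4} {'Out':>4}"
      f" {'GES all':>8} {'GES in':>7} {'GES out':>8}")
for r in rows + [mean]:
    print(f"{r.protein_id:6} {r.n_tm_residues:4d} {r.n_total_residues:6d}"
          f" {r.n_strands:8d} {r.n_in:4d} {r.n_out:4d}"
          f" {r.hydro_all:8.2f} {r.hydro_in:7.2f} {r.hydro_out:8.2f}")

print()
print(f"total strands: {sum(r.n_strands for r in rows)}")
print("negative GES = polar, positive = hydrophobic (kcal/mol scale)")
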