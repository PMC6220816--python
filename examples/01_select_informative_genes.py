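"""Select the most consistently implicated genes from the evidence table.

Builds the clinical-settings x genes matrix from the packaged persisting-
pain evidence table, runs computed ABC analysis on the per-gene setting
counts, and prints the genes in sets A and B — those reported in enough
distinct clinical settings to be informative about the phenotype rather
than any single underlying disease.
"""

from genefunc import abc_analysis, packaged_data, parse_evidence, settings_matrix

table = parse_evidence(packaged_data("pain_evidence.tsv"))
matrix = settings_matrix(table)
print(f"evidence: {len(table.genes)} genes, {len(table.settings)} clinical settings, "
      f"{len(table.records)} deduplicated reports")

result = abc_analysis({g: float(s) for g, s in matrix.column_sums.items()})
print(f"ABC limits: A|B at x = {result.ab_x:.3f}, B|C at x = {result.bc_x:.3f} "
      f"(Pareto point {result.pareto_point[0]:.3f}, break-even {result.break_even_x:.3f})")

selected = result.selected
print(f"\n{len(selected)} genes in sets A or B (gene: settings count):")
counts = matrix.column_sums
for gene in selected:
    print(f"  {gene}: {counts[gene]}")
# Genes below the B|C limit were reported in a single setting each; their
# association may reflect the triggering disease rather than the pain trait.
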