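"""Cross-reference hybrid parental-origin calls with an imprinting database.

Uses the bundled 14-gene table for the buck-ewe hybrid system: each gene's
observed parent-of-origin in the hybrid is compared against the expressed
allele reported by the geneimprint database.  Concordant = same pole,
discordant = opposite poles, unresolvable = the database reports biallelic
or conflicting evidence.
"""

from hybridscope import imprint

table = imprint.bundled_imprint_table()
calls = {r.gene_symbol: r.origin_in_hybrid for r in table}
result = imprint.crossref_imprint(calls, table)

print(f"matched genes: {result.n_matched}")
print(f"  concordant:   {result.n_concordant}")
print(f"  discordant:   {result.n_discordant}")
print(f"  unresolvable: {result.n_unresolvable}")
print()
for rec in result.matched:
    print(f"  {rec.gene_symbol:>8}  hybrid={rec.origin_in_hybrid:<8} "
          f"reported={rec.reported_allele:<24} -> {rec.classification}")
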