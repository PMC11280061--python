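"""The enrichment primitive on a hand-built example.

Ten genes, three of them DEGs; a TF binds the promoters of two DEGs and one
background gene. The 2x2 table, one-sided Fisher p and BH adjustment are
printed step by step.
"""

from tfrn.enrichment import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    fisher_pvalue,
)

universe = {f"g{i}" for i in range(1, 11)}
deg = {"g1", "g2", "g3"}
bound = {"g1", "g2", "g4"}

table = build_contingency(deg, bound, universe)
print(f"contingency (a,b,c,d) = ({table.a},{table.b},{table.c},{table.d})")
p = fisher_pvalue(table)
print(f"one-sided Fisher p = {p:.6f}  (= P(X>=2), X~Hypergeom(N=10,K=3,n=3) = 11/60)")
print(f"odds ratio = {table.odds_ratio:.2f}")

qs = bh_adjust([0.01, 0.04])
print(f"BH on [0.01, 0.04] -> {qs}  (step-up: min(2*0.01, 0.04), 0.04)")
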