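"""Translate a DIGS slope into net lateral gene transfer rates.

The DIGS-vs-NDgenome slope for tropical/subtropical surface-ocean
prokaryoplankton is about -26% per 1% NDgenome.  Halving it twice (gain/loss
balance; two lineages per pair) and combining with an amino-acid clock of
2%/Ma, 1377 genes per genome, 10-day generations and 5e8 cells per litre
yields the gene-, cell- and ecosystem-scale net LGT rates.
"""

from digs.rates import RateParams, translate_rates

est = translate_rates(RateParams(digs_slope_per_pct=-26.0))

print(f"net fraction per 1% NDgenome : {est.net_fraction_per_pct_nd:.3%}")
print(f"genes per lineage per Ma     : {est.genes_per_ma:.0f}"
      f"  ({est.pct_genes_per_ma:.0f}% of gene content)")
print(f"genes per cell generation    : {est.genes_per_cell_generation:.2e}")
print(f"genes per litre per day      : {est.genes_per_liter_day:.0f}")
print()
print("A negative DIGS slope means close genome pairs share fewer")
print("near-identical genes than substitution-only evolution predicts;")
print("the chain above converts that deficit into a net LGT rate.")
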