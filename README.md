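# digs — quantifying net lateral gene transfer from partial microbial genomes

Microbial genomes constantly gain and lose genes through lateral gene
transfer (LGT), but measuring *how fast* this happens in a natural community
is hard: phylogenetic methods need genes shared by many genomes, while most
genes in environmental pangenomes are rare, and single-cell assemblies are
incomplete.  `digs` implements the **Discrepancy in Gene Share (DIGS)**
framework, which turns collections of partial genomes (e.g. single amplified
genomes from ocean surveys) into microbiome-wide net LGT rate estimates, plus
the tree-based tests used to corroborate individual transfer events.

It is a library for computational microbiologists, with a thin `digs` CLI for
the common pipelines.

## The model and statistic

For a genome pair with mean per-gene nucleotide divergence *D* (≈ NDgenome =
1 − ANI), each gene *i* carries a rate multiplier *rᵢ* ~ Gamma(α, α) (mean 1,
variance 1/α), and its observed substitution count is Poisson(*rᵢ D L*) for
gene length *L*.  The **expected gene share** under substitution-only
evolution is the probability that a gene stays within an NDgene threshold ρ:

    EGS(ρ; D, α, L) = P(X ≤ ⌊ρL⌋),   X ~ NegBinomial(size α, prob α/(α + DL))

(the closed form of the Poisson–Gamma mixture; an adaptive-quadrature oracle
`egs_numeric` verifies it to 1e−9).  The **observed gene share** is computed
from reciprocal best hits between 500–1500 nt ORFs and corrected for assembly
incompleteness (completeness *c*, observed gene count *n*):

    OGS(A,B; ρ) = (s/2) · (1/(n_A c_A) + 1/(n_B c_B))

**DIGS(D, ρ)** is the mean of OGS − EGS over genome pairs binned by divergence
(bin width ε = 0.1%).  Without LGT it is ~0 at every divergence (verified by
the built-in genome-evolution simulator); in real communities it declines with
D at low divergence, and a zero-intercept slope of −26% DIGS per 1% NDgenome
translates into a net LGT rate via

    26%/1% × 0.5 (gain/loss balance) × 0.5 (two lineages) = 6.5% of gene
    content per 1% NDgenome  →  1377 × 0.065 × 2%/Ma = 179 genes/Ma (13%)
    →  4.9e−6 genes/cell/generation  →  245 genes per litre of seawater/day.

The package also provides the conserved-gene ("core" gene) LGT tests: the
Δ statistic contrasting gene-tree neighbourhoods with genome-wide amino-acid
divergence (exponential null, median-fitted, BH-FDR), and noise-corrected
quartet distances on divergence-controlled genome subsets.

## Worked example

Evolve a synthetic bacterial genome (codon-structured ORFs, ~5% intergenic,
gamma rate heterogeneity with true α = 5) to a series of divergence levels
without any gene transfer, push all pairs through the comparison pipeline,
and check the model:

```bash
python examples/lgt_free_simulation.py
```

```
re-estimated gamma shape (true 5): 5.55
mean in-window gene length L     : 912.1 nt

DIGS at NDgene threshold 1% (LGT-free, should hover around 0):
  D in (0.000, 0.001] : mean DIGS +0.0000  (1 pairs)
  D in (0.001, 0.002] : mean DIGS +0.0009  (1 pairs)
  D in (0.002, 0.003] : mean DIGS -0.0014  (1 pairs)
  ...
  D in (0.099, 0.100] : mean DIGS +0.0008  (1 pairs)
  D in (0.139, 0.140] : mean DIGS -0.0000  (1 pairs)
```

The re-estimated α comes from the same per-pair procedure used on real data
(α̂ = (D/σ)² over pairs with 0.05 < D < 0.2); DIGS staying within a couple of
percent of zero at every divergence is the model-validation result — any
systematic deviation on real data is then attributable to gene gain/loss, not
to the pipeline.  The other scripts in `examples/` each demonstrate one
capability (rate translation, the EGS band, the completeness correction, the
planted-transfer Δ test, quartet discordance).

Translating the published slope into rates:

```bash
$ digs rates --slope -26
net_fraction_per_pct_nd 0.065
genes_per_ma            179
pct_genes_per_ma        13
genes_per_cell_generation 4.90411e-06
genes_per_liter_day     245.205
```

## Layout

| module | contents |
| --- | --- |
| `digs.io` | `GeneRecord`/`Genome`/`GenomeSet`, FASTA + manifest + Newick I/O |
| `digs.null_model` | EGS closed form and quadrature oracle, α estimation, spurious-pair filter |
| `digs.gene_share` | reciprocal best hits, shared-gene counts, OGS correction, DIGS curves and slope |
| `digs.simulate` | base-genome generator, nucleotide/amino-acid evolution, incompleteness degradation, end-to-end validation |
| `digs.discordance` | AAD matrix, Δ statistics with exponential null and BH-FDR, quartet distances, single-linkage subsets |
| `digs.rates` | DIGS slope → gene/cell/ecosystem LGT rates |
| `digs.cli` | `digs rates / model / pairwise / curve / slope / simulate / discord` |
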