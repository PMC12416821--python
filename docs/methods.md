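# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix.  Nothing
here states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The LGT-free null model (EGS)

A genome pair is summarised by its mean per-gene nucleotide divergence *D*
(1 − identity averaged over retained orthologous hits; this approximates
NDgenome = 1 − ANI).  Gene *i* evolves at relative rate *rᵢ* drawn from a
gamma distribution with shape α and **rate** α, i.e. mean 1 and variance 1/α.
(The shape/scale = α parameterisation sometimes quoted for this model would
give mean α² and contradict the stated moments; the stated moments govern
here.)  Conditional on *rᵢ*, the observed substitution count in a gene of
length *L* is Poisson(*rᵢ D L*).  Marginally the count is negative binomial
with size α and success probability α/(α + DL), so

    EGS(ρ; D, α, L) = NB-CDF(⌊ρL⌋; α, α/(α + DL)).

Conventions:

* "NDgene below ρ" with integer substitution counts is implemented as
  X ≤ ⌊ρL⌋ (the continuous formulation integrates the count from 0 to ρL).
* ρ must stay small (≤ 0.05 hard limit, warning above 0.02) because the model
  ignores back-mutation.
* `egs_numeric` evaluates the defining sum-of-integrals by adaptive
  quadrature term by term and is the independent oracle; closed form and
  quadrature agree to 1e−9 across the working grid (D up to 0.3, the three
  reference α quantiles, ρ ∈ {1%, 1.5%, 2%}).
* As α → ∞ the model degenerates to a pure Poisson with mean DL (checked at
  α = 1e6 against the Poisson CDF to 1e−4).

### Length-aware evaluation in DIGS curves

EGS as defined takes a single representative length (defaults: L = 904.3, the
mean in-window gene length of the reference collection; recomputed from data
when available).  The observation side, however, applies a per-gene integer
threshold ⌊ρL_g⌋ with L_g spanning 500–1500 nt.  Averaged over a bell-shaped
length window, the effective threshold sits about half a substitution below
⌊ρL̄⌋, which makes single-length EGS optimistic by up to ~0.04 around D ≈ ρ —
easily mistaken for an LGT signal.  DIGS-curve construction therefore
averages the closed-form EGS over the empirical in-window length distribution
whenever gene lengths are available (`digs_curve(..., gene_lengths=...)`,
automatic when a genome set is supplied); `egs()` itself keeps the
single-length definition.

## α estimation

For each genome pair, α̂ = (D̄/σ)², with D̄ and σ the mean and sample (n−1)
standard deviation of per-hit divergences.  Under the model the per-gene
divergence has mean D and standard deviation D/√α, which makes this estimator
consistent; the variant ((1−D̄)/σ)² circulating in some descriptions is
exposed behind `estimator="literal"` but recovers nothing resembling the true
shape on simulated data (for divergences of a few percent it is three orders
of magnitude too large), so the model-consistent form is the default.

Within-gene Poisson counting noise inflates σ² by ≈ D/L beyond the
across-gene component D²/α.  The default estimator ignores it, matching the
printed procedure it reproduces; `poisson_correction_length=L` enables the
bias-corrected α̂ = D̄²/(σ² − D̄/L).

Reliability filters, applied before pooling: the empirical spurious-pair rule
*keep iff hits > 800 − 5000·D*; the divergence window 0.05 < D̄ < 0.2; at
least five hits.  Pooled summaries use the 10/50/90% empirical quantiles
(linear interpolation).  The reference collection's quantiles
(3.31, 5.28, 7.77) are shipped as documented defaults when no data are
available, with 5.28 the working default.

Two biases of the full pipeline's α̂ are worth knowing about (both verified on
simulations with known α, both shared by the procedure the pipeline
reproduces): multiple substitutions at one site compress the top of the
per-gene divergence distribution under Jukes–Cantor evolution, deflating σ
and inflating α̂ increasingly with D; and any search tool's sensitivity floor
truncates the fastest genes at high D with the same effect.  At true α = 5 the
recovered pooled median is ≈ 5.5–6.

## Pairwise comparison pipeline

The search for orthologous gene pairs is an internal replacement for
reciprocal blastn, so results are reproducible without external binaries:

1. **Candidate screen.** All 12-mers of each genome's ORFs are indexed
   (2-bit encoded, sorted array); gene pairs sharing ≥ 2 sampled words (every
   2nd word queried) become candidates.
2. **Scoring.** Candidates are scored by banded global edit distance
   (edlib); identity = 1 − dist/max(len_a, len_b); candidates below an
   identity floor of 0.60 are dropped.
3. **Rescue pass.** Genes left unpartnered on both sides get a second screen
   with 10-mers, stride 1 and floor 0.55, approximating the sensitivity of a
   word-11 nucleotide search at 30–45% divergence.  Unrelated sequences stay
   safely below the floor: the global-alignment identity of random ORFs
   concentrates near 0.48 (empirical max ≈ 0.53).  The pass is skipped when
   more than half of either genome is unpartnered (effectively unrelated
   genomes, outside the model's operating range).
4. **Reciprocal best hits.** Best partner per gene by identity, ties broken
   by longer alignment then lexicographically smaller partner id; a pair is
   kept only when both directions agree.

A local affine-gap aligner with the classic nucleotide-search scoring
(match +2, mismatch −3, gap open 5, extend 2) is available as
`align_gene_pair`/`engine="exact"` for small inputs, and an outfmt-6 adapter
(`hits_from_blast_outfmt6`) ingests external blastn tables for fidelity
studies.

Divergence summaries (D̄, σ, hit count) and shared-gene counts use only hits
whose genes both lie in the 500–1500 nt window, keeping them consistent with
the model's L.  A hit counts as shared at threshold ρ when identity ≥ 1 − ρ
and the alignment covers ≥ 80% of the shorter gene (`strict_coverage` switches
to the longer gene).  The completeness correction defaults to in-window gene
counts for both the shared count *s* and the denominators *n* — using all
ORFs in the denominator while counting *s* among in-window genes only would
bias OGS low by the out-of-window fraction; `gene_count_mode="all"` provides
that variant for comparison with CheckM-scaled totals.

DIGS curves bin pairs by their own D̄ into (upper − ε, upper] intervals
(ε = 0.001) and subtract EGS evaluated at each pair's D̄ (a bin-midpoint mode
is deliberately not provided: the defining sum subtracts the per-pair model
value).  The slope is weighted least squares through the origin on
(bin upper D, mean DIGS), weights = pairs per bin, over bins with upper
D ≤ 0.5ρ by default, reported as DIGS percentage points per 1% NDgenome.

## Genome evolution simulator

The simulator is the validation backbone: it produces data whose generating
process *is* the null model, so any pipeline bias shows up as nonzero DIGS.

**Base genomes.**  1000 ORFs by default; lengths ≈ Normal(900, 200) nt
rounded to whole codons and clipped to [300, 2400] — a realistic envelope
that keeps ~97% of genes inside the 500–1500 nt analysis window; ATG start,
random stop, no internal stops; GC content 0.4; intergenic gaps sized to ~5%
of the genome; ~2% of adjacent gene pairs overlap in a shifted reading frame
(the overlap segment is rejection-sampled so both frames stay stop-free).

**Nucleotide mode.**  One gamma rate multiplier per gene, drawn once per base
genome and reused for every level of a series.  For level ℓ, exactly
n = round(ℓ × mutable length) positions are chosen without replacement
(Gumbel top-k weighted sampling, weights = the owning gene's rate; positions
inside overlaps take the rate of one randomly chosen covering gene, fixed per
series) and mutated Jukes–Cantor style to one of the three other bases.
Start/stop codons are never touched; intergenic sequence is not mutated (it
carries no signal for any downstream statistic).  The default level series is
0%, 0.05%, 0.1%, 0.2%…1% (step 0.1%), 2%…19% (step 1%) — 30 genomes per
base genome.  Ground truth (mutation count, per-gene rates) is retained.

**Amino-acid mode.**  n = round(μ × eligible residues) internal residues
(codons fully owned by one gene; overlaps and start/stop excluded) are
substituted using BLOSUM62 scores mapped to transition weights 2^(score/2)
over the 19 alternatives — a monotone unscaling of the half-bit log-odds —
then back-translated keeping original codons at untouched positions and
sampling the new residue's codon with weight 4 − d (d = Hamming distance to
the original codon).  Default series μ = 0.01…0.69 step 0.02, α = 22
(amino-acid rates vary less across genes than nucleotide rates).

**Incompleteness.**  The removed-fraction target p is Beta-distributed with
mean 12% (shape a = 4, a synthetic stand-in for the empirical completeness
distribution of single-cell assemblies); chunk count ~ Poisson(17), chunk
lengths ~ Poisson(p·L/n), uniform starts; genes touching a removed chunk are
dropped whole (downstream statistics operate on whole genes).  Ground-truth
completeness is the retained-gene fraction — a marker-based estimate of the
degraded assembly divided by that of the original would converge to the same
ratio, and external completeness tables can be supplied through the manifest
for fidelity studies.

**Planted turnover.**  `turnover_per_unit_divergence` replaces whole genes
with fresh random sequence at a configured rate per unit divergence; it
exists only to give the slope fit a recoverable signal and is not part of the
null simulator.

**Scale of the standard validation run.**  Five base genomes × 30 levels,
all within-series pairs (cross-series pairs share no homology and are
skipped) ≈ 2 175 comparisons per arm, about 6–8 minutes per arm on one CPU.

## Conserved-gene discordance tests

**AAD matrix.**  ORFs are translated (bacterial code, table 11; genes with
internal stops or ambiguity are skipped with a warning) and matched by
reciprocal best amino-acid hits (5-mer screen + global edit distance); AAD =
1 − mean identity over reciprocal hits.  Pairs with no hits are missing and
excluded from nearest-neighbour searches.

**Δ statistic.**  For each query leaf Q of a gene tree: M = genome with the
lowest AAD to Q's genome; N₁…N₃ = closest leaves by gene-tree path length
(ties by label; leaves of Q's own genome are never candidates — their AAD of
0 would make the contrast ill-defined; each copy of a multi-copy gene is an
independent query).  Δⱼ = AAD(Q, Nⱼ) − AAD(Q, M) ≥ 0.

**Exponential null.**  λ̂ = ln 2 / median(Δ) per gene (robust to the very
outliers the test hunts); significance is the upper tail p = exp(−λ̂δ) —
the lower-tail CDF variant, under which extreme transfers would score p ≈ 1,
is available behind `tail="cdf"` for compatibility.  BH-FDR is pooled across
all (gene × query × neighbour) tests by default (`bh_scope="per_gene"` for
sensitivity analysis).  `hellinger_fit` compares Exponential / Log-Normal /
Gamma candidates on 20 equal-probability bins; since the gamma family nests
the exponential, near-ties (ΔH² < 0.002) rank by parameter count.

**Quartet discordance.**  Quartet topologies are resolved by the four-point
condition on topological distances (the pairing with the strictly smallest
distance sum); a tied minimum marks the quadruple unresolved, and a quadruple
resolved in exactly one tree counts as different by default
(`unresolved="same"` flips that).  Brute-force enumeration of all C(n,4)
quadruples is exact and fast at the subset size used (10 leaves → 210
quadruples); the suite cross-checks it against an independent
path-disjointness oracle.  Subsets come from cutting the single-linkage
dendrogram of the AAD matrix at thresholds 0.5%…29.5% (step 0.5%), drawing
10 genomes from 10 distinct clusters, 50 subsets per threshold; thresholds
with fewer than 10 clusters are reported and skipped.  The reported
discordance is q_s − q_∅ (gene-vs-species minus mean gene-vs-bootstrap),
which may be negative.

**Synthetic discordance data.**  The built-in generator uses a balanced
species tree whose branch lengths grow geometrically with depth (×3 per
level, terminal edges ~0.001), giving every genome a comparably dense
neighbourhood inside a collection spanning a wide divergence range — the
regime in which the exponential null is a reasonable description of
concordant Δ values.  Concordant gene trees jitter branch lengths
log-normally; AAD carries a small log-normal measurement noise; a planted
transfer regrafts a query leaf next to a distant donor.  What passing tests
on these data do *not* show: robustness to gene-tree topology estimation
error, unbalanced taxon sampling (sparse neighbourhoods produce heavy-tailed
concordant Δ and can yield false positives), or alignment-quality artefacts.

## Rate translation

net fraction per 1% NDgenome = |slope|/100 × 0.5 × 0.5.  The two 0.5 factors
are exposed as `gain_fraction` (assuming stable genome sizes, half of the
DIGS decrease reflects acquisitions) and `lineage_fraction` (each lineage of
a pair contributes half of the observed content difference) and can be varied
for sensitivity analysis.  Downstream: genes/Ma = genes-per-genome × fraction
× AA-substitution-rate(%/Ma); per cell generation = genes/Ma × generation
days / (10⁶ × 365); per litre day = genes/Ma × cells per litre × 10⁻⁶ / 365.
By default genes/Ma is rounded to an integer before the last two steps,
reproducing the published arithmetic chain digit for digit;
`round_genes_per_ma=False` gives exact arithmetic.

## Known limitations

* The simulator has no indels, rearrangements, duplications or recombination;
  the comparison engine is correspondingly untested on structurally variable
  real genomes (the blastn adapter exists for such fidelity studies).
* α̂ from the full pipeline carries the upward multiple-hit bias described
  above; rate estimates inherit whatever α is used in EGS only weakly (the
  DIGS slope at D ≪ ρ is insensitive to α within the reference band).
* The spurious-pair filter (hits > 800 − 5000 D) presumes roughly
  1000-gene inventories; collections with far fewer observed genes per
  genome will see low-divergence pairs filtered (this mirrors the procedure
  it reproduces, but it removes degraded low-D pairs from DIGS curves).
* Completeness values are taken at face value; systematic completeness
  estimation bias propagates directly into OGS.
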