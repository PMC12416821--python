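"""Pairwise genome comparisons, completeness-corrected gene share and DIGS curves.

Pipeline: reciprocal best hits between two genomes' ORFs -> per-pair divergence
summary (mean ``D``, sd ``sigma``, hit count) -> shared-gene counts ``s`` at the
configured NDgene thresholds -> completeness-corrected observed gene share
(OGS) -> binned OGS - EGS (the DIGS curve) -> zero-intercept slope.

Only genes inside the 500-1500 nt length window enter the shared-gene counts
and the divergence summaries; the model parameter ``L`` is the mean length of
in-window genes, computed accordingly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .io import Genome, GenomeSet
from .null_model import NullModelParams, egs, filter_spurious

DEFAULT_RHOS = (0.01, 0.015, 0.02)
DEFAULT_EPSILON = 0.001
MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class GenePairHit:
    """One retained hit between a gene of A and a gene of B."""

    gene_a: str
    gene_b: str
    identity: float
    alignment_length: int
    reciprocal: bool = True


@dataclass
class PairComparison:
    """Summary of one genome pair.

    ``mean_divergence``/``std_divergence`` are over retained in-window
    reciprocal hits (1 - identity per hit); ``shared_counts`` maps each NDgene
    threshold rho to the shared-gene count ``s``; ``ogs`` maps rho to the
    completeness-corrected observed gene share (may exceed 1 by design of the
    correction).
    """

    genome_a: str
    genome_b: str
    mean_divergence: float
    std_divergence: float
    n_hits: int
    shared_counts: dict[float, int] = field(default_factory=dict)
    ogs: dict[float, float] = field(default_factory=dict)
    spurious: bool = False
    usable: bool = True


@dataclass
class DIGSCurve:
    """Binned mean OGS - EGS versus pair divergence at one NDgene threshold.

    Bins are half-open intervals ``(upper - epsilon, upper]``; only populated
    bins are stored.
    """

    rho: float
    epsilon: float
    bin_upper_d: np.ndarray
    mean_digs: np.ndarray
    n_pairs: np.ndarray
    alpha: float
    mean_gene_length: float


@dataclass(frozen=True)
class SlopeFit:
    """Zero-intercept weighted least-squares slope of a DIGS curve.

    ``slope`` is the change of DIGS (in percentage points) per 1% genome-wide
    divergence; e.g. -26 means DIGS drops by 26 percentage points per 1%
    NDgenome.
    """

    slope: float
    fit_window_max_d: float
    n_bins_used: int


# ---------------------------------------------------------------------------
# alignment layer


def align_gene_pair(a, b, min_coverage: float = MIN_COVERAGE) -> GenePairHit | None:
    """Local alignment of two genes with the classic nucleotide-search scoring.

    Match +2, mismatch -3, gap open 5, gap extend 2.  Identity counts matched
    columns over all alignment columns (gap columns count as unmatched).
    Returns ``None`` when the best local alignment covers less than
    ``min_coverage`` of the shorter gene.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-3,
        open_gap_score=-5, extend_gap_score=-2,
    )
    if not a.sequence or not b.sequence:
        return None
    alignments = aligner.align(a.sequence, b.sequence)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns < min_coverage * min(len(a.sequence), len(b.sequence)):
        return None
    return GenePairHit(
        gene_a=a.gene_id, gene_b=b.gene_id,
        identity=counts.identities / columns,
        alignment_length=columns, reciprocal=False,
    )


def _kmer_index(genome: Genome) -> _align.KmerIndex:
    # memoised per Genome object; sequences are treated as immutable
    idx = getattr(genome, "_digs_kmer_index", None)
    if idx is None:
        idx = _align.build_index(genome.genes)
        genome._digs_kmer_index = idx
    return idx


def _best_per_query(identities, side: int):
    """Best partner per gene on one side; ties -> longer alignment, then id."""
    best: dict[int, tuple] = {}
    for (ia, ib), (ident, alen) in identities.items():
        q, t = (ia, ib) if side == 0 else (ib, ia)
        key = (ident, alen, t)
        cur = best.get(q)
        if cur is None or (key[0], key[1]) > (cur[0], cur[1]) or (
            (key[0], key[1]) == (cur[0], cur[1]) and key[2] < cur[2]
        ):
            best[q] = key
    return {q: t for q, (_, _, t) in best.items()}


def reciprocal_best_hits(
    a: Genome,
    b: Genome,
    *,
    engine: str = "kmer",
    min_identity: float = _align.DEFAULT_MIN_IDENTITY,
) -> list[GenePairHit]:
    """Orthologous gene pairs between two genomes by reciprocal best hit.

    ``engine="kmer"`` (default) screens candidates by shared k-mers and scores
    them with a banded global edit distance; ``engine="exact"`` scores every
    gene pair with :func:`align_gene_pair` (quadratic; small genomes only).
    Best hits are chosen by identity, ties broken by longer alignment then
    lexicographically smaller partner gene id; a pair is kept only when the two
    directions agree.
    """
    if engine == "kmer":
        ia, ib = _kmer_index(a), _kmer_index(b)
        identities = _align.genome_pair_identities(ia, ib, min_identity=min_identity)
        ids_a, ids_b = ia.gene_ids, ib.gene_ids
    elif engine == "exact":
        identities = {}
        ids_a = [g.gene_id for g in a]
        ids_b = [g.gene_id for g in b]
        for i, ga in enumerate(a):
            for j, gb in enumerate(b):
                hit = align_gene_pair(ga, gb)
                if hit is not None and hit.identity >= min_identity:
                    identities[(i, j)] = (hit.identity, hit.alignment_length)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    # tie-break by partner gene id needs ids, not indices: rebuild keyed on ids
    by_id = {
        (ids_a[i], ids_b[j]): v for (i, j), v in identities.items()
    }
    best_a = _best_per_query(by_id, side=0)
    best_b = _best_per_query(by_id, side=1)
    hits = []
    for ga, gb in best_a.items():
        if best_b.get(gb) == ga:
            ident, alen = by_id[(ga, gb)]
            hits.append(GenePairHit(gene_a=ga, gene_b=gb, identity=ident,
                                    alignment_length=alen, reciprocal=True))
    hits.sort(key=lambda h: h.gene_a)
    return hits


# ---------------------------------------------------------------------------
# gene-share statistics


def count_shared(
    a: Genome,
    b: Genome,
    rho: float,
    hits: list[GenePairHit] | None = None,
    *,
    strict_coverage: bool = False,
    **rbh_kwargs,
) -> int:
    """Number of reciprocal hits with NDgene at or below ``rho``.

    A hit counts when identity >= 1 - rho, the alignment covers at least 80%
    of the shorter gene (of the longer one with ``strict_coverage``), and both
    genes fall in the 500-1500 nt length window.
    """
    if hits is None:
        hits = reciprocal_best_hits(a, b, **rbh_kwargs)
    genes_a = {g.gene_id: g for g in a}
    genes_b = {g.gene_id: g for g in b}
    s = 0
    for h in hits:
        ga, gb = genes_a[h.gene_a], genes_b[h.gene_b]
        if not (ga.in_length_window and gb.in_length_window):
            continue
        ref = max(ga.length_nt, gb.length_nt) if strict_coverage else min(ga.length_nt, gb.length_nt)
        if h.alignment_length < MIN_COVERAGE * ref:
            continue
        if h.identity >= 1.0 - rho:
            s += 1
    return s


def ogs_corrected(s: int, n_a: int, c_a: float, n_b: int, c_b: float) -> float:
    """Completeness-corrected observed gene share.

    ``OGS = (s/2) * (1/(n_A c_A) + 1/(n_B c_B))``: assuming genes are lost to
    incompleteness independently of whether they are shared, ``s / c_A c_B``
    estimates the shared count of the complete genomes and ``n/c`` their full
    gene complements.  Values above 1 are possible (and expected at very low
    divergence between partially overlapping assemblies).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("gene counts must be >= 1")
    if not (0.0 < c_a <= 1.0 and 0.0 < c_b <= 1.0):
        raise ValueError("completeness values must be in (0, 1]")
    if s < 0:
        raise ValueError("shared count must be non-negative")
    return 0.5 * s * (1.0 / (n_a * c_a) + 1.0 / (n_b * c_b))


def pair_divergence(
    a: Genome,
    b: Genome,
    rhos=DEFAULT_RHOS,
    *,
    gene_count_mode: str = "in_window",
    strict_coverage: bool = False,
    **rbh_kwargs,
) -> PairComparison:
    """Full comparison of one genome pair.

    Divergence statistics (``D``, ``sigma``, ``n_hits``) are computed over
    retained reciprocal hits whose genes both lie in the length window, keeping
    the summaries consistent with the model's ``L``.  ``gene_count_mode``
    selects the denominator of the completeness correction: in-window gene
    counts (default, consistent with counting ``s`` among in-window genes) or
    ``"all"`` ORFs.
    """
    hits = reciprocal_best_hits(a, b, **rbh_kwargs)
    genes_a = {g.gene_id: g for g in a}
    genes_b = {g.gene_id: g for g in b}
    window_hits = [
        h for h in hits
        if genes_a[h.gene_a].in_length_window and genes_b[h.gene_b].in_length_window
    ]
    if not window_hits:
        return PairComparison(a.genome_id, b.genome_id, math.nan, math.nan, 0,
                              spurious=True, usable=False)
    div = np.array([1.0 - h.identity for h in window_hits])
    mean_d = float(div.mean())
    sigma = float(div.std(ddof=1)) if div.size > 1 else math.nan
    n_hits = len(window_hits)
    spurious = not filter_spurious(mean_d, n_hits)
    if gene_count_mode == "in_window":
        n_a, n_b = a.n_in_window, b.n_in_window
    elif gene_count_mode == "all":
        n_a, n_b = a.n_observed_genes, b.n_observed_genes
    else:
        raise ValueError(f"unknown gene_count_mode {gene_count_mode!r}")
    shared, ogs = {}, {}
    for rho in rhos:
        s = count_shared(a, b, rho, hits=window_hits, strict_coverage=strict_coverage)
        shared[rho] = s
        ogs[rho] = ogs_corrected(s, n_a, a.completeness, n_b, b.completeness)
    return PairComparison(a.genome_id, b.genome_id, mean_d, sigma, n_hits,
                          shared_counts=shared, ogs=ogs, spurious=spurious)


def all_pair_comparisons(gset: GenomeSet, rhos=DEFAULT_RHOS, **kwargs) -> list[PairComparison]:
    """Pairwise comparisons over every genome pair of a set."""
    genomes = list(gset)
    out = []
    for a, b in itertools.combinations(genomes, 2):
        out.append(pair_divergence(a, b, rhos=rhos, **kwargs))
    return out


def mean_in_window_length(gset: GenomeSet) -> float:
    """Mean length of in-window genes across the set (the model's ``L``)."""
    lengths = [g.length_nt for genome in gset for g in genome if g.in_length_window]
    if not lengths:
        raise ValueError("no genes inside the length window")
    return float(np.mean(lengths))


def digs_curve(
    gset: GenomeSet | None,
    rho: float = 0.01,
    epsilon: float = DEFAULT_EPSILON,
    alpha: float | None = None,
    mean_gene_length: float | None = None,
    *,
    comparisons: list[PairComparison] | None = None,
    gene_lengths=None,
) -> DIGSCurve:
    """Binned mean of (corrected OGS - EGS) versus pair divergence.

    Each usable, non-spurious pair contributes ``OGS(rho) - EGS(rho; D_pair)``
    evaluated at the pair's own mean divergence; pairs are binned into
    ``(upper - epsilon, upper]`` intervals of ``D``.  When the in-window gene
    lengths are available (``gene_lengths``, or derived from ``gset``), EGS is
    averaged over that length distribution, which removes the bias of a single
    representative length near the NDgene threshold; otherwise the closed form
    at ``mean_gene_length`` is used.  ``comparisons`` may be supplied to reuse
    precomputed pair tables.
    """
    from .null_model import DEFAULT_ALPHA, egs_length_mixture

    if comparisons is None:
        if gset is None:
            raise ValueError("either a genome set or precomputed comparisons are required")
        comparisons = all_pair_comparisons(gset, rhos=(rho,))
    if alpha is None:
        alpha = DEFAULT_ALPHA
    if gene_lengths is None and gset is not None:
        gene_lengths = [g.length_nt for genome in gset for g in genome if g.in_length_window]
    if mean_gene_length is None:
        if gene_lengths is None:
            raise ValueError("mean_gene_length required when no genome set is given")
        mean_gene_length = float(np.mean(gene_lengths))
    length_values = length_counts = None
    if gene_lengths is not None:
        length_values, length_counts = np.unique(
            np.asarray(gene_lengths, dtype=float), return_counts=True)
    usable = [c for c in comparisons if c.usable and not c.spurious and rho in c.ogs]
    if not usable:
        raise ValueError("no usable genome pairs for the DIGS curve")
    bins: dict[int, list[float]] = {}
    for c in usable:
        if length_values is not None:
            model = egs_length_mixture(c.mean_divergence, rho, alpha,
                                       length_values, length_counts)
        else:
            model = egs(NullModelParams(alpha=alpha, mean_gene_length=mean_gene_length,
                                        ndgene_threshold=rho,
                                        avg_divergence=c.mean_divergence))
        contribution = c.ogs[rho] - model
        k = max(0, math.ceil(c.mean_divergence / epsilon - 1e-9))
        bins.setdefault(k, []).append(contribution)
    ks = sorted(bins)
    return DIGSCurve(
        rho=rho, epsilon=epsilon,
        bin_upper_d=np.array([k * epsilon for k in ks]),
        mean_digs=np.array([float(np.mean(bins[k])) for k in ks]),
        n_pairs=np.array([len(bins[k]) for k in ks]),
        alpha=alpha, mean_gene_length=mean_gene_length,
    )


def fit_slope(curve: DIGSCurve, fit_window_max_d: float | None = None) -> SlopeFit:
    """Weighted zero-intercept slope of the DIGS curve at low divergence.

    Least squares through the origin on (bin upper D, mean DIGS), weighted by
    the number of pairs per bin, restricted to bins with upper D at most
    ``fit_window_max_d`` (default ``0.5 * rho``).  The returned slope is in
    DIGS percentage points per 1% NDgenome.
    """
    if fit_window_max_d is None:
        fit_window_max_d = 0.5 * curve.rho
    sel = curve.bin_upper_d <= fit_window_max_d + 1e-12
    x = curve.bin_upper_d[sel]
    y = curve.mean_digs[sel]
    w = curve.n_pairs[sel].astype(float)
    nz = x > 0
    if nz.sum() < 2:
        raise ValueError(
            f"need >= 2 populated bins with D in (0, {fit_window_max_d}] to fit a slope"
        )
    denom = float(np.sum(w[nz] * x[nz] ** 2))
    slope = float(np.sum(w[nz] * x[nz] * y[nz])) / denom
    return SlopeFit(slope=slope, fit_window_max_d=fit_window_max_d,
                    n_bins_used=int(nz.sum()))


# ---------------------------------------------------------------------------
# adapters and export


def _read_outfmt6(path, min_identity: float) -> dict[tuple[str, str], tuple[float, int]]:
    by_id: dict[tuple[str, str], tuple[float, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            q, s, ident, alen = f[0], f[1], float(f[2]) / 100.0, int(f[3])
            if ident < min_identity:
                continue
            cur = by_id.get((q, s))
            if cur is None or (ident, alen) > cur:
                by_id[(q, s)] = (ident, alen)
    return by_id


def hits_from_blast_outfmt6(path_a_vs_b, path_b_vs_a,
                            min_identity: float = _align.DEFAULT_MIN_IDENTITY):
    """Reciprocal best hits from a pair of blastn tabular files (outfmt 6).

    ``path_a_vs_b`` holds the A-as-query search, ``path_b_vs_a`` the reverse;
    both need at least the default columns ``qseqid sseqid pident length ...``.
    A pair is kept when each gene is the other's best hit (identity, then
    alignment length, then partner id).  Adapter for fidelity studies of the
    internal engine against an external search tool.
    """
    ab = _read_outfmt6(path_a_vs_b, min_identity)
    ba = _read_outfmt6(path_b_vs_a, min_identity)
    best_a = _best_per_query(ab, side=0)
    best_b = _best_per_query(ba, side=0)
    hits = []
    for a_gene, b_gene in best_a.items():
        if best_b.get(b_gene) == a_gene:
            ident, alen = ab[(a_gene, b_gene)]
            hits.append(GenePairHit(gene_a=a_gene, gene_b=b_gene, identity=ident,
                                    alignment_length=alen, reciprocal=True))
    hits.sort(key=lambda h: h.gene_a)
    return hits


def comparisons_to_frame(comparisons: list[PairComparison]):
    """Tidy DataFrame of pair comparisons (one row per genome pair)."""
    import pandas as pd

    rows = []
    for c in comparisons:
        row = {
            "genome_a": c.genome_a, "genome_b": c.genome_b,
            "D": c.mean_divergence, "sigma": c.std_divergence,
            "n_hits": c.n_hits, "spurious": c.spurious, "usable": c.usable,
        }
        for rho, s in c.shared_counts.items():
            row[f"s@{rho:g}"] = s
        for rho, v in c.ogs.items():
            row[f"OGS@{rho:g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def curve_to_frame(curve: DIGSCurve):
    """Tidy DataFrame of a DIGS curve (one row per populated bin)."""
    import pandas as pd

    return pd.DataFrame({
        "rho": curve.rho,
        "bin_upper_D": curve.bin_upper_d,
        "n_pairs": curve.n_pairs,
        "mean_digs": curve.mean_digs,
    })
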