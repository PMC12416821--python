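"""Conserved-gene LGT tests: gene-tree/AAD discordance and quartet analyses.

Two complementary detectors of lateral transfer in conserved ("core") genes:

* **Delta statistics** — for each query genome Q on a gene tree, compare the
  genome-wide amino-acid divergence (AAD) from Q to its nearest gene-tree
  neighbours against the minimum AAD from Q to any genome.  Without LGT the
  gene tree ranks genomes like AAD does and the differences
  ``delta = D(Q, N_j) - D(Q, M)`` stay small; a transfer from a distant donor
  makes delta large.  Deltas follow an approximately exponential null, fitted
  robustly through the median, with BH-FDR control across all genes.

* **Quartet discordance** — normalised quartet distance between a gene tree
  and the species tree on 10-genome subsets with controlled AAD range, with
  the gene tree's bootstrap-replicate quartet distance subtracted to cancel
  tree-estimation noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import Genome, GenomeSet

__all__ = [
    "AADMatrix", "DiscordanceRecord", "QuartetSample",
    "aad_matrix", "delta_statistics", "fit_exponential_robust", "delta_pvalues",
    "hellinger_fit", "quartet_distance", "single_linkage_subsets",
    "noise_corrected_discordance", "translate_genome",
    "simulate_discordance_dataset",
]


@dataclass
class AADMatrix:
    """Symmetric genome-wide amino-acid divergence matrix (AAD = 1 - AAI)."""

    genome_ids: list[str]
    values: np.ndarray  # NaN marks missing pairs
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genome_ids),) * 2:
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("AAD matrix must be symmetric")
        if len(self.genome_ids) and np.max(np.abs(np.diag(v))) > 1e-12:
            raise ValueError("AAD diagonal must be zero")
        self.values = v
        self._index = {g: i for i, g in enumerate(self.genome_ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def nearest(self, a: str) -> str | None:
        """Genome with the smallest non-missing AAD to ``a`` (ties by label)."""
        i = self._index[a]
        row = self.values[i].copy()
        row[i] = np.nan
        if np.all(np.isnan(row)):
            return None
        best = np.nanmin(row)
        candidates = sorted(self.genome_ids[j] for j in np.nonzero(row == best)[0])
        return candidates[0]


def translate_genome(genome: Genome) -> dict[str, str]:
    """Translate a genome's ORFs (bacterial code); skips untranslatable genes.

    Returns ``gene_id -> protein`` (stop codon trimmed).  Genes with internal
    stops, frame violations or ambiguity characters are skipped with a warning.
    """
    import warnings

    from Bio.Seq import Seq

    out = {}
    for g in genome:
        if not g.frame_ok or g.has_ambiguity:
            warnings.warn(f"skipping untranslatable gene {g.gene_id}", stacklevel=2)
            continue
        prot = str(Seq(g.sequence).translate(table=11))
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            warnings.warn(f"skipping gene with internal stop: {g.gene_id}", stacklevel=2)
            continue
        out[g.gene_id] = prot
    return out


def _aa_identity(a: str, b: str) -> float:
    import edlib

    span = max(len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / span


def aad_matrix(gset: GenomeSet, *, min_identity: float = 0.3,
               kmer_size: int = 5, min_shared_kmers: int = 2) -> AADMatrix:
    """Genome-wide AAD between every genome pair by reciprocal best AA hits.

    Proteins are matched with a k-mer candidate screen plus global edit
    distance (like the nucleotide engine); AAD is 1 minus the mean identity
    over reciprocal best hits, averaged over the two directions.  Pairs with no
    hits are NaN (missing).
    """
    aa_code = np.full(256, -1, dtype=np.int64)
    for ci, aa in enumerate("ACDEFGHIKLMNPQRSTVWY"):
        aa_code[ord(aa)] = ci
    ids = list(gset.genomes)
    proteins = {gid: translate_genome(gset[gid]) for gid in ids}
    indexes = {}
    for gid in ids:
        kmers, gene_idx, names = [], [], []
        for gi, (gene_id, prot) in enumerate(proteins[gid].items()):
            names.append(gene_id)
            codes = aa_code[np.frombuffer(prot.encode("ascii"), dtype=np.uint8)]
            m = codes.size - kmer_size + 1
            if m <= 0:
                continue
            km = np.zeros(m, dtype=np.int64)
            bad = np.zeros(m, dtype=bool)
            for jj in range(kmer_size):
                win = codes[jj : jj + m]
                km = km * 20 + np.maximum(win, 0)
                bad |= win < 0
            kmers.extend(km[~bad].tolist())
            gene_idx.extend([gi] * int((~bad).sum()))
        k = np.array(kmers, dtype=np.int64)
        g = np.array(gene_idx, dtype=np.int32)
        order = np.argsort(k, kind="stable")
        indexes[gid] = (k[order], g[order], names)
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        ka, ga, names_a = indexes[ids[i]]
        kb, gb, names_b = indexes[ids[j]]
        prots_a = proteins[ids[i]]
        prots_b = proteins[ids[j]]
        if ka.size == 0 or kb.size == 0:
            continue
        left = np.searchsorted(kb, ka, side="left")
        right = np.searchsorted(kb, ka, side="right")
        cnt = np.minimum(right - left, 2)
        keys = []
        for off in range(2):
            sel = cnt > off
            if sel.any():
                keys.append(ga[sel].astype(np.int64) << 32 | gb[left[sel] + off].astype(np.int64))
        if not keys:
            continue
        uniq, counts = np.unique(np.concatenate(keys), return_counts=True)
        uniq = uniq[counts >= min_shared_kmers]
        identities = {}
        for key in uniq:
            a_idx, b_idx = int(key >> 32), int(key & 0xFFFFFFFF)
            pa, pb = prots_a[names_a[a_idx]], prots_b[names_b[b_idx]]
            ident = _aa_identity(pa, pb)
            if ident >= min_identity:
                identities[(names_a[a_idx], names_b[b_idx])] = (ident, max(len(pa), len(pb)))
        if not identities:
            continue
        from .gene_share import _best_per_query

        best_a = _best_per_query(identities, side=0)
        best_b = _best_per_query(identities, side=1)
        idents = [identities[(qa, qb)][0] for qa, qb in best_a.items()
                  if best_b.get(qb) == qa]
        if idents:
            values[i, j] = values[j, i] = 1.0 - float(np.mean(idents))
    return AADMatrix(genome_ids=ids, values=values)


# ---------------------------------------------------------------------------
# delta statistics


@dataclass
class DiscordanceRecord:
    """One query leaf's nearest-neighbour contrast on one gene tree."""

    gene_id: str
    query: str  # genome id of the query leaf
    query_leaf: str  # full leaf label (copies carry a |suffix)
    nearest_overall: str  # M: genome with the lowest AAD to the query
    neighbors: list[str]  # genome ids of the closest gene-tree leaves
    tree_distances: list[float]  # gene-tree path lengths to those leaves
    deltas: list[float]  # D(Q, N_j) - D(Q, M), >= 0 by construction
    p_values: list[float] = field(default_factory=list)
    q_values: list[float] = field(default_factory=list)
    flagged: bool = False  # fewer neighbours than requested, or no test possible


def _leaf_genome(label: str) -> str:
    return label.split("|")[0]


def delta_statistics(
    gene_tree: dendropy.Tree,
    aad: AADMatrix,
    k: int = 3,
    gene_id: str = "gene",
) -> list[DiscordanceRecord]:
    """Delta statistics for every query leaf of one gene tree.

    For each leaf Q: ``M`` is the genome with the lowest AAD to Q's genome;
    ``N_1..N_k`` are the k closest leaves by gene-tree path length (ties broken
    by label); each ``delta_j = D(Q, N_j) - D(Q, M) >= 0``.  Each copy of a
    multi-copy gene is processed as an independent query; leaves of Q's own
    genome are never candidate neighbours (their AAD of zero would make the
    contrast ill-defined).  Leaves whose genome is absent from the AAD matrix
    are skipped; queries with fewer than k usable neighbours are flagged.
    """
    pdm = gene_tree.phylogenetic_distance_matrix()
    taxa = list(gene_tree.taxon_namespace)
    known = set(aad.genome_ids)
    records = []
    for t_q in taxa:
        q_genome = _leaf_genome(t_q.label)
        if q_genome not in known:
            continue
        m = aad.nearest(q_genome)
        if m is None:
            continue
        d_qm = aad.get(q_genome, m)
        cand = []
        for t in taxa:
            if t is t_q:
                continue
            genome = _leaf_genome(t.label)
            if genome == q_genome or genome not in known:
                continue
            if math.isnan(aad.get(q_genome, genome)):
                continue
            cand.append((pdm.patristic_distance(t_q, t), t.label, genome))
        cand.sort()
        chosen = cand[:k]
        deltas = [aad.get(q_genome, g) - d_qm for _, _, g in chosen]
        records.append(DiscordanceRecord(
            gene_id=gene_id, query=q_genome, query_leaf=t_q.label,
            nearest_overall=m,
            neighbors=[g for _, _, g in chosen],
            tree_distances=[d for d, _, _ in chosen],
            deltas=deltas,
            flagged=len(chosen) < k,
        ))
    return records


def fit_exponential_robust(deltas) -> float:
    """Robust exponential rate: ``lambda_hat = ln 2 / median(delta)``.

    The median-based estimator resists the LGT outliers the test is meant to
    find.  Returns NaN when the median is zero (no test possible).
    """
    d = np.asarray(list(deltas), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one delta")
    med = float(np.median(d))
    if med <= 0:
        return math.nan
    return math.log(2.0) / med


def delta_pvalues(
    records: list[DiscordanceRecord],
    *,
    tail: str = "survival",
    bh_scope: str = "pooled",
) -> list[DiscordanceRecord]:
    """Assign per-delta p-values from the per-gene exponential null, plus BH q.

    The significance measure is the upper tail ``p = exp(-lambda * delta)``
    (large deltas are the LGT signal); ``tail="cdf"`` exposes the literal
    lower-tail variant as a compatibility flag.  BH correction is applied over
    the pooled set of all tests across genes (``bh_scope="per_gene"`` for
    sensitivity analysis).  Records from genes whose rate is undefined keep
    empty p/q lists and are flagged.
    """
    from statsmodels.stats.multitest import multipletests

    by_gene: dict[str, list[DiscordanceRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    lam: dict[str, float] = {}
    for gene, recs in by_gene.items():
        all_d = [d for r in recs for d in r.deltas]
        lam[gene] = fit_exponential_robust(all_d) if all_d else math.nan

    flat: list[tuple[DiscordanceRecord, int, float]] = []
    for r in records:
        lmb = lam[r.gene_id]
        if math.isnan(lmb):
            r.p_values, r.q_values = [], []
            r.flagged = True
            continue
        r.p_values = []
        for j, d in enumerate(r.deltas):
            p = math.exp(-lmb * d) if tail == "survival" else -math.expm1(-lmb * d)
            r.p_values.append(p)
            flat.append((r, j, p))
        r.q_values = [math.nan] * len(r.deltas)

    if flat:
        if bh_scope == "pooled":
            groups = [flat]
        elif bh_scope == "per_gene":
            by: dict[str, list] = {}
            for item in flat:
                by.setdefault(item[0].gene_id, []).append(item)
            groups = list(by.values())
        else:
            raise ValueError(f"unknown bh_scope {bh_scope!r}")
        for group in groups:
            pvals = [p for _, _, p in group]
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for (r, j, _), q in zip(group, qvals):
                r.q_values[j] = float(q)
    return records


def hellinger_fit(deltas, n_bins: int = 20) -> list[tuple[str, float]]:
    """Rank Exponential / Log-Normal / Gamma fits by Hellinger distance.

    The Exponential is fitted with the robust median rule, the others by
    maximum likelihood (location fixed at zero).  Each fitted model's support
    is cut into ``n_bins`` equal-probability bins and the squared Hellinger
    distance ``H^2 = 1 - sum(sqrt(p_i q_i))`` against the empirical bin masses
    is reported, smallest (best) first.
    """
    from scipy import stats

    d = np.asarray(list(deltas), dtype=float)
    d = d[d > 0]
    if d.size < 30:
        raise ValueError("need at least 30 positive deltas")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate (constant) sample")
    lam = fit_exponential_robust(d)
    models = {"exponential": stats.expon(scale=1.0 / lam)}
    logd = np.log(d)
    models["lognormal"] = stats.lognorm(s=float(logd.std(ddof=0)),
                                        scale=float(np.exp(logd.mean())))
    a, _, scale = stats.gamma.fit(d, floc=0)
    models["gamma"] = stats.gamma(a=a, scale=scale)
    out = []
    p_model = 1.0 / n_bins
    n_params = {"exponential": 1, "lognormal": 2, "gamma": 2}
    for name, dist in models.items():
        edges = dist.ppf(np.linspace(0.0, 1.0, n_bins + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        q_emp, _ = np.histogram(d, bins=edges)
        q_emp = q_emp / d.size
        h2 = 1.0 - float(np.sum(np.sqrt(p_model * q_emp)))
        out.append((name, h2))
    # parsimony tie-break: the gamma family nests the exponential, so on
    # near-exponential data their distances coincide to within sampling noise;
    # rank near-ties (within 0.002) by parameter count
    out.sort(key=lambda t: (round(t[1] / 0.002), n_params[t[0]], t[1]))
    return out


# ---------------------------------------------------------------------------
# quartet distances


def _topological_distances(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    n = len(labels)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.path_edge_count(taxa[labels[i]], taxa[labels[j]])
        dm[i, j] = dm[j, i] = d
    return dm


def _quartet_topologies(dm: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Resolved split per quadruple: 0=ab|cd, 1=ac|bd, 2=ad|bc, -1=unresolved.

    Uses the four-point condition on topological distances: the true split is
    the pairing with the strictly smallest distance sum.
    """
    a, b, c, d = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    s0 = dm[a, b] + dm[c, d]
    s1 = dm[a, c] + dm[b, d]
    s2 = dm[a, d] + dm[b, c]
    sums = np.stack([s0, s1, s2], axis=1)
    order = np.argsort(sums, axis=1)
    smallest = np.take_along_axis(sums, order[:, :1], axis=1)[:, 0]
    second = np.take_along_axis(sums, order[:, 1:2], axis=1)[:, 0]
    topo = order[:, 0].astype(np.int64)
    topo[np.isclose(smallest, second)] = -1
    return topo


def quartet_distance(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    *,
    unresolved: str = "different",
) -> float:
    """Normalised quartet distance between two trees on their shared leaves.

    Fraction of leaf quadruples whose induced topologies differ, over all
    ``C(n, 4)`` quadruples.  When exactly one tree resolves a quadruple the
    default convention counts it as different; pass ``unresolved="same"`` to
    count one-sided unresolved quadruples as matching.
    """
    labels = sorted(
        {leaf.taxon.label for leaf in t1.leaf_node_iter()}
        & {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    )
    n = len(labels)
    if n < 4:
        raise ValueError(f"need >= 4 shared leaves, got {n}")
    quads = np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
    topo1 = _quartet_topologies(_topological_distances(t1, labels), quads)
    topo2 = _quartet_topologies(_topological_distances(t2, labels), quads)
    both_resolved = (topo1 >= 0) & (topo2 >= 0)
    different = both_resolved & (topo1 != topo2)
    one_sided = (topo1 >= 0) != (topo2 >= 0)
    if unresolved == "different":
        different = different | one_sided
    elif unresolved != "same":
        raise ValueError(f"unknown unresolved convention {unresolved!r}")
    return float(different.sum()) / len(quads)


# ---------------------------------------------------------------------------
# subset construction and noise-corrected discordance


@dataclass
class SubsetRecord:
    threshold: float
    genome_ids: list[str]


def single_linkage_subsets(
    aad: AADMatrix,
    thresholds=None,
    subsets_per_threshold: int = 50,
    subset_size: int = 10,
    seed: int = 0,
) -> tuple[list[SubsetRecord], list[float]]:
    """Random genome subsets drawn from distinct single-linkage clusters.

    The single-linkage dendrogram of the AAD matrix is built once; at each
    threshold the clusters are the connected components below that cut and each
    subset draws one genome from ``subset_size`` distinct clusters, controlling
    the subset's pairwise AAD range.  Thresholds yielding fewer clusters than
    ``subset_size`` are skipped and reported.  Returns (subsets, skipped
    thresholds).
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if thresholds is None:
        thresholds = [round(0.005 * k, 4) for k in range(1, 60)]  # 0.5%..29.5%
    v = aad.values
    if np.isnan(v).any():
        raise ValueError("AAD matrix must be complete for subset construction")
    Z = linkage(squareform(v, checks=False), method="single")
    rng = np.random.default_rng(seed)
    ids = np.array(aad.genome_ids)
    subsets, skipped = [], []
    for thr in thresholds:
        clusters = fcluster(Z, t=thr, criterion="distance")
        labels = np.unique(clusters)
        if labels.size < subset_size:
            skipped.append(thr)
            continue
        members = {lab: ids[clusters == lab] for lab in labels}
        for _ in range(subsets_per_threshold):
            chosen_clusters = rng.choice(labels, size=subset_size, replace=False)
            genomes = [str(rng.choice(members[lab])) for lab in chosen_clusters]
            subsets.append(SubsetRecord(threshold=thr, genome_ids=sorted(genomes)))
    if not subsets:
        raise ValueError("no threshold yields enough clusters for a subset")
    return subsets, skipped


@dataclass
class QuartetSample:
    """Noise-corrected quartet discordance of one genome subset."""

    subset: list[str]
    q_s: float  # gene tree vs species tree
    q_noise: float  # mean gene tree vs its bootstrap replicates
    corrected: float  # q_s - q_noise (may be negative)
    mean_pairwise_aad: float


def _prune_to(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    return tree.extract_tree_with_taxa_labels(labels)


def noise_corrected_discordance(
    gene_tree: dendropy.Tree,
    bootstrap_trees: list[dendropy.Tree],
    species_tree: dendropy.Tree,
    subset,
    aad: AADMatrix | None = None,
) -> QuartetSample:
    """Quartet discordance of a subset, corrected for gene-tree noise.

    All trees are pruned to the subset; ``q_s`` is the gene-vs-species quartet
    distance and ``q_noise`` the mean gene-vs-bootstrap distance; the reported
    discordance is ``q_s - q_noise``.
    """
    labels = set(subset.genome_ids if isinstance(subset, SubsetRecord) else subset)
    for name, tree in [("gene tree", gene_tree), ("species tree", species_tree)] + [
        (f"bootstrap {i}", t) for i, t in enumerate(bootstrap_trees)
    ]:
        present = {t.label for t in tree.taxon_namespace}
        missing = labels - present
        if missing:
            raise ValueError(f"{name} lacks subset leaves: {sorted(missing)}")
    gene_p = _prune_to(gene_tree, labels)
    species_p = _prune_to(species_tree, labels)
    q_s = quartet_distance(gene_p, species_p)
    q_noise = float(np.mean([
        quartet_distance(gene_p, _prune_to(bt, labels)) for bt in bootstrap_trees
    ])) if bootstrap_trees else 0.0
    mean_aad = math.nan
    if aad is not None:
        ids = sorted(labels)
        vals = [aad.get(a, b) for a, b in itertools.combinations(ids, 2)]
        mean_aad = float(np.mean(vals))
    return QuartetSample(subset=sorted(labels), q_s=q_s, q_noise=q_noise,
                         corrected=q_s - q_noise, mean_pairwise_aad=mean_aad)


# ---------------------------------------------------------------------------
# synthetic discordance data


def simulate_discordance_dataset(
    n_genomes: int = 32,
    n_genes: int = 40,
    n_transfers: int = 1,
    seed: int = 0,
    *,
    branch_jitter_sd: float = 0.35,
    aad_noise_sd: float = 0.05,
):
    """Synthetic species tree, gene trees, AAD matrix and planted transfers.

    Genomes evolve on a random coalescent species tree; the AAD between two
    genomes is their species-tree path length times a small log-normal
    measurement noise.  Concordant gene trees share the species topology with
    log-normal branch-length jitter.  Each planted transfer regrafts one
    query leaf next to a distant donor leaf in one gene tree, emulating a
    homologous replacement from a divergent lineage.

    Returns ``(species_tree, {gene_id: tree}, AADMatrix, planted)`` where
    ``planted`` is a list of ``(gene_id, query_genome, donor_genome)``.
    """
    rng = np.random.default_rng(seed)
    ids = [f"g{i:02d}" for i in range(n_genomes)]

    def balanced(labels):
        if len(labels) == 1:
            return labels[0]
        half = len(labels) // 2
        return f"({balanced(labels[:half])},{balanced(labels[half:])})"

    species = dendropy.Tree.get(data=balanced(ids) + ";", schema="newick",
                                preserve_underscores=True)
    # balanced topology: every genome has a comparably dense neighbourhood, as
    # in a large evenly-sampled collection; branch lengths grow geometrically
    # with depth so close relatives are very close while the collection spans a
    # wide divergence range (dense clades, large diameter)
    heights = {}
    for node in species.postorder_node_iter():
        heights[node] = 0 if node.is_leaf() else 1 + max(
            heights[c] for c in node.child_nodes())
    for e in species.preorder_edge_iter():
        if e.head_node is not species.seed_node:
            e.length = float(0.001 * 3.0 ** heights[e.head_node]
                             * np.exp(rng.normal(0.0, 0.25)))

    taxa = {t.label: t for t in species.taxon_namespace}
    pdm = species.phylogenetic_distance_matrix()
    base = np.zeros((n_genomes, n_genomes))
    for i, j in itertools.combinations(range(n_genomes), 2):
        base[i, j] = base[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
    noise = np.exp(rng.normal(0.0, aad_noise_sd, size=base.shape))
    noise = np.sqrt(noise * noise.T)  # keep symmetry
    values = base * noise
    np.fill_diagonal(values, 0.0)
    aad = AADMatrix(genome_ids=ids, values=values)

    def jittered_gene_tree() -> dendropy.Tree:
        t = species.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length = float(e.length * np.exp(rng.normal(0.0, branch_jitter_sd)))
        return t

    gene_trees = {f"gene{k:03d}": jittered_gene_tree() for k in range(n_genes)}
    planted = []
    gene_ids = sorted(gene_trees)
    chosen_genes = rng.choice(len(gene_ids), size=n_transfers, replace=False)
    for gk in chosen_genes:
        gid = gene_ids[int(gk)]
        # pick the most distant genome pair as (query, donor)
        q_i, d_i = np.unravel_index(np.argmax(base), base.shape)
        query, donor = ids[q_i], ids[d_i]
        _regraft_leaf(gene_trees[gid], query, donor, branch_length=0.002)
        planted.append((gid, query, donor))
    return species, gene_trees, aad, planted


def _regraft_leaf(tree: dendropy.Tree, leaf_label: str, sister_label: str,
                  branch_length: float = 0.002) -> None:
    """Move a leaf so it becomes the sister of another leaf (in place)."""
    leaf = tree.find_node_with_taxon_label(leaf_label)
    sister = tree.find_node_with_taxon_label(sister_label)
    if leaf is None or sister is None:
        raise ValueError("leaf to regraft not found")
    parent = leaf.parent_node
    parent.remove_child(leaf)
    tree.suppress_unifurcations()
    sister_parent = sister.parent_node
    sister_edge_len = sister.edge.length or 0.0
    new_node = dendropy.Node()
    sister_parent.remove_child(sister)
    sister_parent.add_child(new_node)
    new_node.edge.length = max(sister_edge_len - branch_length, 0.0)
    new_node.add_child(sister)
    sister.edge.length = branch_length
    leaf.edge.length = branch_length
    new_node.add_child(leaf)
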