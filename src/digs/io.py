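"""Core genome data types and readers/writers for FASTA, manifests and Newick trees.

Genes are handled as standalone ORF sequences already oriented 5'->3'; no genome
coordinates are required by any downstream statistic.  Simulator-built genomes
additionally carry an optional coordinate layout (used only for incompleteness
degradation), stored opaquely on :class:`Genome`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LENGTH_WINDOW = (500, 1500)
"""Gene length window (nt) used for gene-share statistics."""

_ACGT = frozenset("ACGT")


class GenomeIOError(ValueError):
    """Raised on malformed genome inputs (empty files, duplicate ids, bad manifests)."""


@dataclass
class GeneRecord:
    """A single ORF nucleotide sequence belonging to a genome."""

    gene_id: str
    genome_id: str
    sequence: str
    has_ambiguity: bool = field(init=False)
    frame_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"gene {self.gene_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        self.has_ambiguity = not _ACGT.issuperset(self.sequence)
        # real inputs may violate the codon frame; flag, don't reject
        self.frame_ok = len(self.sequence) % 3 == 0

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def in_length_window(self) -> bool:
        lo, hi = LENGTH_WINDOW
        return lo <= self.length_nt <= hi


@dataclass
class Genome:
    """An ordered collection of ORFs with an assembly completeness estimate.

    ``completeness`` is the estimated fraction of the complete genome that was
    recovered (CheckM-style estimate for real assemblies, ground-truth retained
    gene fraction for simulated ones).  ``layout``/``genome_length`` are optional
    coordinate metadata carried opaquely (filled by the simulator).
    """

    genome_id: str
    genes: list[GeneRecord]
    completeness: float = 1.0
    taxon_label: str | None = None
    layout: dict[str, tuple[int, int]] | None = None
    genome_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise GenomeIOError(
                f"genome {self.genome_id!r}: completeness must be in (0, 1], "
                f"got {self.completeness}"
            )
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeIOError(
                    f"genome {self.genome_id!r}: duplicate gene id {g.gene_id!r}"
                )
            seen.add(g.gene_id)

    @property
    def n_observed_genes(self) -> int:
        return len(self.genes)

    @property
    def n_in_window(self) -> int:
        return sum(1 for g in self.genes if g.in_length_window)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GenomeSet:
    """A keyed collection of genomes plus free-text provenance."""

    genomes: dict[str, Genome]
    provenance: str = ""

    def __getitem__(self, genome_id: str) -> Genome:
        return self.genomes[genome_id]

    def __iter__(self):
        return iter(self.genomes.values())

    def __len__(self) -> int:
        return len(self.genomes)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)


def parse_gene_fasta(path, genome_id: str, completeness: float = 1.0) -> Genome:
    """Read a per-genome multi-FASTA of ORFs into a :class:`Genome`.

    Gene order follows file order; lower-case bases are canonicalised to
    upper-case; non-ACGT characters are retained but flag the record.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"{path}: duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        genes.append(GeneRecord(gene_id=rec.id, genome_id=genome_id, sequence=str(rec.seq)))
    if not genes:
        raise GenomeIOError(f"{path}: no records")
    return Genome(genome_id=genome_id, genes=genes, completeness=completeness)


def write_gene_fasta(genome: Genome, path) -> None:
    """Write a genome's ORFs as multi-FASTA (inverse of :func:`parse_gene_fasta`)."""
    records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in genome]
    SeqIO.write(records, str(path), "fasta")


def load_genome_set(manifest_path) -> GenomeSet:
    """Load genomes listed in a TSV manifest.

    Columns: ``genome_id``, ``fasta_path`` (relative paths resolved against the
    manifest location) and either ``completeness`` (fraction in (0,1]) or
    ``completeness_percent`` ((0,100]); the header token declares the dialect.
    Lines starting with ``#`` are comments.
    """
    import csv
    from pathlib import Path

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise GenomeIOError(f"{manifest_path}: empty manifest")
    header = rows[0]
    required = {"genome_id", "fasta_path"}
    if not required.issubset(header):
        raise GenomeIOError(f"{manifest_path}: manifest must have columns {sorted(required)}")
    if "completeness" in header:
        c_col, scale = header.index("completeness"), 1.0
    elif "completeness_percent" in header:
        c_col, scale = header.index("completeness_percent"), 0.01
    else:
        raise GenomeIOError(
            f"{manifest_path}: need a 'completeness' or 'completeness_percent' column"
        )
    id_col, fa_col = header.index("genome_id"), header.index("fasta_path")
    genomes: dict[str, Genome] = {}
    for row in rows[1:]:
        gid = row[id_col]
        if gid in genomes:
            raise GenomeIOError(f"{manifest_path}: duplicate genome_id {gid!r}")
        c = float(row[c_col]) * scale
        if not 0.0 < c <= 1.0:
            raise GenomeIOError(
                f"{manifest_path}: genome {gid!r}: completeness {c} outside (0, 1]"
            )
        fa = Path(row[fa_col])
        if not fa.is_absolute():
            fa = manifest_path.parent / fa
        if not fa.exists():
            raise GenomeIOError(f"{manifest_path}: genome {gid!r}: missing FASTA {fa}")
        genomes[gid] = parse_gene_fasta(fa, gid, completeness=c)
    return GenomeSet(genomes=genomes, provenance=f"loaded from {manifest_path}")


def write_genome_set(gset: GenomeSet, out_dir, manifest_name: str = "manifest.tsv") -> None:
    """Write every genome as FASTA plus a fraction-dialect manifest TSV."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["genome_id\tfasta_path\tcompleteness"]
    for genome in gset:
        fa = f"{genome.genome_id}.fna"
        write_gene_fasta(genome, out_dir / fa)
        lines.append(f"{genome.genome_id}\t{fa}\t{genome.completeness!r}")
    (out_dir / manifest_name).write_text("\n".join(lines) + "\n")


def read_newick(path_or_string) -> dendropy.Tree:
    """Parse a Newick tree; multifurcations allowed, negative branch lengths kept.

    Accepts a file path or a raw Newick string.  Path lengths between leaves are
    then computable with :func:`leaf_path_lengths`.
    """
    import os

    text = str(path_or_string)
    if os.path.exists(text):
        with open(text) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise GenomeIOError(f"unparseable Newick: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            warnings.warn(
                f"negative branch length {edge.length} kept on edge to "
                f"{edge.head_node}", stacklevel=2,
            )
    return tree


def leaf_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Sum-of-branch-length distances between every pair of leaf labels."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            d = pdm.patristic_distance(t1, t2)
            out[(t1.label, t2.label)] = d
            out[(t2.label, t1.label)] = d
    return out


def reconcile_tree_labels(tree: dendropy.Tree, gset: GenomeSet) -> dict[str, list[str]]:
    """Report which tree leaves map to genomes and which are orphaned.

    Leaf labels may carry copy suffixes separated by ``|`` (``genomeA|2``).
    Nothing is dropped; callers decide what to do with orphans.
    """
    known = set(gset.genomes)
    matched, orphan_leaves = [], []
    for taxon in tree.taxon_namespace:
        gid = taxon.label.split("|")[0]
        (matched if gid in known else orphan_leaves).append(taxon.label)
    missing = sorted(known - {lbl.split("|")[0] for lbl in matched})
    return {
        "matched": matched,
        "orphan_leaves": orphan_leaves,
        "genomes_without_leaves": missing,
    }
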