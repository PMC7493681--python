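"""Reading and validation of genomes, gene sets, manifests and tables.

Conventions
-----------
* Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  is converted on ingest.
* Sequences are uppercased on read.  Degenerate IUPAC codes are legal in
  genome/gene sequences (they simply never match anything but themselves
  in alignment) but illegal in primers.
* Replicon type is parsed from a ``replicon=`` key in FASTA headers
  (``chromosome``/``plasmid``), defaulting to ``unknown``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from skbio import TreeNode

__all__ = [
    "Contig",
    "GeneRecord",
    "GenomeRecord",
    "TaxonManifest",
    "GenomeIOError",
    "read_genomes",
    "read_gene_sets",
    "extract_cds",
    "read_manifest",
    "write_matrix",
    "read_matrix",
    "write_newick",
    "read_newick",
    "read_primer_table",
]

_NUC = set("ACGTNURYSWKMBDHV")


class GenomeIOError(ValueError):
    pass


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    replicon: str = "unknown"  # chromosome | plasmid | unknown


@dataclass(frozen=True)
class GeneRecord:
    """A CDS on the coding strand with 0-based half-open coordinates."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeIOError(f"{self.gene_id}: end must be > start")
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise GenomeIOError(f"{self.gene_id}: sequence length != end - start")


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[Contig] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise GenomeIOError(f"{self.genome_id}: duplicate contig ids")
        by_id = {c.contig_id: c for c in self.contigs}
        for g in self.genes:
            c = by_id.get(g.contig_id)
            if c is not None and g.end > len(c.sequence):
                raise GenomeIOError(f"gene {g.gene_id} exceeds contig {g.contig_id}")

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise GenomeIOError(f"{self.genome_id}: no contig {contig_id}")


@dataclass
class TaxonManifest:
    """genome_id -> taxon assignments plus the ordered marker target list."""

    assignments: dict[str, str]
    target_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.target_taxa:
            self.target_taxa = sorted(set(self.assignments.values()))
        for t in self.target_taxa:
            if t not in self.assignments.values():
                raise GenomeIOError(f"target taxon {t!r} has no genomes")

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def genomes_of(self, taxon: str) -> list[str]:
        gids = sorted(g for g, t in self.assignments.items() if t == taxon)
        if not gids:
            raise GenomeIOError(f"unknown taxon {taxon!r}")
        return gids


def _clean_seq(raw: str, what: str) -> str:
    seq = str(raw).upper()
    bad = set(seq) - _NUC
    if bad:
        raise GenomeIOError(f"{what}: illegal characters {sorted(bad)}")
    return seq


def _parse_replicon(description: str) -> str:
    m = re.search(r"replicon=(\S+)", description)
    if m and m.group(1) in ("chromosome", "plasmid"):
        return m.group(1)
    return "unknown"


def read_manifest(path: str | Path) -> TaxonManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "taxon"} <= set(df.columns):
        raise GenomeIOError("manifest needs genome_id and taxon columns")
    if df["genome_id"].duplicated().any():
        dup = df["genome_id"][df["genome_id"].duplicated()].iloc[0]
        raise GenomeIOError(f"duplicate genome_id {dup!r} in manifest")
    return TaxonManifest(assignments=dict(zip(df["genome_id"], df["taxon"])))


def read_genomes(
    paths: list[str | Path], manifest_path: str | Path
) -> tuple[list[GenomeRecord], TaxonManifest]:
    """Load genome FASTAs (one file per genome, id = file stem) + manifest."""
    manifest = read_manifest(manifest_path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    by_id: dict[str, Path] = {}
    for p in paths:
        p = Path(p)
        gid = p.stem
        if gid in seen:
            raise GenomeIOError(f"duplicate genome_id {gid!r}")
        seen.add(gid)
        by_id[gid] = p
    missing = sorted(set(manifest.assignments) - seen)
    if missing:
        raise GenomeIOError(f"manifest genomes without files: {missing}")
    for gid in sorted(seen):
        if gid not in manifest.assignments:
            raise GenomeIOError(f"genome {gid!r} missing from manifest")
        contigs = []
        for rec in SeqIO.parse(str(by_id[gid]), "fasta"):
            cid = rec.id.split("|")[-1]
            contigs.append(
                Contig(cid, _clean_seq(rec.seq, f"{gid}/{cid}"), _parse_replicon(rec.description))
            )
        if not contigs:
            raise GenomeIOError(f"empty FASTA for genome {gid!r}")
        records.append(GenomeRecord(genome_id=gid, contigs=contigs))
    return records, manifest


_DESC_RE = re.compile(r"(\S+)\|(\S+):(\d+)-(\d+)\(([+-])\)")


def read_gene_sets(paths: list[str | Path]) -> list[GeneRecord]:
    """Load per-genome CDS FASTAs (genome id = file stem).

    Coordinates are taken from a ``genome|contig:start-end(strand)``
    token in the description when present, else synthesized as a
    zero-based span on an unknown contig.
    """
    genes: list[GeneRecord] = []
    for p in paths:
        p = Path(p)
        gid = p.stem
        n_before = len(genes)
        for rec in SeqIO.parse(str(p), "fasta"):
            seq = _clean_seq(rec.seq, rec.id)
            m = _DESC_RE.search(rec.description)
            if m:
                _, cid, start, end, strand = m.groups()
                genes.append(GeneRecord(rec.id, gid, cid, int(start), int(end), strand, seq))
            else:
                genes.append(GeneRecord(rec.id, gid, "unplaced", 0, len(seq), "+", seq))
        if len(genes) == n_before:
            raise GenomeIOError(f"empty CDS FASTA for genome {gid!r}")
    return genes


def extract_cds(genome: GenomeRecord, gff_path: str | Path) -> list[GeneRecord]:
    """CDS features of a GFF3 file as GeneRecords on the coding strand.

    GFF3 1-based inclusive coordinates become 0-based half-open; minus
    strand features are reverse-complemented.  Gene ids synthesized from
    coordinates are ``genome|contig|start-end(strand)``.
    """
    import gffutils

    contigs = {c.contig_id: c for c in genome.contigs}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        cid = feat.seqid.split("|")[-1]
        if cid not in contigs:
            raise GenomeIOError(f"GFF seqid {feat.seqid!r} matches no contig of {genome.genome_id}")
        start, end = feat.start - 1, feat.end
        contig = contigs[cid]
        if start < 0 or end > len(contig.sequence):
            raise GenomeIOError(f"CDS {feat.seqid}:{feat.start}-{feat.end} outside contig bounds")
        gene_id = (
            feat.attributes["ID"][0]
            if "ID" in feat.attributes
            else f"{genome.genome_id}|{cid}|{start}-{end}({feat.strand})"
        )
        sub = contig.sequence[start:end]
        seq = sub if feat.strand == "+" else str(Seq(sub).reverse_complement())
        genes.append(GeneRecord(gene_id, genome.genome_id, cid, start, end, feat.strand, seq))
    return genes


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cluster_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cluster_id")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def read_primer_table(path: str | Path):
    """Parse a tab-separated primer table into PrimerPair objects.

    Expected columns: taxon, primer name, sequence (5'->3'), optional
    expected product size on the forward row.  Whitespace inside the
    sequence column is ignored, so triplet-spaced oligos are accepted.
    Forward/reverse mates share a name stem and end in ``-F`` / ``-R``.
    """
    from .primers import PrimerPair, melting_temperature, gc_fraction

    rows = []
    current_taxon = ""
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts and parts[0].strip():
            current_taxon = parts[0].strip()
        if len(parts) < 3 or parts[1].strip().lower() in ("primer name", "name"):
            continue
        name = parts[1].strip()
        seq = re.sub(r"\s+", "", parts[2]).upper()
        bad = set(seq) - set("ACGT")
        if bad:
            raise GenomeIOError(f"primer {name}: non-ACGT characters {sorted(bad)}")
        size = None
        if len(parts) > 3 and parts[3].strip():
            size = int(parts[3])
        rows.append((current_taxon, name, seq, size))

    def stem(name: str) -> str:
        return re.sub(r"[-_]?[FR]$", "", name)

    pairs = []
    fwd = {stem(n): (t, n, s, z) for t, n, s, z in rows if n.upper().endswith("F")}
    rev = {stem(n): (t, n, s, z) for t, n, s, z in rows if n.upper().endswith("R")}
    for key in fwd:
        if key not in rev:
            raise GenomeIOError(f"primer {fwd[key][1]} has no reverse mate")
        taxon, fname, fseq, fsize = fwd[key]
        _, _, rseq, rsize = rev[key]
        pairs.append(
            PrimerPair(
                name=key,
                taxon=taxon,
                forward=fseq,
                reverse=rseq,
                product_size=fsize or rsize or 0,
                tm_forward=melting_temperature(fseq),
                tm_reverse=melting_temperature(rseq),
                gc_forward=gc_fraction(fseq),
                gc_reverse=gc_fraction(rseq),
            )
        )
    return pairs
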