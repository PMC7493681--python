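"""Greedy centroid clustering of genes into a pan-genome.

The clustering rule is incremental, UCLUST-style: genes are processed in
deterministic order (length descending, gene_id ascending) and each gene
is compared against existing cluster centroids in decreasing order of
shared k-mer count (ties broken by centroid creation order).  The gene
joins the first centroid reached at identity >= threshold, otherwise it
founds a new cluster with itself as centroid.  The shared-k-mer
prefilter only prunes centroids with zero shared k-mers; comparisons are
additionally skipped when a provable identity upper bound (see
``align.identity_upper_bound``) already rules the centroid out, which
cannot change the result.

The default identity threshold of 0.50 mirrors the default of the
pan-genome pipelines this toolkit models; the presence/absence matrix
and the core/accessory/unique partition follow the standard definitions
(core = all genomes, unique = exactly one, accessory = the rest).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .align import identity_upper_bound, pairwise_identity
from .io import GeneRecord, TaxonManifest

__all__ = [
    "GeneCluster",
    "cluster_genes",
    "build_matrix",
    "partition",
    "taxon_core",
    "kmer_set",
    "best_hit_identity",
]

DEFAULT_THRESHOLD = 0.50
DEFAULT_K = 8


@dataclass
class GeneCluster:
    cluster_id: str
    representative: str  # gene_id of the centroid
    representative_seq: str
    members: list[tuple[str, str, float]] = field(default_factory=list)  # (gene_id, genome_id, identity)

    @property
    def gene_ids(self) -> list[str]:
        return [m[0] for m in self.members]


@lru_cache(maxsize=100_000)
def kmer_set(seq: str, k: int = DEFAULT_K) -> frozenset[int]:
    """k-mer content used by the prefilter, encoded deterministically.

    Cached: the same gene sequences are screened against many queries.
    """
    if len(seq) < k:
        return frozenset()
    raw = seq.encode("ascii")
    return frozenset(int.from_bytes(raw[i: i + k], "big") for i in range(len(raw) - k + 1))


def cluster_genes(
    genes: list[GeneRecord],
    threshold: float = DEFAULT_THRESHOLD,
    prefilter_k: int = DEFAULT_K,
    use_prefilter: bool = True,
) -> list[GeneCluster]:
    """Partition genes into clusters by greedy centroid assignment."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(genes, key=lambda g: (-len(g.sequence), g.gene_id))
    clusters: list[GeneCluster] = []
    centroid_kmers: list[frozenset[int]] = []
    postings: dict[int, list[int]] = defaultdict(list)  # kmer -> centroid indexes

    for gene in order:
        kmers = kmer_set(gene.sequence, prefilter_k)
        counts: dict[int, int] = defaultdict(int)
        for km in kmers:
            for ci in postings.get(km, ()):
                counts[ci] += 1
        if use_prefilter:
            candidates = sorted(counts, key=lambda ci: (-counts[ci], ci))
        else:
            shared = sorted(counts, key=lambda ci: (-counts[ci], ci))
            rest = [ci for ci in range(len(clusters)) if ci not in counts]
            candidates = shared + rest

        home = None
        lg = len(gene.sequence)
        for ci in candidates:
            rep = clusters[ci].representative_seq
            if min(len(rep), lg) / max(len(rep), lg) < threshold:
                continue
            if identity_upper_bound(gene.sequence, rep) < threshold:
                continue
            ident = pairwise_identity(gene.sequence, rep).identity
            if ident >= threshold:
                home = (ci, ident)
                break
        if home is None:
            ci = len(clusters)
            clusters.append(
                GeneCluster(
                    cluster_id=f"PC{ci + 1:05d}",
                    representative=gene.gene_id,
                    representative_seq=gene.sequence,
                    members=[(gene.gene_id, gene.genome_id, 1.0)],
                )
            )
            centroid_kmers.append(kmers)
            for km in kmers:
                postings[km].append(ci)
        else:
            ci, ident = home
            clusters[ci].members.append((gene.gene_id, gene.genome_id, ident))
    return clusters


def build_matrix(clusters: list[GeneCluster], manifest: TaxonManifest) -> pd.DataFrame:
    """Clusters x genomes copy-count matrix (ints, genomes sorted)."""
    genome_ids = sorted(manifest.assignments)
    index = [c.cluster_id for c in clusters]
    mat = pd.DataFrame(0, index=index, columns=genome_ids, dtype=int)
    for c in clusters:
        for _, genome_id, _ in c.members:
            if genome_id not in manifest.assignments:
                raise ValueError(f"genome {genome_id!r} absent from manifest")
            mat.loc[c.cluster_id, genome_id] += 1
    return mat


def partition(matrix: pd.DataFrame) -> tuple[set[str], set[str], set[str]]:
    """Split cluster ids into (core, accessory, unique) by genome occupancy."""
    if matrix.shape[1] < 2:
        raise ValueError("partition needs >= 2 genomes")
    present = (matrix > 0).sum(axis=1)
    n = matrix.shape[1]
    core = set(matrix.index[present == n])
    unique = set(matrix.index[present == 1])
    accessory = set(matrix.index) - core - unique
    return core, accessory, unique


def taxon_core(
    matrix: pd.DataFrame,
    manifest: TaxonManifest,
    taxon: str,
    presence_fraction: float = 1.0,
) -> set[str]:
    """Clusters present in >= presence_fraction of the taxon's genomes."""
    gids = manifest.genomes_of(taxon)  # raises on unknown taxon
    sub = (matrix[gids] > 0).sum(axis=1)
    need = presence_fraction * len(gids)
    return set(matrix.index[sub >= need])


def best_hit_identity(
    query: str,
    subjects: list[tuple[str, str]],
    k: int = DEFAULT_K,
    use_prefilter: bool = True,
    floor: float = 0.0,
) -> tuple[float, str | None]:
    """Best global-alignment identity of ``query`` against (id, seq) subjects.

    Exact maximum over all subjects sharing at least one k-mer with the
    query (subjects with no shared k-mer count as identity 0); the
    upper-bound prune only skips subjects that provably cannot beat the
    running maximum.  ``floor`` seeds the running maximum when a hit at
    that identity is already known elsewhere.
    """
    lq = len(query)
    best, best_id = floor, None
    qk: frozenset[int] | None = None
    # identity <= min(len)/max(len): visit subjects in decreasing order of
    # that free bound so the scan can stop as soon as it drops below best
    order = sorted(
        subjects, key=lambda s: (-min(len(s[1]), lq) / max(len(s[1]), lq), s[0])
    )
    for sid, seq in order:
        if min(len(seq), lq) / max(len(seq), lq) <= best:
            break
        if use_prefilter:
            if qk is None:
                qk = kmer_set(query, k)
            if qk.isdisjoint(kmer_set(seq, k)):
                continue  # recorded as identity 0 by convention
        if identity_upper_bound(query, seq) <= best:
            continue
        ident = pairwise_identity(query, seq).identity
        if ident > best:
            best, best_id = ident, sid
    return best, best_id


def cluster_table(clusters: list[GeneCluster]) -> pd.DataFrame:
    """Long-format membership table: cluster_id, gene_id, genome_id, identity."""
    rows = [
        (c.cluster_id, gid, genome, round(ident, 6))
        for c in clusters
        for gid, genome, ident in c.members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "gene_id", "genome_id", "identity"])
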