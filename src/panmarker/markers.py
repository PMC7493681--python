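"""Taxon-specific marker selection and in-silico verification.

A marker candidate starts from a taxon-core cluster and is scored by two
identities: ``within_min_identity`` — the minimum, over target-taxon
genomes, of the best identity between the cluster representative and any
gene of that genome — and ``cross_max_identity`` — the maximum identity
of the representative against any gene of any non-target genome.  With
the default thresholds a marker is accepted when it is >= 0.90 within
the target taxon and <= 0.50 against everything else, the operational
form of the "present in all members of the taxon, absent elsewhere"
definition of a diagnostic marker.

The cross screen is exact at gene level: identities of non-target genes
that co-clustered with the candidate are already known from clustering
(the representative is the centroid), and the remaining genes are
scanned with a provable upper-bound prune, so a gene is only skipped
when it cannot change the maximum.  Genes sharing no k-mer with the
representative are recorded as identity 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .align import identity_upper_bound, pairwise_identity
from .io import GeneRecord, GenomeRecord, TaxonManifest
from .pangenome import GeneCluster, best_hit_identity, kmer_set, taxon_core

__all__ = [
    "MarkerCandidate",
    "select_candidates",
    "mobile_element_filter",
    "verify_markers",
    "cluster_consensus",
]

ID_WITHIN = 0.90
ID_CROSS = 0.50


@dataclass(frozen=True)
class MarkerCandidate:
    taxon: str
    cluster_id: str
    representative: str
    sequence: str
    within_min_identity: float
    cross_max_identity: float
    replicon: str = "unknown"
    status: str = "candidate"  # candidate|accepted|rejected_cross|rejected_within|rejected_mobile


def select_candidates(
    matrix: pd.DataFrame,
    clusters: list[GeneCluster],
    genes: list[GeneRecord],
    manifest: TaxonManifest,
    taxon: str,
    id_within: float = ID_WITHIN,
    id_cross: float = ID_CROSS,
    presence_fraction: float = 1.0,
    use_prefilter: bool = True,
    exhaustive: bool = False,
) -> list[MarkerCandidate]:
    """Score every taxon-core cluster as a marker candidate for ``taxon``.

    With ``exhaustive=False`` (default) the screens stop as soon as a
    candidate's fate is decided: a candidate whose own cluster already
    contains a non-target gene above ``id_cross`` is rejected without
    scanning the remaining non-target genes (its reported
    ``cross_max_identity`` is then the largest identity observed, a lower
    bound on the true maximum), and a target genome whose co-clustered
    copy already clears ``id_within`` is not re-scanned for a better hit.
    Accepted candidates are always screened exhaustively, so acceptance
    itself never depends on the flag; ``exhaustive=True`` additionally
    makes both reported identities exact maxima for every candidate.
    """
    targets = set(manifest.genomes_of(taxon))
    core_ids = taxon_core(matrix, manifest, taxon, presence_fraction)
    by_id = {c.cluster_id: c for c in clusters}
    genes_by_genome: dict[str, list[tuple[str, str]]] = {}
    for g in genes:
        genes_by_genome.setdefault(g.genome_id, []).append((g.gene_id, g.sequence))
    non_target_genomes = sorted(set(manifest.assignments) - targets)

    out: list[MarkerCandidate] = []
    for cid in sorted(core_ids):
        cluster = by_id[cid]
        rep = cluster.representative_seq

        # Within-taxon floor comes straight from cluster membership
        # (identity-to-centroid IS representative-vs-gene identity), then
        # each target genome's remaining genes are scanned with the prune.
        within_vals = []
        member_best: dict[str, float] = {}
        member_ids: dict[str, set[str]] = {}
        for gid, genome, ident in cluster.members:
            if genome in targets:
                member_best[genome] = max(member_best.get(genome, 0.0), ident)
                member_ids.setdefault(genome, set()).add(gid)
        for genome in sorted(targets):
            floor = member_best.get(genome, 0.0)
            if not exhaustive and floor >= id_within:
                within_vals.append(floor)
                continue
            others = [
                (gid, seq)
                for gid, seq in genes_by_genome.get(genome, [])
                if gid not in member_ids.get(genome, set())
            ]
            best, _ = best_hit_identity(rep, others, use_prefilter=use_prefilter, floor=floor)
            within_vals.append(best)
        within_min = min(within_vals) if within_vals else 0.0

        # Cross screen: seed with co-clustered non-target genes, then scan.
        cross_max = 0.0
        co_clustered: set[str] = set()
        for gid, genome, ident in cluster.members:
            if genome not in targets:
                cross_max = max(cross_max, ident)
                co_clustered.add(gid)
        if exhaustive or cross_max <= id_cross:
            others = [
                (gid, seq)
                for genome in non_target_genomes
                for gid, seq in genes_by_genome.get(genome, [])
                if gid not in co_clustered
            ]
            cross_max, _ = best_hit_identity(
                rep, others, use_prefilter=use_prefilter, floor=cross_max
            )

        status = "accepted"
        if cross_max > id_cross:
            status = "rejected_cross"
        elif within_min < id_within:
            status = "rejected_within"
        out.append(
            MarkerCandidate(
                taxon=taxon,
                cluster_id=cid,
                representative=cluster.representative,
                sequence=rep,
                within_min_identity=within_min,
                cross_max_identity=cross_max,
                status=status,
            )
        )
    out.sort(key=lambda c: (c.cross_max_identity, -c.within_min_identity, c.cluster_id))
    return out


def mobile_element_filter(
    candidates: list[MarkerCandidate],
    genomes: list[GenomeRecord],
    genes: list[GeneRecord],
    clusters: list[GeneCluster],
    manifest: TaxonManifest,
    exclusion_fasta: str | Path | None = None,
    hit_identity: float = 0.80,
) -> list[MarkerCandidate]:
    """Reject candidates on plasmid replicons or matching an exclusion set.

    A candidate is ``rejected_mobile`` when any of its target-taxon source
    genes sits on a plasmid-flagged contig, or when its representative
    aligns to any exclusion sequence (phage/plasmid database extract
    supplied by the operator) at identity >= ``hit_identity``.
    """
    replicon_of: dict[tuple[str, str], str] = {}
    for gr in genomes:
        for c in gr.contigs:
            replicon_of[(gr.genome_id, c.contig_id)] = c.replicon
    gene_loc = {g.gene_id: (g.genome_id, g.contig_id) for g in genes}
    members_of = {c.cluster_id: c.members for c in clusters}

    exclusion: list[tuple[str, str]] = []
    if exclusion_fasta is not None:
        if not Path(exclusion_fasta).exists():
            raise FileNotFoundError(f"exclusion FASTA not found: {exclusion_fasta}")
        exclusion = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(exclusion_fasta), "fasta")
        ]

    out: list[MarkerCandidate] = []
    for cand in candidates:
        targets = set(manifest.genomes_of(cand.taxon))
        replicon = "chromosome"
        mobile = False
        for gid, genome, _ in members_of.get(cand.cluster_id, []):
            if genome not in targets:
                continue
            rep = replicon_of.get(gene_loc.get(gid, (genome, "?")), "unknown")
            if rep == "plasmid":
                replicon = "plasmid"
                mobile = True
                break
            if rep == "unknown" and replicon != "plasmid":
                replicon = "unknown"
        if not mobile and exclusion:
            for _, seq in exclusion:
                if identity_upper_bound(cand.sequence, seq) < hit_identity:
                    continue
                if pairwise_identity(cand.sequence, seq).identity >= hit_identity:
                    mobile = True
                    break
        status = "rejected_mobile" if mobile else cand.status
        out.append(replace(cand, replicon=replicon, status=status))
    return out


def verify_markers(
    markers: list[MarkerCandidate],
    genes: list[GeneRecord],
    genome_ids: list[str] | None = None,
    use_prefilter: bool = True,
) -> pd.DataFrame:
    """Markers x genomes table of best-hit identities (the heatmap analog).

    A genome with zero genes yields a row of zeros.
    """
    if not markers:
        raise ValueError("verify_markers needs >= 1 marker")
    genes_by_genome: dict[str, list[tuple[str, str]]] = {}
    for g in genes:
        genes_by_genome.setdefault(g.genome_id, []).append((g.gene_id, g.sequence))
    genomes = sorted(genome_ids) if genome_ids is not None else sorted(genes_by_genome)
    rows = []
    for m in markers:
        row = []
        for genome in genomes:
            best, _ = best_hit_identity(
                m.sequence, genes_by_genome.get(genome, []), use_prefilter=use_prefilter
            )
            row.append(round(best, 6))
        rows.append(row)
    idx = [f"{m.taxon}:{m.cluster_id}" for m in markers]
    return pd.DataFrame(rows, index=idx, columns=genomes)


def cluster_consensus(
    cluster: GeneCluster,
    genes: list[GeneRecord],
    restrict_genomes: set[str] | None = None,
) -> str:
    """Majority-rule consensus of a cluster's member sequences.

    Intended as the primer-design template: a single member copy carries
    its own private substitutions, which would turn into systematic
    mismatches in every other genome of the taxon; the per-column
    majority removes them.  Only members of the modal sequence length
    participate (gene families here diverge by substitutions, so length
    outliers are partial or mis-clustered copies); ties fall back to the
    representative's base.
    """
    seq_of = {g.gene_id: g.sequence for g in genes}
    seqs = [
        seq_of[gid]
        for gid, genome, _ in cluster.members
        if gid in seq_of and (restrict_genomes is None or genome in restrict_genomes)
    ]
    rep = cluster.representative_seq
    if not seqs:
        return rep
    lengths = pd.Series([len(s) for s in seqs])
    modal = int(lengths.mode().iloc[0])
    seqs = [s for s in seqs if len(s) == modal]
    template = rep if len(rep) == modal else seqs[0]
    out = []
    for i in range(modal):
        column = [s[i] for s in seqs]
        counts = {}
        for b in column:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = sorted(b for b, n in counts.items() if n == top)
        out.append(template[i] if template[i] in winners else winners[0])
    return "".join(out)


def candidate_table(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.taxon, c.cluster_id, c.representative, c.status, c.replicon,
             round(c.within_min_identity, 6), round(c.cross_max_identity, 6),
             len(c.sequence))
            for c in candidates
        ],
        columns=["taxon", "cluster_id", "representative", "status", "replicon",
                 "within_min_identity", "cross_max_identity", "length"],
    )
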