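"""Marker selection: recovery of planted markers, rejection, mobile filter."""

from __future__ import annotations

import numpy as np
import pytest

from panmarker import markers as mk
from panmarker import pangenome as pg
from panmarker.io import Contig, GeneRecord, GenomeRecord, TaxonManifest

from oracles import oracle_identity


@pytest.fixture(scope="module")
def selected(small_sim, small_clusters):
    clusters, matrix = small_clusters
    out = {}
    for taxon in small_sim["manifest"].taxa:
        out[taxon] = mk.select_candidates(
            matrix, clusters, small_sim["genes"], small_sim["manifest"], taxon
        )
    return out


def family_of(cluster, clusters):
    by_id = {c.cluster_id: c for c in clusters}
    return {gid.split("|")[1] for gid, _, _ in by_id[cluster].members}


def test_accepted_markers_recover_planted(selected, small_sim, small_clusters):
    clusters, _ = small_clusters
    truth = small_sim["truth"]
    for taxon, cands in selected.items():
        accepted_fams = set()
        for c in cands:
            if c.status == "accepted":
                accepted_fams |= family_of(c.cluster_id, clusters)
        assert set(truth.markers[taxon]) <= accepted_fams
        assert not any(f.startswith("decoy") for f in accepted_fams)


def test_decoys_rejected_cross(selected, small_clusters):
    clusters, _ = small_clusters
    for cands in selected.values():
        decoy_cands = [
            c for c in cands
            if any(f.startswith("decoy") for f in family_of(c.cluster_id, clusters))
        ]
        assert decoy_cands
        for c in decoy_cands:
            assert c.status == "rejected_cross"
            # the decoy's cross-taxon twin sits above the 0.50 threshold
            # (identity 1.0 when the cluster centroid is itself a
            # non-target genome's copy)
            assert c.cross_max_identity > 0.5


def test_accepted_cross_identity_exhaustive(selected, small_sim):
    """Exhaustively re-verify accepted markers against every non-target gene.

    The full scan uses the package aligner with the prefilter and all
    pruning disabled (plain pairwise calls); the slow quadratic Python
    oracle additionally spot-checks the closest-length pairs.
    """
    from panmarker.align import pairwise_identity

    manifest = small_sim["manifest"]
    genes = small_sim["genes"]
    for taxon, cands in selected.items():
        targets = set(manifest.genomes_of(taxon))
        non_target = [g for g in genes if g.genome_id not in targets]
        for c in [c for c in cands if c.status == "accepted"]:
            idents = {g.gene_id: pairwise_identity(c.sequence, g.sequence).identity
                      for g in non_target}
            assert max(idents.values()) <= 0.50
    # oracle spot check: one marker vs its five closest-length rivals
    taxon, cands = sorted(selected.items())[0]
    marker = [c for c in cands if c.status == "accepted"][0]
    targets = set(small_sim["manifest"].genomes_of(taxon))
    rivals = sorted(
        (g for g in genes if g.genome_id not in targets),
        key=lambda g: abs(len(g.sequence) - len(marker.sequence)),
    )[:5]
    for g in rivals:
        assert oracle_identity(marker.sequence, g.sequence) <= 0.50


def test_candidate_ordering(selected):
    for cands in selected.values():
        keys = [(c.cross_max_identity, -c.within_min_identity, c.cluster_id) for c in cands]
        assert keys == sorted(keys)


def test_exhaustive_flag_does_not_change_acceptance(small_sim, small_clusters):
    clusters, matrix = small_clusters
    taxon = small_sim["manifest"].taxa[0]
    fast = mk.select_candidates(matrix, clusters, small_sim["genes"], small_sim["manifest"], taxon)
    full = mk.select_candidates(
        matrix, clusters, small_sim["genes"], small_sim["manifest"], taxon, exhaustive=True
    )
    assert {c.cluster_id: c.status for c in fast} == {c.cluster_id: c.status for c in full}
    # exhaustive cross maxima can only be larger or equal
    fast_by = {c.cluster_id: c for c in fast}
    for c in full:
        assert c.cross_max_identity >= fast_by[c.cluster_id].cross_max_identity - 1e-12


def test_prefilter_neutral_on_fixture(small_sim, small_clusters):
    clusters, matrix = small_clusters
    taxon = small_sim["manifest"].taxa[1]
    on = mk.select_candidates(
        matrix, clusters, small_sim["genes"], small_sim["manifest"], taxon, exhaustive=True
    )
    off = mk.select_candidates(
        matrix, clusters, small_sim["genes"], small_sim["manifest"], taxon,
        exhaustive=True, use_prefilter=False,
    )
    # statuses are prefilter-invariant; sub-threshold cross values may differ
    # because genes sharing no k-mer are recorded as 0 when the prefilter is on
    assert {c.cluster_id: c.status for c in on} == {c.cluster_id: c.status for c in off}
    off_by = {c.cluster_id: c for c in off}
    for c in on:
        assert c.cross_max_identity <= off_by[c.cluster_id].cross_max_identity + 1e-12


def test_threshold_monotonicity(small_sim, small_clusters):
    """Tightening either threshold never grows the accepted set."""
    clusters, matrix = small_clusters
    taxon = small_sim["manifest"].taxa[0]

    def accepted(id_within, id_cross):
        cands = mk.select_candidates(
            matrix, clusters, small_sim["genes"], small_sim["manifest"], taxon,
            id_within=id_within, id_cross=id_cross,
        )
        return {c.cluster_id for c in cands if c.status == "accepted"}

    base = accepted(0.90, 0.50)
    assert accepted(0.95, 0.50) <= base
    assert accepted(0.90, 0.40) <= base
    assert accepted(0.90, 0.0) == set()


def test_single_taxon_vacuous_screen():
    rng = np.random.default_rng(2)
    seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(3)]
    genes = [
        GeneRecord(f"g1|fam{i}", "g1", "c1", 0, 150, "+", s) for i, s in enumerate(seqs)
    ]
    man = TaxonManifest({"g1": "t1"})
    clusters = pg.cluster_genes(genes)
    matrix = pg.build_matrix(clusters, man)
    cands = mk.select_candidates(matrix, clusters, genes, man, "t1")
    assert all(c.status == "accepted" for c in cands)
    assert all(c.cross_max_identity == 0.0 for c in cands)


def _plasmid_setup():
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list("ACGT"), 200))
    gene = GeneRecord("g1|m1", "g1", "p1", 0, 200, "+", seq)
    genome = GenomeRecord("g1", [Contig("c1", "A" * 50, "chromosome"), Contig("p1", seq, "plasmid")])
    cluster = pg.GeneCluster("PC1", "g1|m1", seq, members=[("g1|m1", "g1", 1.0)])
    man = TaxonManifest({"g1": "t1"})
    cand = mk.MarkerCandidate("t1", "PC1", "g1|m1", seq, 1.0, 0.0, status="accepted")
    return cand, genome, [gene], [cluster], man, seq


def test_plasmid_marker_rejected_mobile():
    cand, genome, genes, clusters, man, _ = _plasmid_setup()
    out = mk.mobile_element_filter([cand], [genome], genes, clusters, man)
    assert out[0].status == "rejected_mobile"
    assert out[0].replicon == "plasmid"


def test_exclusion_fasta_rejects_self(tmp_path):
    cand, genome, genes, clusters, man, seq = _plasmid_setup()
    # move the gene to the chromosome so only the exclusion set can reject it
    genome = GenomeRecord("g1", [Contig("c1", seq, "chromosome")])
    genes = [GeneRecord("g1|m1", "g1", "c1", 0, 200, "+", seq)]
    excl = tmp_path / "mobile.fasta"
    excl.write_text(f">phage1\n{seq}\n")
    out = mk.mobile_element_filter([cand], [genome], genes, clusters, man, exclusion_fasta=excl)
    assert out[0].status == "rejected_mobile"
    # chromosome gene with empty exclusion set stays accepted
    out2 = mk.mobile_element_filter([cand], [genome], genes, clusters, man)
    assert out2[0].status == "accepted"
    assert out2[0].replicon == "chromosome"


def test_missing_exclusion_fasta_errors():
    cand, genome, genes, clusters, man, _ = _plasmid_setup()
    with pytest.raises(FileNotFoundError):
        mk.mobile_element_filter([cand], [genome], genes, clusters, man,
                                 exclusion_fasta="/nonexistent.fasta")


def test_verify_markers_matrix(selected, small_sim):
    manifest = small_sim["manifest"]
    accepted = [c for cands in selected.values() for c in cands if c.status == "accepted"]
    table = mk.verify_markers(accepted, small_sim["genes"],
                              genome_ids=sorted(manifest.assignments))
    assert ((table.values >= 0) & (table.values <= 1)).all()
    for c in accepted:
        row = table.loc[f"{c.taxon}:{c.cluster_id}"]
        for gid in manifest.genomes_of(c.taxon):
            assert row[gid] >= 0.90
        for gid, taxon in manifest.assignments.items():
            if taxon != c.taxon:
                assert row[gid] <= 0.50


def test_verify_markers_empty_genome_row_zero(selected, small_sim):
    accepted = [c for cands in selected.values() for c in cands if c.status == "accepted"]
    table = mk.verify_markers(accepted[:1], small_sim["genes"],
                              genome_ids=["nothing_here"])
    assert (table["nothing_here"] == 0).all()


def test_verify_markers_requires_markers(small_sim):
    with pytest.raises(ValueError):
        mk.verify_markers([], small_sim["genes"])
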