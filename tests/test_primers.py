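"""Melting temperatures, primer design constraints, in-silico PCR."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from panmarker import primers as pr
from panmarker.io import Contig, GenomeRecord, TaxonManifest
from panmarker.reference import load_primer_pairs

from oracles import oracle_amplicons


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestMeltingTemperature:
    def test_wallace_rule(self):
        assert pr.melting_temperature("ACGT", method="wallace") == 12.0
        assert pr.melting_temperature("GGGG", method="wallace") == 16.0

    def test_nn_against_independent_oracle(self):
        """Unified nearest-neighbor Tm vs Biopython's implementation.

        Same thermodynamic model (unified NN table, 0.368*(N-1)*ln[Na+]
        entropy salt correction, C_T/4 with 0.5 uM total primer), coded
        independently.
        """
        pairs = load_primer_pairs()
        oligos = [p.forward for p in pairs] + [p.reverse for p in pairs]
        for oligo in oligos:
            mine = pr.melting_temperature(oligo)
            ref = mt.Tm_NN(oligo, nn_table=mt.DNA_NN3, dnac1=250, dnac2=250,
                           Na=50, saltcorr=5)
            assert mine == pytest.approx(ref, abs=0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            pr.melting_temperature("ACG")  # too short
        with pytest.raises(ValueError):
            pr.melting_temperature("ACGTN" * 4)
        with pytest.raises(ValueError):
            pr.melting_temperature("ACGT" * 5, method="bogus")

    def test_tm_strand_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            oligo = rand_seq(rng, 20)
            assert pr.melting_temperature(oligo) == pytest.approx(
                pr.melting_temperature(pr.revcomp(oligo)), abs=1e-9
            )


class TestDesign:
    def test_marker_too_short_rejected(self):
        with pytest.raises(ValueError):
            pr.design_primers("ACGT" * 10)  # 40 nt < min amplicon

    def test_designed_pairs_satisfy_all_constraints(self):
        rng = np.random.default_rng(17)
        marker = rand_seq(rng, 400)
        c = pr.PrimerConstraints()
        pairs = pr.design_primers(marker, c, top_n=5)
        assert pairs
        for p in pairs:
            for oligo, tm in ((p.forward, p.tm_forward), (p.reverse, p.tm_reverse)):
                assert c.min_len <= len(oligo) <= c.max_len
                assert c.gc_range[0] <= pr.gc_fraction(oligo) <= c.gc_range[1]
                assert c.tm_range[0] <= tm <= c.tm_range[1]
                assert tm == pytest.approx(pr.melting_temperature(oligo))
            assert c.min_amplicon <= p.product_size <= c.max_amplicon
            assert p.dimer_score <= c.max_dimer_score
            assert p.hairpin_score <= c.max_hairpin_score
            # geometry: the pair reproduces its own product on the marker
            assert marker[p.forward_start: p.forward_start + len(p.forward)] == p.forward
            amplicon = marker[p.forward_start: p.reverse_end]
            assert len(amplicon) == p.product_size
            assert amplicon.endswith(pr.revcomp(p.reverse))

    def test_ranking_prefers_matched_tm_near_60(self):
        rng = np.random.default_rng(18)
        marker = rand_seq(rng, 400)
        pairs = pr.design_primers(marker, top_n=5)
        keys = [
            (abs(p.tm_forward - p.tm_reverse),
             abs((p.tm_forward + p.tm_reverse) / 2 - 60.0),
             p.product_size)
            for p in pairs
        ]
        assert keys == sorted(keys)

    def test_published_pairs_fit_the_design_envelope(self):
        """The published assay's oligos and products match the constraints."""
        pairs = load_primer_pairs()
        assert len(pairs) == 22
        for p in pairs:
            assert 18 <= len(p.forward) <= 22
            assert 18 <= len(p.reverse) <= 22
            assert 0 < p.product_size <= 200

    def test_no_valid_pair_returns_empty(self):
        assert pr.design_primers("AT" * 60) == []  # GC 0.5 but Tm/homopolymer fail


class TestInSilicoPCR:
    def _pair(self, fwd, rev):
        return pr.PrimerPair("p", "t", fwd, rev, 0, 60, 60, 0.5, 0.5)

    def test_constructed_template_exact_hit(self):
        rng = np.random.default_rng(4)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        template = fwd + rand_seq(rng, 70) + pr.revcomp(rev)
        genome = GenomeRecord("g", [Contig("c", template)])
        hits = pr.in_silico_pcr(self._pair(fwd, rev), [genome])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.product_size) == (0, 110, "+", 110)
        assert h.forward_mismatches == h.reverse_mismatches == 0

    def test_three_mismatches_kill_binding(self):
        rng = np.random.default_rng(5)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        damaged = list(fwd)
        for i in (3, 8, 12):  # internal positions, 3 substitutions
            damaged[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[damaged[i]]
        template = "".join(damaged) + rand_seq(rng, 70) + pr.revcomp(rev)
        genome = GenomeRecord("g", [Contig("c", template)])
        assert pr.in_silico_pcr(self._pair(fwd, rev), [genome], max_mismatch=2) == []

    def test_three_prime_mismatch_kills_binding(self):
        rng = np.random.default_rng(6)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        damaged = list(fwd)
        damaged[-1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[damaged[-1]]
        template = "".join(damaged) + rand_seq(rng, 70) + pr.revcomp(rev)
        genome = GenomeRecord("g", [Contig("c", template)])
        assert pr.in_silico_pcr(self._pair(fwd, rev), [genome]) == []

    def test_strand_invariance(self, small_sim):
        rng = np.random.default_rng(7)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        template = rand_seq(rng, 150) + fwd + rand_seq(rng, 80) + pr.revcomp(rev) + rand_seq(rng, 150)
        g1 = GenomeRecord("g", [Contig("c", template)])
        g2 = GenomeRecord("g", [Contig("c", pr.revcomp(template))])
        h1 = pr.in_silico_pcr(self._pair(fwd, rev), [g1])
        h2 = pr.in_silico_pcr(self._pair(fwd, rev), [g2])
        assert len(h1) == len(h2) == 1
        assert h1[0].product_size == h2[0].product_size
        assert h1[0].strand != h2[0].strand
        # coordinates remap through the contig length
        n = len(template)
        assert (h2[0].start, h2[0].end) == (n - h1[0].end, n - h1[0].start)

    def test_matches_naive_scan_oracle(self):
        """Site finding equals an all-positions oracle on random templates."""
        for seed in range(6):
            rng = np.random.default_rng(seed)
            fwd, rev = rand_seq(rng, 18), rand_seq(rng, 18)
            # template seeded with perturbed copies of both oligos
            parts = [rand_seq(rng, 40)]
            for oligo in (fwd, rev, pr.revcomp(fwd), pr.revcomp(rev)):
                mutated = list(oligo)
                for p in rng.choice(len(oligo), size=int(rng.integers(0, 3)), replace=False):
                    mutated[p] = "ACGT"[int(rng.integers(0, 4))]
                parts += ["".join(mutated), rand_seq(rng, int(rng.integers(20, 60)))]
            template = "".join(parts)
            genome = GenomeRecord("g", [Contig("c", template)])
            hits = pr.in_silico_pcr(self._pair(fwd, rev), [genome])
            got = sorted((h.start, h.end, h.strand) for h in hits)
            assert got == oracle_amplicons(template, fwd, rev)


def test_specificity_matrix_genus_core_control(tmp_path):
    """A pair targeting a gene shared by all genomes amplifies every taxon."""
    from panmarker.simulate import SimulationSpec, simulate_pangenome
    from panmarker import io as gio

    spec = SimulationSpec(
        n_taxa=2, genomes_per_taxon=2, n_genus_core=2, n_taxon_markers=1,
        n_accessory=0, n_decoy=0, within_taxon_sub_rate=0.0,
        cross_taxon_divergence=0.0, plasmid_fraction=0.0,
        gene_length_range=(250, 400), seed=3,
    )
    genome_paths, gene_paths, manifest_path, truth = simulate_pangenome(spec, tmp_path)
    genomes, manifest = gio.read_genomes(genome_paths, manifest_path)
    genes = gio.read_gene_sets(gene_paths)
    core_gene = next(g for g in genes if "core001" in g.gene_id)
    pairs = pr.design_primers(core_gene.sequence, top_n=1, taxon="taxon01")
    assert pairs
    matrix, summary = pr.specificity_matrix(pairs, genomes, manifest)
    assert (matrix.loc[pairs[0].name] > 0).all()  # amplifies everything
    row = summary.iloc[0]
    assert row.sensitivity == 1.0 and row.specificity == 0.0


def test_specificity_matrix_requires_pairs(small_sim):
    with pytest.raises(ValueError):
        pr.specificity_matrix([], small_sim["genomes"], small_sim["manifest"])
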