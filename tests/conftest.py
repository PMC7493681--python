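from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from panmarker import io as gio
from panmarker.simulate import SimulationSpec, simulate_pangenome

SMALL_SPEC = SimulationSpec(
    n_taxa=3,
    genomes_per_taxon=3,
    n_genus_core=4,
    n_taxon_markers=2,
    n_accessory=3,
    n_decoy=2,
    within_taxon_sub_rate=0.01,
    cross_taxon_divergence=0.45,
    plasmid_fraction=0.3,
    gene_length_range=(200, 500),
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact simulated pan-genome reused by most unit tests."""
    out = tmp_path_factory.mktemp("small_sim")
    genome_paths, gene_paths, manifest_path, truth = simulate_pangenome(SMALL_SPEC, out)
    genomes, manifest = gio.read_genomes(genome_paths, manifest_path)
    genes = gio.read_gene_sets(gene_paths)
    return {
        "dir": out,
        "spec": SMALL_SPEC,
        "genome_paths": genome_paths,
        "gene_paths": gene_paths,
        "manifest_path": manifest_path,
        "truth": truth,
        "genomes": genomes,
        "manifest": manifest,
        "genes": genes,
    }


@pytest.fixture(scope="session")
def small_clusters(small_sim):
    from panmarker import pangenome as pg

    clusters = pg.cluster_genes(small_sim["genes"])
    matrix = pg.build_matrix(clusters, small_sim["manifest"])
    return clusters, matrix
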