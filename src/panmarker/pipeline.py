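"""End-to-end orchestration: simulate -> cluster -> trees -> markers ->
primers -> in-silico PCR, and the monitoring report.

``run_discover`` is a pure function of its config and inputs: stage
outputs land in the run directory as tab-separated tables / FASTA /
newick, together with a verbatim copy of the config, so a finished run
can be reproduced from its own directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from . import markers as mk
from . import pangenome as pg
from . import phylogeny as phy
from . import primers as pr
from . import qpcr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discover", "run_monitor"]


@dataclass
class RunConfig:
    genomes_dir: str = ""
    genes_dir: str = ""
    manifest: str = ""
    out_dir: str = "run"
    cluster_id: float = pg.DEFAULT_THRESHOLD
    prefilter_k: int = pg.DEFAULT_K
    id_within: float = mk.ID_WITHIN
    id_cross: float = mk.ID_CROSS
    presence_fraction: float = 1.0
    exclusion_fasta: str = ""
    max_amplicon: int = 200
    min_amplicon: int = 80
    ispcr_max_mismatch: int = 2
    ispcr_three_prime_exact: int = 2
    ct_cutoff: float = qpcr.CT_CUTOFF
    tree_metric: str = "jaccard"
    seed: int = 0

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in open(path):
            if "=" not in line:
                continue
            key, val = line.strip().split("=", 1)
            if key not in types:
                continue
            t = types[key]
            kwargs[key] = float(val) if t == "float" else int(val) if t == "int" else val
        return cls(**kwargs)


def run_discover(config: RunConfig) -> Path:
    """Run the full marker-discovery pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write(out / "config.txt")
    log_lines: list[str] = []

    def stage(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    genome_paths = sorted(Path(config.genomes_dir).glob("*.fna")) + sorted(
        Path(config.genomes_dir).glob("*.fasta")
    )
    genomes, manifest = gio.read_genomes(genome_paths, config.manifest)
    gene_paths = sorted(Path(config.genes_dir).glob("*.ffn")) + sorted(
        Path(config.genes_dir).glob("*.fasta")
    )
    genes = gio.read_gene_sets(gene_paths)
    stage(f"ingest: {len(genomes)} genomes, {len(genes)} genes, {len(manifest.taxa)} taxa")

    clusters = pg.cluster_genes(genes, threshold=config.cluster_id, prefilter_k=config.prefilter_k)
    matrix = pg.build_matrix(clusters, manifest)
    gio.write_matrix(matrix, out / "matrix.tsv")
    pg.cluster_table(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
    core, accessory, unique = pg.partition(matrix)
    stage(
        f"cluster: {len(clusters)} clusters (core {len(core)}, accessory "
        f"{len(accessory)}, unique {len(unique)})"
    )

    pan_tree = phy.neighbor_joining(phy.frequency_distance(matrix, config.tree_metric))
    gio.write_newick(pan_tree, out / "pan_tree.nwk")
    core_tree = phy.neighbor_joining(phy.core_identity_distance(genes, clusters, core))
    gio.write_newick(core_tree, out / "core_tree.nwk")
    mono = phy.monophyly_report(pan_tree, manifest)
    mono.to_csv(out / "monophyly.tsv", sep="\t", index=False)
    stage(f"tree: monophyletic {int(mono['monophyletic'].sum())}/{len(mono)} taxa")

    all_candidates: list[mk.MarkerCandidate] = []
    for taxon in manifest.target_taxa:
        cands = mk.select_candidates(
            matrix, clusters, genes, manifest, taxon,
            id_within=config.id_within, id_cross=config.id_cross,
            presence_fraction=config.presence_fraction,
        )
        cands = mk.mobile_element_filter(
            cands, genomes, genes, clusters, manifest,
            exclusion_fasta=config.exclusion_fasta or None,
        )
        all_candidates.extend(cands)
    accepted = [c for c in all_candidates if c.status == "accepted"]
    mk.candidate_table(all_candidates).to_csv(out / "markers.tsv", sep="\t", index=False)
    with open(out / "markers.fasta", "w") as fh:
        for c in accepted:
            fh.write(f">{c.taxon}|{c.cluster_id} {c.representative}\n{c.sequence}\n")
    stage(f"markers: {len(accepted)} accepted of {len(all_candidates)} candidates")

    if accepted:
        verification = mk.verify_markers(
            accepted, genes, genome_ids=sorted(manifest.assignments)
        )
        verification.to_csv(out / "verification.tsv", sep="\t", index_label="marker")

    constraints = pr.PrimerConstraints(
        min_amplicon=config.min_amplicon, max_amplicon=config.max_amplicon
    )
    cluster_by_id = {c.cluster_id: c for c in clusters}
    pairs: list[pr.PrimerPair] = []
    for taxon in manifest.target_taxa:
        targets = set(manifest.genomes_of(taxon))
        chosen = None
        fallback = None
        for cand in (c for c in accepted if c.taxon == taxon):
            # design on the target-taxon consensus, not one genome's copy:
            # a member's private substitutions would otherwise sit under
            # the primers in every other genome of the taxon
            template = mk.cluster_consensus(
                cluster_by_id[cand.cluster_id], genes, restrict_genomes=targets
            )
            designed = pr.design_primers(
                template, constraints, top_n=10, taxon=taxon,
                name_prefix=f"{taxon}_{cand.cluster_id}",
            )
            if designed and fallback is None:
                fallback = designed[0]
            # keep the first pair that the in-silico screen fully validates
            for pair in designed:
                amplified = {
                    h.genome_id
                    for h in pr.in_silico_pcr(
                        pair, genomes, config.ispcr_max_mismatch,
                        config.ispcr_three_prime_exact,
                    )
                }
                if targets <= amplified and not (amplified - targets):
                    chosen = pair
                    break
            if chosen:
                break
        if chosen is None and fallback is not None:
            logger.warning(
                "no fully validated primer pair for %s; keeping best-ranked", taxon
            )
            chosen = fallback
        if chosen is None:
            logger.warning("no primer pair designed for taxon %s", taxon)
        else:
            pairs.append(chosen)
    pd.DataFrame(
        [
            (p.name, p.taxon, p.forward, p.reverse, p.product_size,
             round(p.tm_forward, 2), round(p.tm_reverse, 2),
             round(p.gc_forward, 3), round(p.gc_reverse, 3),
             p.dimer_score, p.hairpin_score)
            for p in pairs
        ],
        columns=["name", "taxon", "forward", "reverse", "product_size",
                 "tm_forward", "tm_reverse", "gc_forward", "gc_reverse",
                 "dimer_score", "hairpin_score"],
    ).to_csv(out / "primers.tsv", sep="\t", index=False)
    stage(f"primers: {len(pairs)} pairs designed")

    if pairs:
        hits = [
            (p.name, h.genome_id, h.contig_id, h.start, h.end, h.strand,
             h.forward_mismatches, h.reverse_mismatches, h.product_size)
            for p in pairs
            for h in pr.in_silico_pcr(
                p, genomes, config.ispcr_max_mismatch,
                config.ispcr_three_prime_exact,
            )
        ]
        pd.DataFrame(
            hits,
            columns=["pair", "genome_id", "contig_id", "start", "end", "strand",
                     "forward_mismatches", "reverse_mismatches", "product_size"],
        ).to_csv(out / "ispcr_hits.tsv", sep="\t", index=False)
        spec_mat, summary = pr.specificity_matrix(
            pairs, genomes, manifest, config.ispcr_max_mismatch,
            config.ispcr_three_prime_exact,
        )
        spec_mat.to_csv(out / "specificity_matrix.tsv", sep="\t", index_label="pair")
        summary.to_csv(out / "specificity.tsv", sep="\t", index=False)
        stage(
            "ispcr: mean sensitivity "
            f"{summary['sensitivity'].mean():.3f}, mean specificity "
            f"{summary['specificity'].mean():.3f}"
        )
    else:
        pd.DataFrame(columns=["pair", "taxon", "sensitivity", "specificity"]).to_csv(
            out / "specificity.tsv", sep="\t", index=False
        )

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def run_monitor(
    calls: pd.DataFrame,
    labels: pd.DataFrame,
    curves: dict[str, qpcr.StandardCurve],
    taxonomy: qpcr.Taxonomy,
    out_dir: str | Path,
    ct_cutoff: float = qpcr.CT_CUTOFF,
) -> Path:
    """Label-claim report + quantification for monitored products.

    ``calls`` columns: product_id, taxon, ct (blank = no amplification);
    ``labels`` columns: product_id, labeled (taxa joined by ``|``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    quant_rows = []
    detected: dict[str, list[str]] = {}
    for _, row in calls.iterrows():
        ct = row.get("ct")
        ct = None if pd.isna(ct) else float(ct)
        call = qpcr.DetectionCall(str(row["product_id"]), str(row["taxon"]), ct)
        if not call.positive or call.ct is None or call.ct > ct_cutoff:
            continue
        if call.taxon not in curves:
            raise ValueError(f"no standard curve for detected taxon {call.taxon!r}")
        log_cfu, extrapolated = qpcr.quantify(call.ct, curves[call.taxon])
        detected.setdefault(call.product_id, []).append(call.taxon)
        quant_rows.append(
            (call.product_id, call.taxon, call.ct, round(log_cfu, 3), extrapolated)
        )
    report_rows = []
    for _, row in labels.iterrows():
        pid = str(row["product_id"])
        labeled = [t.strip() for t in str(row["labeled"]).split("|") if t.strip()]
        cmp = qpcr.compare_to_label(pid, labeled, detected.get(pid, []), taxonomy)
        report_rows.append(
            (pid, " | ".join(cmp.labeled), " | ".join(cmp.detected), cmp.verdict, cmp.detail)
        )
    pd.DataFrame(
        quant_rows, columns=["product_id", "taxon", "ct", "log10_cfu_per_ml", "extrapolated"]
    ).to_csv(out / "quantification.tsv", sep="\t", index=False)
    pd.DataFrame(
        report_rows, columns=["product_id", "labeled", "detected", "verdict", "detail"]
    ).to_csv(out / "label_report.tsv", sep="\t", index=False)
    return out
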