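"""Distance matrices, neighbor-joining trees and monophyly checks.

Two distances are offered, matching the two trees the pipeline draws:

* ``frequency_distance`` — computed from the presence/absence matrix,
  either Jaccard distance on binary cluster presence (default) or
  Euclidean distance on per-genome cluster count vectors normalised by
  the total number of clusters.
* ``core_identity_distance`` — ``1 - mean pairwise identity`` over core
  clusters in which both genomes are single-copy.  This stands in for a
  concatenated core-gene alignment: only the tree topology (do taxa form
  clades?) is consumed downstream, and mean per-gene identity preserves
  exactly that signal without a multiple-alignment dependency.

``neighbor_joining`` is the classic Saitou-Nei agglomeration with the
Q-criterion, exact on additive matrices.  Ties in Q are broken by the
lexicographically smallest pair of node labels (a node is labelled by
the smallest leaf beneath it), making the topology deterministic.
Negative branch-length estimates are clamped to zero and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .align import pairwise_identity
from .io import GeneRecord, TaxonManifest
from .pangenome import GeneCluster

__all__ = [
    "frequency_distance",
    "core_identity_distance",
    "neighbor_joining",
    "monophyly_report",
]

logger = logging.getLogger(__name__)


def frequency_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Genome-genome distances from pan-genome cluster frequencies."""
    if matrix.shape[1] < 3:
        raise ValueError("frequency_distance needs >= 3 genomes")
    empty = matrix.columns[(matrix > 0).sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"genomes with zero clusters: {list(empty)}")
    if metric == "jaccard":
        binary = (matrix.values > 0).astype(bool).T
        d = pdist(binary, metric="jaccard")
    elif metric == "euclidean":
        freq = matrix.values.T / matrix.values.sum()
        d = pdist(freq, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=matrix.columns, columns=matrix.columns)


def core_identity_distance(
    genes: list[GeneRecord],
    clusters: list[GeneCluster],
    core_ids: set[str],
) -> pd.DataFrame:
    """1 - mean single-copy core-gene identity for every genome pair."""
    seq_of = {g.gene_id: g.sequence for g in genes}
    genomes = sorted({g.genome_id for g in genes})
    idx = {g: i for i, g in enumerate(genomes)}
    total = np.zeros((len(genomes), len(genomes)))
    count = np.zeros((len(genomes), len(genomes)), dtype=int)
    for c in clusters:
        if c.cluster_id not in core_ids:
            continue
        per_genome: dict[str, list[str]] = {}
        for gid, genome, _ in c.members:
            per_genome.setdefault(genome, []).append(gid)
        single = {g: ids[0] for g, ids in per_genome.items() if len(ids) == 1}
        gs = sorted(single)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                ident = pairwise_identity(seq_of[single[gs[i]]], seq_of[single[gs[j]]]).identity
                a, b = idx[gs[i]], idx[gs[j]]
                total[a, b] += ident
                total[b, a] += ident
                count[a, b] += 1
                count[b, a] += 1
    d = np.zeros_like(total)
    for a in range(len(genomes)):
        for b in range(a + 1, len(genomes)):
            if count[a, b] == 0:
                raise ValueError(
                    f"no shared single-copy core cluster for {genomes[a]} / {genomes[b]}"
                )
            d[a, b] = d[b, a] = 1.0 - total[a, b] / count[a, b]
    return pd.DataFrame(d, index=genomes, columns=genomes)


class _Node:
    __slots__ = ("newick", "key")

    def __init__(self, newick: str, key: str):
        self.newick = newick
        self.key = key  # smallest leaf label beneath, for tie-breaks


def _fmt(x: float) -> str:
    return f"{max(x, 0.0):.10g}"


def neighbor_joining(d: pd.DataFrame) -> TreeNode:
    """Classic NJ tree from a symmetric distance matrix (>= 3 leaves)."""
    if d.shape[0] != d.shape[1] or not np.allclose(d.values, d.values.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] < 3:
        raise ValueError("neighbor_joining needs >= 3 leaves")
    labels = list(d.index)
    nodes = [_Node(str(l), str(l)) for l in labels]
    dm = d.values.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = dm.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * dm[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i].key, nodes[j].key)))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        vi = 0.5 * dm[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = dm[i, j] - vi
        vi, vj = clamp(vi), clamp(vj)
        merged = _Node(
            f"({nodes[i].newick}:{_fmt(vi)},{nodes[j].newick}:{_fmt(vj)})",
            min(nodes[i].key, nodes[j].key),
        )
        dnew = 0.5 * (dm[i] + dm[j] - dm[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        dm2 = np.zeros((len(keep) + 1, len(keep) + 1))
        dm2[:-1, :-1] = dm[np.ix_(keep, keep)]
        dm2[-1, :-1] = dm2[:-1, -1] = dnew[keep]
        dm = dm2
        nodes = [nodes[k] for k in keep] + [merged]

    # closed-form star resolution of the last three nodes
    a, b, c = range(3)
    va = clamp(0.5 * (dm[a, b] + dm[a, c] - dm[b, c]))
    vb = clamp(0.5 * (dm[a, b] + dm[b, c] - dm[a, c]))
    vc = clamp(0.5 * (dm[a, c] + dm[b, c] - dm[a, b]))
    newick = (
        f"({nodes[a].newick}:{_fmt(va)},{nodes[b].newick}:{_fmt(vb)},"
        f"{nodes[c].newick}:{_fmt(vc)});"
    )
    if clamped:
        logger.warning("neighbor_joining clamped %d negative branch lengths to 0", clamped)
    return TreeNode.read([newick], convert_underscores=False)


def monophyly_report(tree: TreeNode, manifest: TaxonManifest) -> pd.DataFrame:
    """Per-taxon monophyly: does some bipartition isolate exactly its leaves?

    Returns a table with columns taxon, monophyletic, offending_leaves;
    offenders are the extra leaves inside the smallest clade containing
    the taxon.  Single-leaf taxa are trivially monophyletic.
    """
    leaves = {n.name for n in tree.tips()}
    unknown = leaves - set(manifest.assignments)
    if unknown:
        raise ValueError(f"tree leaves not in manifest: {sorted(unknown)}")
    clades: list[frozenset[str]] = []
    for node in tree.non_tips(include_self=True):
        clades.append(frozenset(t.name for t in node.tips()))
    rows = []
    for taxon in manifest.taxa:
        mine = frozenset(g for g in manifest.genomes_of(taxon) if g in leaves)
        if not mine:
            continue
        complement = frozenset(leaves) - mine
        mono = (
            len(mine) == 1
            or any(c == mine or c == complement for c in clades)
        )
        offenders: list[str] = []
        if not mono:
            containing = [c for c in clades if mine <= c]
            smallest = min(containing, key=len) if containing else frozenset(leaves)
            offenders = sorted(smallest - mine)
        rows.append((taxon, mono, ",".join(offenders)))
    return pd.DataFrame(rows, columns=["taxon", "monophyletic", "offending_leaves"])
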