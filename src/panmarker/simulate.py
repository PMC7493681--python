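"""Synthetic labeled pan-genomes with planted taxon-specific markers.

The generator emulates the statistical structure that taxon-specific
marker discovery relies on: every genome carries a genus-wide core gene
set, each taxon additionally carries private marker genes found nowhere
else, "decoy" gene families sit at intermediate cross-taxon identity
(inside ``decoy_identity_band``, i.e. between the cross-specificity
threshold of 0.50 and the within-taxon band of 0.90+), and accessory
genes are scattered over random genome subsets.  Gene sequences within a
taxon differ by per-site substitutions at ``within_taxon_sub_rate``;
taxon ancestors of shared families differ at ``cross_taxon_divergence``.

Because the identity statistic of unrelated equal-length sequences sits
near 0.5 under the toolkit's alignment scoring, freshly drawn marker
sequences occasionally violate the planted-marker contract
(cross-identity <= 0.50 against every non-target family).  The generator
enforces the contract empirically: each marker is aligned against all
other family ancestors and redrawn until it clears the threshold with a
safety margin; the number of redraws is reported on the truth table.

All randomness flows from one ``numpy.random.default_rng(seed)`` in a
fixed documented order, so identical specs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import pairwise_identity

__all__ = ["SimulationSpec", "TruthTable", "simulate_pangenome"]

_BASES = np.array(list("ACGT"))

# Contract-enforcement constants (see module docstring): markers are redrawn
# until their ancestor-level identity against every non-target family is at
# most id_cross - margin, leaving headroom for within-taxon drift.
_MARKER_ID_CROSS = 0.50
_MARKER_MARGIN = 0.04
_MAX_REDRAWS = 300


class SpecError(ValueError):
    """A SimulationSpec field is out of its legal range."""


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic pan-genome.

    Counts are per the glossary: ``n_genus_core`` families occur in every
    genome, ``n_taxon_markers`` private families per taxon, ``n_accessory``
    families on random genome subsets, ``n_decoy`` families in all genomes
    at intermediate cross-taxon identity.  Rates are per-site substitution
    probabilities.
    """

    n_taxa: int = 3
    genomes_per_taxon: int = 3
    n_genus_core: int = 8
    n_taxon_markers: int = 3
    n_accessory: int = 6
    n_decoy: int = 4
    within_taxon_sub_rate: float = 0.01
    cross_taxon_divergence: float = 0.45
    decoy_identity_band: tuple[float, float] = (0.65, 0.85)
    plasmid_fraction: float = 0.25
    gene_length_range: tuple[int, int] = (300, 1500)
    indel_rate: float = 0.0  # off by default: keeps identity bands analytic
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_taxa", "genomes_per_taxon", "n_genus_core", "n_taxon_markers"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be >= 1")
        for name in ("n_accessory", "n_decoy"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if not 0.0 <= self.within_taxon_sub_rate <= 0.1:
            raise SpecError("within_taxon_sub_rate must be in [0, 0.1]")
        if not (self.cross_taxon_divergence == 0.0 or 0.2 <= self.cross_taxon_divergence <= 0.6):
            raise SpecError("cross_taxon_divergence must be 0 or in [0.2, 0.6]")
        lo, hi = self.decoy_identity_band
        if not 0.5 < lo < hi < 1.0:
            raise SpecError("decoy_identity_band must satisfy 0.5 < lo < hi < 1.0")
        if not 0.0 <= self.plasmid_fraction <= 1.0:
            raise SpecError("plasmid_fraction must be in [0, 1]")
        glo, ghi = self.gene_length_range
        if not 50 <= glo <= ghi:
            raise SpecError("gene_length_range must satisfy 50 <= lo <= hi")
        if not 0.0 <= self.indel_rate <= 0.02:
            raise SpecError("indel_rate must be in [0, 0.02]")


@dataclass
class GenePlacement:
    gene_id: str
    genome_id: str
    contig_id: str
    replicon: str
    start: int
    end: int
    strand: str
    family_id: str


@dataclass
class TruthTable:
    """Ground truth of a simulated set: planted markers and gene placements."""

    markers: dict[str, list[str]]  # taxon -> planted marker family ids
    placements: list[GenePlacement] = field(default_factory=list)
    marker_redraws: int = 0

    def genes_of(self, genome_id: str) -> list[GenePlacement]:
        return [p for p in self.placements if p.genome_id == genome_id]

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#marker_redraws={self.marker_redraws}\n")
            for taxon in sorted(self.markers):
                fh.write(f"M\t{taxon}\t{','.join(self.markers[taxon])}\n")
            for p in self.placements:
                fh.write(
                    f"G\t{p.gene_id}\t{p.genome_id}\t{p.contig_id}\t{p.replicon}"
                    f"\t{p.start}\t{p.end}\t{p.strand}\t{p.family_id}\n"
                )

    @classmethod
    def read(cls, path: Path) -> "TruthTable":
        markers: dict[str, list[str]] = {}
        placements: list[GenePlacement] = []
        redraws = 0
        for line in open(path):
            if line.startswith("#"):
                redraws = int(line.strip().split("=")[1])
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "M":
                markers[parts[1]] = parts[2].split(",") if parts[2] else []
            else:
                placements.append(
                    GenePlacement(parts[1], parts[2], parts[3], parts[4],
                                  int(parts[5]), int(parts[6]), parts[7], parts[8])
                )
        return cls(markers=markers, placements=placements, marker_redraws=redraws)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    if rate <= 0.0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(seq.shape[0]) < rate
    # shift by 1..3 mod 4 guarantees a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


_COMP = np.array([3, 2, 1, 0], dtype=np.int8)
_COMP_STR = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return _COMP[seq[::-1]]


def _revcomp_str(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def _calibrate_decoy(
    rng: np.random.Generator, root: np.ndarray, n_taxa: int, band: tuple[float, float]
) -> list[np.ndarray]:
    """Mutate per-taxon decoy variants until pairwise identities sit in band."""
    lo, hi = band
    target = (lo + hi) / 2.0
    rate = (1.0 - target) / 2.0  # pairwise divergence approx 2 * branch rate
    best: list[np.ndarray] | None = None
    best_gap = np.inf
    for _ in range(10):
        variants = [_mutate(rng, root, rate) for _ in range(n_taxa)]
        if n_taxa == 1:
            return variants
        idents = [
            pairwise_identity(_to_str(variants[i]), _to_str(variants[j])).identity
            for i in range(n_taxa)
            for j in range(i + 1, n_taxa)
        ]
        mean = float(np.mean(idents))
        gap = abs(mean - target)
        if min(idents) >= lo and max(idents) <= hi:
            return variants
        if gap < best_gap:
            best, best_gap = variants, gap
        rate *= mean / target  # more identity than wanted -> mutate harder
        rate = float(np.clip(rate, 0.005, 0.45))
    assert best is not None
    return best


def _spaced(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i: i + width] for i in range(0, len(seq), width))


def simulate_pangenome(spec: SimulationSpec, out_dir: str | Path):
    """Generate genome FASTAs, per-genome CDS FASTAs, a manifest and truth.

    Returns ``(genome_paths, gene_paths, manifest_path, TruthTable)``.
    Layout under ``out_dir``: ``genomes/<genome>.fna``, ``genes/<genome>.ffn``,
    ``manifest.tsv``, ``truth.tsv`` and a JSON copy of the spec.
    """
    out_dir = Path(out_dir)
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    (out_dir / "genes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    taxa = [f"taxon{t + 1:02d}" for t in range(spec.n_taxa)]
    genomes = {t: [f"{t}_g{g + 1:02d}" for g in range(spec.genomes_per_taxon)] for t in taxa}
    all_genomes = [g for t in taxa for g in genomes[t]]
    glo, ghi = spec.gene_length_range

    def draw_len() -> int:
        return int(rng.integers(glo, ghi + 1))

    # --- 1. genus-core families: one root, one ancestor per taxon -----------
    core: dict[str, dict[str, np.ndarray]] = {}
    for i in range(spec.n_genus_core):
        fid = f"core{i + 1:03d}"
        root = _random_seq(rng, draw_len())
        core[fid] = {t: _mutate(rng, root, spec.cross_taxon_divergence / 2.0) for t in taxa}

    # --- 2. accessory families: one root + random genome subset -------------
    accessory: dict[str, tuple[np.ndarray, list[str]]] = {}
    for i in range(spec.n_accessory):
        fid = f"acc{i + 1:03d}"
        root = _random_seq(rng, draw_len())
        subset = [g for g in all_genomes if rng.random() < 0.5]
        if not subset:
            subset = [all_genomes[int(rng.integers(0, len(all_genomes)))]]
        accessory[fid] = (root, subset)

    # --- 3. decoy families: calibrated per-taxon variants, all genomes ------
    decoys: dict[str, dict[str, np.ndarray]] = {}
    for i in range(spec.n_decoy):
        fid = f"decoy{i + 1:03d}"
        root = _random_seq(rng, draw_len())
        variants = _calibrate_decoy(rng, root, spec.n_taxa, spec.decoy_identity_band)
        decoys[fid] = dict(zip(taxa, variants))

    # --- 4. marker families: private per taxon, contract-enforced -----------
    non_marker_pool: list[str] = []
    for fam in core.values():
        non_marker_pool.extend(_to_str(s) for s in fam.values())
    non_marker_pool.extend(_to_str(root) for root, _ in accessory.values())
    for fam in decoys.values():
        non_marker_pool.extend(_to_str(s) for s in fam.values())

    markers: dict[str, dict[str, np.ndarray]] = {t: {} for t in taxa}
    accepted_strs: list[str] = []
    redraws = 0
    limit = _MARKER_ID_CROSS - _MARKER_MARGIN
    for t in taxa:
        for i in range(spec.n_taxon_markers):
            fid = f"{t}_marker{i + 1:02d}"
            for attempt in range(_MAX_REDRAWS):
                cand = _random_seq(rng, draw_len())
                cand_s = _to_str(cand)
                cl = len(cand_s)
                ok = True
                for ref in non_marker_pool + accepted_strs:
                    if min(cl, len(ref)) / max(cl, len(ref)) < limit:
                        continue  # identity can never reach the limit
                    if pairwise_identity(cand_s, ref).identity > limit:
                        ok = False
                        break
                if ok:
                    break
                redraws += 1
            else:
                raise RuntimeError(f"could not draw a contract-satisfying marker for {t}")
            markers[t][fid] = cand
            accepted_strs.append(cand_s)

    truth = TruthTable(markers={t: sorted(markers[t]) for t in taxa}, marker_redraws=redraws)

    # --- 5. per-genome gene emission and contig assembly ---------------------
    n_plasmid = int(round(spec.plasmid_fraction * len(all_genomes)))
    plasmid_genomes = set(
        rng.choice(np.array(all_genomes), size=n_plasmid, replace=False).tolist()
    ) if n_plasmid else set()

    genome_paths, gene_paths = [], []
    manifest_rows = []
    for t in taxa:
        for gid in genomes[t]:
            manifest_rows.append((gid, t))
            fams: list[tuple[str, np.ndarray]] = []
            for fid in sorted(core):
                fams.append((fid, _mutate(rng, core[fid][t], spec.within_taxon_sub_rate)))
            for fid in sorted(markers[t]):
                fams.append((fid, _mutate(rng, markers[t][fid], spec.within_taxon_sub_rate)))
            for fid in sorted(accessory):
                root, subset = accessory[fid]
                if gid in subset:
                    fams.append((fid, _mutate(rng, root, spec.within_taxon_sub_rate)))
            for fid in sorted(decoys):
                fams.append((fid, _mutate(rng, decoys[fid][t], spec.within_taxon_sub_rate)))

            order = rng.permutation(len(fams))
            fams = [fams[i] for i in order]
            n_contigs = int(rng.integers(1, 4)) if len(fams) > 1 else 1
            n_contigs = min(n_contigs, len(fams))
            # split gene list into n_contigs consecutive chunks
            cuts = sorted(rng.choice(np.arange(1, len(fams)), size=n_contigs - 1, replace=False).tolist()) if n_contigs > 1 else []
            chunks = np.split(np.arange(len(fams)), cuts)

            contigs: list[tuple[str, str, str]] = []  # (contig_id, replicon, seq)
            for ci, chunk in enumerate(chunks):
                cid = f"c{ci + 1}"
                parts: list[str] = []
                pos = 0
                for k in chunk:
                    fid, seq = fams[k]
                    spacer = _to_str(_random_seq(rng, int(rng.integers(50, 201))))
                    parts.append(spacer)
                    pos += len(spacer)
                    strand = "+" if rng.random() < 0.5 else "-"
                    placed = seq if strand == "+" else _revcomp(seq)
                    parts.append(_to_str(placed))
                    start, end = pos, pos + len(seq)
                    pos = end
                    truth.placements.append(
                        GenePlacement(f"{gid}|{fid}", gid, cid, "chromosome",
                                      start, end, strand, fid)
                    )
                parts.append(_to_str(_random_seq(rng, int(rng.integers(50, 201)))))
                contigs.append((cid, "chromosome", "".join(parts)))

            if gid in plasmid_genomes:
                acc_here = [fid for fid, _ in fams if fid.startswith("acc")]
                picked = acc_here[:2]
                parts, pos = [], 0
                for fid in picked or ["plasmid_filler"]:
                    spacer = _to_str(_random_seq(rng, int(rng.integers(50, 201))))
                    parts.append(spacer)
                    pos += len(spacer)
                    if fid == "plasmid_filler":
                        parts.append(_to_str(_random_seq(rng, 300)))
                        pos += 300
                        continue
                    seq = dict(fams)[fid]
                    strand = "+" if rng.random() < 0.5 else "-"
                    placed = seq if strand == "+" else _revcomp(seq)
                    parts.append(_to_str(placed))
                    truth.placements.append(
                        GenePlacement(f"{gid}|{fid}|p", gid, "p1", "plasmid",
                                      pos, pos + len(seq), strand, fid)
                    )
                    pos += len(seq)
                parts.append(_to_str(_random_seq(rng, int(rng.integers(50, 201)))))
                contigs.append(("p1", "plasmid", "".join(parts)))

            gpath = out_dir / "genomes" / f"{gid}.fna"
            with open(gpath, "w") as fh:
                for cid, replicon, seq in contigs:
                    fh.write(f">{gid}|{cid} replicon={replicon}\n{_spaced(seq)}\n")
            genome_paths.append(gpath)

            cpath = out_dir / "genes" / f"{gid}.ffn"
            with open(cpath, "w") as fh:
                contig_seqs = {cid: seq for cid, _, seq in contigs}
                for p in truth.genes_of(gid):
                    sub = contig_seqs[p.contig_id][p.start: p.end]
                    coding = sub if p.strand == "+" else _revcomp_str(sub)
                    fh.write(
                        f">{p.gene_id} {gid}|{p.contig_id}:{p.start}-{p.end}({p.strand})\n"
                        f"{_spaced(coding)}\n"
                    )
            gene_paths.append(cpath)

    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("genome_id\ttaxon\n")
        for gid, t in manifest_rows:
            fh.write(f"{gid}\t{t}\n")

    truth.write(out_dir / "truth.tsv")
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=1, default=list)

    return genome_paths, gene_paths, manifest_path, truth
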