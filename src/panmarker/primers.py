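"""qPCR primer design and in-silico PCR.

Primer pairs are designed for SYBR-green real-time PCR: short amplicons
(<= 200 bp by default, because short products amplify processed-food DNA
more efficiently), oligos of 18-24 nt with nearest-neighbor melting
temperatures near the 60 degC annealing step, moderate GC, no long
homopolymers, and bounded self/cross complementarity.

The in-silico PCR binding model is deliberately simple and standard for
primer specificity screening: no indels, at most ``max_mismatch``
substitutions per oligo and none in the 3'-terminal ``three_prime_exact``
bases (polymerase extension is far more sensitive to 3' mismatches than
to internal ones).  Amplicons are reported for convergent primer sites
within ``max_product`` on either strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeRecord, TaxonManifest

__all__ = [
    "PrimerPair",
    "PrimerConstraints",
    "AmpliconHit",
    "melting_temperature",
    "gc_fraction",
    "design_primers",
    "in_silico_pcr",
    "specificity_matrix",
]

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")

# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K).
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)  # per G/C terminus
_INIT_AT = (2.3, 4.1)  # per A/T terminus
_R = 1.98722  # gas constant, cal/mol/K


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(oligo: str) -> float:
    return (oligo.count("G") + oligo.count("C")) / len(oligo)


def melting_temperature(
    oligo: str, method: str = "nn", Na_mM: float = 50.0, oligo_uM: float = 0.5
) -> float:
    """Melting temperature in degC.

    ``wallace``: 2*(A+T) + 4*(G+C).  ``nn``: unified nearest-neighbor
    dH/dS sums with terminal initiation terms, a 0.368*(N-1)*ln[Na+]
    entropy salt correction, and Tm = dH / (dS + R ln(C/4)) - 273.15
    with C the total oligo concentration (primers in large excess over
    template).
    """
    oligo = oligo.upper()
    if not 4 <= len(oligo) <= 36:
        raise ValueError("oligo length must be in [4, 36]")
    if set(oligo) - set("ACGT"):
        raise ValueError(f"non-ACGT symbols in oligo {oligo!r}")
    if method == "wallace":
        at = oligo.count("A") + oligo.count("T")
        gc = len(oligo) - at
        return float(2 * at + 4 * gc)
    if method != "nn":
        raise ValueError(f"unknown Tm method {method!r}")
    dh, ds = 0.0, 0.0
    for end in (oligo[0], oligo[-1]):
        ih, is_ = _INIT_GC if end in "GC" else _INIT_AT
        dh += ih
        ds += is_
    for i in range(len(oligo) - 1):
        h, s = _NN[oligo[i: i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(oligo) - 1) * math.log(Na_mM / 1000.0)
    c = oligo_uM * 1e-6
    return dh * 1000.0 / (ds + _R * math.log(c / 4.0)) - 273.15


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair with its design-time attributes."""

    name: str
    taxon: str
    forward: str  # 5'->3' on the marker's coding strand
    reverse: str  # 5'->3' on the opposite strand
    product_size: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    dimer_score: int = 0
    hairpin_score: int = 0
    forward_start: int = -1  # binding coordinates on the source marker
    reverse_end: int = -1


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 24
    tm_range: tuple[float, float] = (58.0, 62.0)
    gc_range: tuple[float, float] = (0.40, 0.60)
    min_amplicon: int = 80
    max_amplicon: int = 200
    max_homopolymer: int = 4
    max_dimer_score: int = 8
    max_hairpin_score: int = 6
    tm_method: str = "nn"


def _max_homopolymer(oligo: str) -> int:
    best = run = 1
    for a, b in zip(oligo, oligo[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _comp_run(a: str, b: str) -> tuple[int, int]:
    """(longest, longest touching a 3' end) antiparallel complementary run.

    A run is a substring of ``a`` that is reverse-complementary to a
    substring of ``b``, i.e. a common substring of ``a`` and
    ``revcomp(b)``.  The second value is the longest run that includes
    the 3'-terminal base of either oligo.
    """
    rb = revcomp(b)
    la, lb = len(a), len(rb)
    best = best3 = 0
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        for j in range(1, lb + 1):
            if a[i - 1] == rb[j - 1]:
                run = prev[j - 1] + 1
                cur[j] = run
                best = max(best, run)
                # a's 3' end is index la-1; b's 3' end maps to rb index 0,
                # so a run containing rb[0] ends a range that started at j-run==0
                if i == la or j - run == 0:
                    best3 = max(best3, run)
        prev = cur
    return best, best3


def dimer_score(a: str, b: str) -> int:
    """Complementarity score: maximal run, 3'-anchored runs counted double."""
    best, best3 = _comp_run(a, b)
    return max(best, 2 * best3)


_PAIRED = {"A": "T", "T": "A", "G": "C", "C": "G"}


def hairpin_score(oligo: str) -> int:
    """Longest self-complementary stem closable by a loop of >= 3 bases.

    A stem of length k pairs ``oligo[i+t]`` with ``oligo[j-t]`` for
    t = 0..k-1 (antiparallel), with at least 3 unpaired bases between the
    innermost paired positions.
    """
    n = len(oligo)
    best = 0
    for i in range(n):
        for j in range(i + 4, n):
            t = 0
            while (j - t) - (i + t) - 1 >= 3 and _PAIRED[oligo[i + t]] == oligo[j - t]:
                t += 1
            best = max(best, t)
    return best


def _valid_oligos(seq: str, c: PrimerConstraints) -> list[tuple[int, int, float]]:
    """(start, length, Tm) windows passing the per-oligo filters."""
    out = []
    for ln in range(c.min_len, c.max_len + 1):
        for s in range(0, len(seq) - ln + 1):
            oligo = seq[s: s + ln]
            if not c.gc_range[0] <= gc_fraction(oligo) <= c.gc_range[1]:
                continue
            if _max_homopolymer(oligo) > c.max_homopolymer:
                continue
            tm = melting_temperature(oligo, method=c.tm_method)
            if not c.tm_range[0] <= tm <= c.tm_range[1]:
                continue
            out.append((s, ln, tm))
    return out


def design_primers(
    marker: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    top_n: int = 5,
    taxon: str = "",
    name_prefix: str = "pair",
) -> list[PrimerPair]:
    """Exhaustively enumerate constraint-satisfying primer pairs, ranked.

    Pairs are ordered by |Tm_f - Tm_r|, then |mean Tm - 60|, then product
    size, with binding coordinates as the final deterministic tie-break.
    Returns an empty list (logged) when no pair satisfies the constraints.
    """
    marker = marker.upper()
    c = constraints
    if len(marker) < c.min_amplicon:
        raise ValueError("marker shorter than the minimum amplicon size")
    windows = _valid_oligos(marker, c)
    by_end: list[tuple[int, int, int, float]] = sorted(
        (s + ln, s, ln, tm) for s, ln, tm in windows
    )
    # rank all geometrically valid pairs by the cheap key, then evaluate the
    # quadratic dimer/hairpin screens lazily in rank order until top_n pass
    candidates: list[tuple[tuple, int, int, int, int, float, float]] = []
    for fs, fl, ftm in windows:
        for r_end, rs, rl, rtm in by_end:
            product = r_end - fs
            if product < c.min_amplicon or rs < fs + fl:
                continue
            if product > c.max_amplicon:
                break
            key = (abs(ftm - rtm), abs((ftm + rtm) / 2.0 - 60.0), product, fs, r_end)
            candidates.append((key, fs, fl, rs, rl, ftm, rtm))
    candidates.sort(key=lambda t: t[0])

    hairpins: dict[str, int] = {}
    out: list[PrimerPair] = []
    for _, fs, fl, rs, rl, ftm, rtm in candidates:
        fwd = marker[fs: fs + fl]
        rev = revcomp(marker[rs: rs + rl])
        for oligo in (fwd, rev):
            if oligo not in hairpins:
                hairpins[oligo] = hairpin_score(oligo)
        hp = max(hairpins[fwd], hairpins[rev])
        if hp > c.max_hairpin_score:
            continue
        dim = max(dimer_score(fwd, fwd), dimer_score(rev, rev), dimer_score(fwd, rev))
        if dim > c.max_dimer_score:
            continue
        out.append(
            PrimerPair(
                name=f"{name_prefix}_{fs}_{fs + (rs + rl - fs)}",
                taxon=taxon,
                forward=fwd,
                reverse=rev,
                product_size=rs + rl - fs,
                tm_forward=ftm,
                tm_reverse=rtm,
                gc_forward=gc_fraction(fwd),
                gc_reverse=gc_fraction(rev),
                dimer_score=dim,
                hairpin_score=hp,
                forward_start=fs,
                reverse_end=rs + rl,
            )
        )
        if len(out) >= top_n:
            break
    if not out:
        logger.info("no primer pair satisfies the constraints on a %d nt marker", len(marker))
    return out


@dataclass(frozen=True)
class AmpliconHit:
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+': forward primer on the plus strand
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def product_size(self) -> int:
        return self.end - self.start


def _window_mismatches(template: np.ndarray, oligo: str) -> np.ndarray:
    """Mismatch count of ``oligo`` against every window of ``template``."""
    enc = np.frombuffer(oligo.encode("ascii"), dtype=np.uint8)
    k, n = enc.shape[0], template.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(n - k + 1, dtype=np.int32)
    for off in range(k):
        mism += template[off: n - k + 1 + off] != enc[off]
    return mism


def _plus_strand_sites(
    template: np.ndarray, oligo: str, max_mismatch: int, three_prime_exact: int,
    three_prime_at_end: bool,
) -> list[tuple[int, int]]:
    """(start, mismatches) of oligo images on the plus strand.

    ``three_prime_at_end`` distinguishes an oligo whose 3' terminus maps
    to the right edge of the window (a plus-strand primer) from one whose
    3' terminus maps to the left edge (the reverse-complement image of a
    minus-strand primer).
    """
    k = len(oligo)
    mism = _window_mismatches(template, oligo)
    hits = []
    for s in np.nonzero(mism <= max_mismatch)[0]:
        window = template[s: s + k]
        enc = np.frombuffer(oligo.encode("ascii"), dtype=np.uint8)
        tail = slice(k - three_prime_exact, k) if three_prime_at_end else slice(0, three_prime_exact)
        if np.any(window[tail] != enc[tail]):
            continue
        hits.append((int(s), int(mism[s])))
    return hits


def in_silico_pcr(
    pair: PrimerPair,
    genomes: list[GenomeRecord],
    max_mismatch: int = 2,
    three_prime_exact: int = 2,
    max_product: int = 1500,
) -> list[AmpliconHit]:
    """Predict the amplicons a primer pair yields on a set of genomes."""
    hits: list[AmpliconHit] = []
    for genome in genomes:
        for contig in genome.contigs:
            template = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
            for left_oligo, right_oligo, strand in (
                (pair.forward, pair.reverse, "+"),
                (pair.reverse, pair.forward, "-"),
            ):
                lefts = _plus_strand_sites(
                    template, left_oligo, max_mismatch, three_prime_exact, True
                )
                rights = _plus_strand_sites(
                    template, revcomp(right_oligo), max_mismatch, three_prime_exact, False
                )
                for ls, lm in lefts:
                    for rs, rm in rights:
                        end = rs + len(right_oligo)
                        product = end - ls
                        if rs < ls + len(left_oligo):
                            continue  # not convergent / overlapping sites
                        if product > max_product:
                            continue
                        fm, rm_ = (lm, rm) if strand == "+" else (rm, lm)
                        hits.append(
                            AmpliconHit(
                                genome_id=genome.genome_id,
                                contig_id=contig.contig_id,
                                start=ls,
                                end=end,
                                strand=strand,
                                forward_mismatches=fm,
                                reverse_mismatches=rm_,
                            )
                        )
    hits.sort(key=lambda h: (h.genome_id, h.contig_id, h.start, h.end, h.strand))
    return hits


def specificity_matrix(
    pairs: list[PrimerPair],
    genomes: list[GenomeRecord],
    manifest: TaxonManifest,
    max_mismatch: int = 2,
    three_prime_exact: int = 2,
    max_product: int = 1500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplification matrix plus per-taxon sensitivity and specificity.

    Returns ``(matrix, summary)``: ``matrix`` holds the smallest product
    size per (pair, genome) or 0 when nothing amplifies; ``summary`` has
    one row per pair with sensitivity (fraction of target-taxon genomes
    amplified) and specificity (fraction of non-target genomes not
    amplified).
    """
    if not pairs:
        raise ValueError("specificity_matrix needs >= 1 primer pair")
    genome_ids = [g.genome_id for g in genomes]
    mat = pd.DataFrame(0, index=[p.name for p in pairs], columns=genome_ids, dtype=int)
    rows = []
    for p in pairs:
        hits = in_silico_pcr(p, genomes, max_mismatch, three_prime_exact, max_product)
        sizes: dict[str, int] = {}
        for h in hits:
            sizes[h.genome_id] = min(sizes.get(h.genome_id, 10**9), h.product_size)
        for gid, size in sizes.items():
            mat.loc[p.name, gid] = size
        targets = [g for g in genome_ids if manifest.assignments.get(g) == p.taxon]
        others = [g for g in genome_ids if g not in targets]
        sens = (
            sum(1 for g in targets if sizes.get(g, 0) > 0) / len(targets) if targets else np.nan
        )
        spec = (
            sum(1 for g in others if sizes.get(g, 0) == 0) / len(others) if others else np.nan
        )
        rows.append((p.name, p.taxon, sens, spec))
    summary = pd.DataFrame(rows, columns=["pair", "taxon", "sensitivity", "specificity"])
    return mat, summary
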