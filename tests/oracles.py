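"""Independent brute-force oracles used to validate the fast implementations.

Each oracle re-implements its operation from the definition, sharing no
code with the package: a plain-Python lexicographic Gotoh aligner, a
naive greedy clustering loop, an all-positions PCR site scan, and
closed-form least squares.
"""

from __future__ import annotations

import numpy as np

# Scoring definition (kept in sync with the package's documented scoring,
# but implemented independently): match +1, mismatch -1, a gap of length
# g costs OPEN + g * EXTEND.  Objective: lexicographically maximal
# (score, matches, -alignment_length).
MATCH, MISMATCH, OPEN, EXTEND = 1, -1, -4, -2


def oracle_align(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, alignment_length) by explicit triple-objective DP."""
    la, lb = len(a), len(b)
    neg = (-(10**9), 0, 0)

    def step(t, ds, dm):
        return (t[0] + ds, t[1] + dm, t[2] - 1)

    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = (0, 0, 0)
    for i in range(1, la + 1):
        X[i][0] = step(M[0][0] if i == 1 else X[i - 1][0], OPEN + EXTEND if i == 1 else EXTEND, 0)
    for j in range(1, lb + 1):
        Y[0][j] = step(M[0][0] if j == 1 else Y[0][j - 1], OPEN + EXTEND if j == 1 else EXTEND, 0)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            m = 1 if ai == b[j - 1] else 0
            M[i][j] = step(max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
                           MATCH if m else MISMATCH, m)
            X[i][j] = max(
                step(max(M[i - 1][j], Y[i - 1][j]), OPEN + EXTEND, 0),
                step(X[i - 1][j], EXTEND, 0),
            )
            Y[i][j] = max(
                step(max(M[i][j - 1], X[i][j - 1]), OPEN + EXTEND, 0),
                step(Y[i][j - 1], EXTEND, 0),
            )
    score, matches, neglen = max(M[la][lb], X[la][lb], Y[la][lb])
    return score, matches, -neglen


def oracle_identity(a: str, b: str) -> float:
    _, matches, length = oracle_align(a, b)
    return matches / length


def oracle_greedy_clusters(
    genes: list[tuple[str, str, str]],  # (gene_id, genome_id, sequence)
    threshold: float,
    identity_fn=oracle_identity,
    k: int = 8,
    use_prefilter: bool = True,
) -> list[list[str]]:
    """Naive re-implementation of the greedy centroid rule.

    Same ordering contract as the package: genes by (length desc, id asc);
    candidate centroids by (shared k-mer count desc, creation order asc),
    zero-sharing centroids excluded when the prefilter is on; the gene
    joins the first centroid at identity >= threshold.
    """

    def kmers(seq: str) -> set[str]:
        return {seq[i: i + k] for i in range(len(seq) - k + 1)}

    order = sorted(genes, key=lambda g: (-len(g[2]), g[0]))
    centroids: list[tuple[str, set[str]]] = []  # (sequence, kmer set)
    members: list[list[str]] = []
    for gene_id, _, seq in order:
        gk = kmers(seq)
        shared = [(len(gk & ck), ci) for ci, (_, ck) in enumerate(centroids)]
        if use_prefilter:
            cands = [ci for n, ci in sorted(((-n, ci) for n, ci in shared if n > 0))]
        else:
            pos = [ci for n, ci in sorted(((-n, ci) for n, ci in shared if n > 0))]
            cands = pos + [ci for n, ci in shared if n == 0]
        for ci in cands:
            if identity_fn(seq, centroids[ci][0]) >= threshold:
                members[ci].append(gene_id)
                break
        else:
            centroids.append((seq, gk))
            members.append([gene_id])
    return members


_RC = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def oracle_pcr_sites(template: str, oligo: str, max_mismatch: int, three_prime_exact: int,
                     minus_image: bool) -> list[tuple[int, int]]:
    """All-positions scan for oligo binding sites on the plus strand.

    ``minus_image=True`` scans for the reverse-complement image (3' end
    of the oligo at the left edge of the window).
    """
    probe = _rc(oligo) if minus_image else oligo
    k = len(probe)
    out = []
    for s in range(len(template) - k + 1):
        window = template[s: s + k]
        mism = [i for i in range(k) if window[i] != probe[i]]
        if len(mism) > max_mismatch:
            continue
        exact = range(three_prime_exact) if minus_image else range(k - three_prime_exact, k)
        if any(i in mism for i in exact):
            continue
        out.append((s, len(mism)))
    return out


def oracle_amplicons(template: str, fwd: str, rev: str, max_mismatch: int = 2,
                     three_prime_exact: int = 2, max_product: int = 1500):
    """(start, end, strand) of every amplicon by exhaustive site pairing."""
    out = []
    for left, right, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
        lefts = oracle_pcr_sites(template, left, max_mismatch, three_prime_exact, False)
        rights = oracle_pcr_sites(template, right, max_mismatch, three_prime_exact, True)
        for ls, _ in lefts:
            for rs, _ in rights:
                end = rs + len(right)
                if rs < ls + len(left) or end - ls > max_product:
                    continue
                out.append((ls, end, strand))
    return sorted(out)


def oracle_ols(xs, ys) -> tuple[float, float, float]:
    """Closed-form least squares (slope, intercept, r^2)."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    xbar, ybar = xs.mean(), ys.mean()
    sxx = ((xs - xbar) ** 2).sum()
    sxy = ((xs - xbar) * (ys - ybar)).sum()
    syy = ((ys - ybar) ** 2).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    r2 = sxy**2 / (sxx * syy)
    return float(slope), float(intercept), float(r2)
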