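# Methods

`panmarker` re-implements, at desk scale, the comparative-genomics
workflow behind species/subspecies-specific real-time PCR assays for
*Bifidobacterium*: build a pan-genome from labeled genomes, mine it for
taxon-specific genetic markers, design qPCR primer pairs on those
markers, screen them in silico, and interpret qPCR readouts (standard
curves, quantification, product label-claim verdicts).  This note
documents the models, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## Sequence identity

All comparisons use one statistic: the fraction of matching columns in
an optimal global (Gotoh affine-gap) alignment,

    identity = matches / alignment_length,

where `alignment_length` counts every column including gaps.  Scoring is
match +1, mismatch −1, and a gap of length *g* costs −4 − 2*g*.  Among
co-optimal alignments the reported value is canonical: the
implementation maximises the triple (score, matches, −alignment_length)
lexicographically, and the brute-force test oracle optimises the same
triple, so identity is well defined independently of traceback order.

Normalising by the full alignment length penalises length mismatch: a
300 nt query can never exceed identity 0.2 against a 1500 nt subject.
The gap costs are deliberately stiff.  Under cheap gaps (open −2,
extend −1) the optimal alignment of two *unrelated* equal-length random
sequences chases matches through gaps and converges on identity ≈ 0.49,
which coincides with the 0.50 cross-specificity threshold and leaves no
margin between "absent" and "borderline"; at −4/−2 the unrelated
background sits near 0.40.  Genuine gene families in bacteria diverge
predominantly by substitutions at the identity levels that matter here,
so the stiff gap costs leave homolog identities essentially untouched
while separating the background from the decision thresholds.

Two provable upper bounds prune alignment work without changing any
result: `identity ≤ min(len)/max(len)`, and
`identity ≤ (len(a)+len(b)−ed)/(2·max(len))` with `ed` the Levenshtein
distance (computed by edlib).  A candidate is skipped only when its
bound cannot beat the running maximum or the clustering threshold.

## Pan-genome clustering

Genes are clustered greedily, UCLUST-style: processed in deterministic
order (length descending, gene id ascending), each gene visits existing
cluster centroids in decreasing shared 8-mer count (ties by centroid
creation order) and joins the first one at identity ≥ 0.50 — the
default identity of the pan-genome pipelines this models — otherwise it
founds a new cluster.  The k-mer prefilter excludes only centroids
sharing zero 8-mers; on gene-length inputs this is a pure pruning step
(verified on fixtures), though for very short genes a pair below the
clustering threshold can legitimately share no 8-mer.

The presence/absence matrix holds copy counts per (cluster, genome);
column sums equal per-genome gene counts.  Partition definitions are the
standard ones: core = present in all genomes, unique = present in
exactly one, accessory = the rest.  A taxon core takes
`presence_fraction = 1.0` by default: a marker must be in *every*
genome of its taxon.  When a taxon's core looks eroded, the intended
remedy is the monophyly report (mislabeled genomes are the usual cause,
as with genome-database subspecies labels), not loosening the fraction.

## Trees

The pan-genome tree uses Jaccard distance on binary cluster presence
(optionally Euclidean distance on normalised cluster-count vectors);
the core-genome tree uses `1 − mean pairwise identity` over core
clusters where both genomes are single-copy.  A mean over per-gene
identities replaces a concatenated multiple alignment deliberately:
only the topology (do taxa form clades?) is consumed downstream, and
the mean preserves exactly that signal without a heavyweight aligner.
Both trees are built with classic Saitou–Nei neighbor joining;
tie-breaks are lexicographic on the smallest leaf label under each
node, negative branch-length estimates are clamped to zero (logged),
and NJ is exact on additive matrices (property-tested).  Monophyly of a
taxon means some edge bipartition isolates exactly its leaf set.

## Marker selection

For a target taxon, every taxon-core cluster is scored:

* `within_min_identity` — minimum over target genomes of the best
  identity between the cluster representative and any gene of that
  genome (co-clustered copies give this directly, since the
  representative is the centroid);
* `cross_max_identity` — maximum identity of the representative against
  any gene of any non-target genome, computed at gene level so a
  non-target gene that failed to co-cluster still rejects a marker.
  Genes sharing no 8-mer with the representative count as identity 0.

Acceptance requires `within_min ≥ 0.90`, `cross_max ≤ 0.50`, and a
non-plasmid replicon — the operational form of the observed "90–100%
within the taxon, 0–50% against other species" separation; both
thresholds are exposed on the CLI.  By default the screens short-circuit
candidates whose fate is already decided (e.g. a non-target gene inside
the candidate's own cluster above 0.50 rejects it immediately; its
reported cross value is then the largest identity observed rather than
the global maximum).  Accepted candidates are always screened
exhaustively, and `exhaustive=True` makes every reported value an exact
maximum.

The mobile-element filter rejects a candidate whose source gene lies on
a plasmid-flagged contig in any target genome, or whose representative
matches an operator-supplied exclusion FASTA (plasmid/prophage
sequences) at identity ≥ 0.80.  Screening external databases is the
operator's responsibility via that FASTA; the package does not ship a
plasmid/phage detector.

## Primer design and in-silico PCR

Primers are designed for SYBR-green qPCR at 60 °C annealing: oligo
length 18–24 nt, nearest-neighbor Tm in [58, 62] °C, GC in [0.40,
0.60], homopolymers ≤ 4, product size 80–200 bp (short amplicons
amplify degraded food-matrix DNA efficiently; the published assay's
products run 101–182 bp), and bounded complementarity.  Tm uses the
unified nearest-neighbor parameters with initiation terms, the
0.368·(N−1)·ln[Na⁺] entropic salt correction at 50 mM Na⁺, and
`Tm = ΔH / (ΔS + R ln(C/4)) − 273.15` at the assay's 0.5 µM primer
concentration; an independent implementation (Biopython's) agrees to
within 0.01 °C on all 44 published oligos.  Complementarity scores are
the maximal antiparallel complementary run length (self–self and
forward–reverse, runs touching a 3′ terminus counted double; defaults
≤ 8) and the longest hairpin stem closable by a ≥ 3 nt loop (≤ 6).
Pairs are ranked by |Tm_f − Tm_r|, then |mean Tm − 60|, then product
size, with coordinates as the final deterministic tie-break; the
quadratic complementarity screens are evaluated lazily in rank order,
which cannot change the returned set.

The pipeline designs on the *target-taxon majority consensus* of the
marker cluster rather than the centroid copy: a single genome's private
substitutions would otherwise sit under a primer's 3′ end in every
other genome of the taxon.  Designed pairs are then validated by
in-silico PCR, and the first pair that amplifies all target genomes and
no non-target genome is kept (falling back, with a warning, to the
best-ranked pair).

The binding model for in-silico PCR is the standard specificity-screen
one: no indels, at most 2 substitutions per oligo and none in the
3′-terminal 2 bases, convergent sites within 1500 bp on either strand.
All maximal hits are reported; results are invariant under
reverse-complementing the template (coordinates remap).  Per-taxon
sensitivity is the fraction of target genomes amplified, specificity
the fraction of non-target genomes not amplified.

## qPCR quantification and label claims

A standard curve is the OLS line Ct = slope·log₁₀(CFU/mL) + intercept
over ≥ 3 distinct concentrations (the assay uses five ten-fold points,
8×10⁵–8×10⁹ CFU/mL, in triplicate); R² is the squared Pearson
correlation, with a logged warning below the conventional 0.98
reliability threshold.  Efficiency is `(10^(−1/slope) − 1)·100`
(−3.3219 ⇒ 100%).  Quantification inverts the line; values outside the
calibrated range are returned but flagged extrapolated.  Ct cutoff
defaults to 35 (the assay runs 35 cycles).  Note the published Eff%
values were computed from unrounded slopes, so recomputing from the
printed three-decimal slopes reproduces them only to ≈ ±0.02; the tests
therefore also check the inverse direction (the slope implied by each
printed Eff% reproduces the printed slope to its final digit).

Label-claim comparison is a four-verdict total function applied in
order: all labels non-specific ("Lactic acid bacteria", "Bifidus") ⇒
`unverifiable_label`; a labeled subspecies must be detected exactly
while a labeled species is satisfied by itself or any subspecies;
any unsatisfied label or uncovered detection ⇒ `mismatch`; otherwise
`consistent`, or `consistent_with_refinement` when a species-level
label was resolved at subspecies level.  The published survey never
states the rule behind its single consistency count (and admits several
tallies), so the package reports per-verdict counts instead: on the 33
bundled survey rows this yields 18 consistent, 11 refined, 4
unverifiable, 0 mismatched.

## Synthetic fixtures

The generator plants ground truth in a labeled pan-genome.  Per
simulation: `n_genus_core` families in every genome (taxon ancestors
mutated from a family root at `cross_taxon_divergence/2` per branch);
`n_taxon_markers` private families per taxon; `n_accessory` families on
random genome subsets (presence probability 0.5); `n_decoy` families in
all genomes whose per-taxon variants are calibrated until pairwise
identities fall inside `decoy_identity_band` (default 0.65–0.85 —
squarely between the 0.50 and 0.90 decision thresholds, which is what
makes them decoys).  Genes are drawn 300–1500 nt, placed on 1–3 contigs
per genome with 50–200 nt random spacers on random strands; a fraction
of genomes receives a plasmid-flagged contig carrying copies of
accessory genes.  Each genome's gene copy differs from its family
ancestor by `within_taxon_sub_rate` per-site substitutions.
Substitutions only, no indels, so identity bands are analytically
controllable; an indel rate field exists but defaults to 0.  All
randomness flows from one seeded generator in a fixed order: identical
specs give byte-identical files.

Because unrelated equal-length sequences sit near identity 0.40 (with a
tail approaching 0.45), a freshly drawn marker can violate the
cross-identity contract by chance.  The generator therefore enforces
the contract empirically: each marker is aligned against every other
family ancestor and redrawn until all identities are ≤ 0.46 (0.50 minus
a 0.04 margin for within-taxon drift and per-gene maxima); redraw
counts are recorded in the truth table.  Decoy calibration iterates a
branch substitution rate (up to 10 rounds, multiplicative update)
until empirical pairwise identities land in the band.

What passing on these fixtures shows: the selection machinery recovers
exactly the planted signal and rejects intermediate-identity
familial lookalikes under realistic substitution noise, and the primer
stage turns recovered markers into pairs that are perfectly specific
*in silico*.  What it does not show: robustness to rearrangement,
horizontal transfer, annotation errors, indel-rich divergence, or
sequencing artifacts — none of which the generator emulates — nor
anything about wet-lab amplification efficiency, which depends on
chemistry the binding model does not represent.

## Problem sizes and defaults

Unit tests run on 3 taxa × 3 genomes with 200–500 nt genes; the
headline recovery and specificity checks use 5 taxa × 4 genomes, 3
planted markers per taxon, 20 decoy families, 1% within-taxon
substitution and 0.45 cross-taxon divergence — 10 replicate seeds for
marker recovery, 2 full end-to-end runs.  `scripts/acceptance.py`
recomputes recovery over 3 replicates plus one end-to-end run with
seeds derived from `--seed`.  Genome-database-scale surveys (hundreds
of genomes) are supported as an operator workflow but are not rerun by
the tests or the acceptance script.

## Known limitations

* Clustering is nucleotide-space only; protein-space orthology is out
  of scope.
* The greedy first-fit rule is order-dependent by design (documented
  ordering); it is not an MCL-style orthology inference.
* The cross screen's "no shared k-mer ⇒ identity 0" convention makes
  sub-threshold cross values prefilter-dependent for very short genes.
* In-silico PCR ignores indel-tolerant binding, thermodynamic duplex
  stability at the binding site, and amplification kinetics.
* Label verdicts depend on the declared taxonomy; taxa outside the
  vocabulary raise rather than guess.
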