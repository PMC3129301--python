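# Methods

## Model and procedure

An LTR retrotransposon inserts with two identical long terminal repeats.
Treating each repeat as an independently evolving copy of the same ancestral
sequence, the expected divergence between the two LTRs of a copy inserted
*T* years ago is 2*rT*, where *r* is the per-site yearly substitution rate.
The pipeline estimates divergence with the Kimura two-parameter (K2P)
correction, which models transitions (A↔G, C↔T) and transversions with
separate rates:

    D  = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with *P* and *Q* the observed transition and transversion difference
proportions over *n* compared alignment columns. The large-sample standard
error is Kimura's (1980):

    c1 = 1/(1-2P-Q),  c2 = 1/(1-2Q),  c3 = (c1+c2)/2
    SE = sqrt[(c1²P + c3²Q - (c1P + c3Q)²)/n]

The insertion age is T = D/2r with T's standard error SE/2r. Assumptions:
sites are independent and identically distributed, rates are constant in
time and across sites, base composition is stationary and (under K2P)
effectively uniform, and the two LTRs evolve independently after insertion
(no gene conversion between them). Copies whose divergence saturates the
correction (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raise a typed saturation error rather
than returning NaN, so batch runs can count undatable elements; copies with
a single LTR ("-1p" truncations, solo LTRs) are typed not-datable.

## Stage-by-stage choices

**LTR detection.** The element is compared with itself: exact 12-mer seeds
shared at an offset ≥ `min_len` are grouped by diagonal and extended with an
X-drop rule (match +1, mismatch −2, drop 12), which finds maximal
high-identity direct repeats without crossing into the partner copy.
Candidates are ranked by *terminality* (summed distance of the repeat pair
from the element's two termini), then identity, then length — terminal
repeats are what defines an LTR, so a slightly less identical but terminal
pair beats an internal tandem repeat. Defaults: `min_len` 80 bp,
`min_identity` 0.80, repeat at most 40 % of the element, motif window ±5 bp.
These are conservative for the ~1.5-kb LTRs of the gypsy elements this
pipeline targets and are all configurable. Boundaries are then anchored on
the canonical 5'-TG / CA-3' termini: the nearest TG within the window fixes
the 5' start of both copies, the nearest CA the 3' end of both, keeping the
copies equally long; failure to find a motif leaves the boundary unchanged
and flags it. Only direct (same-strand) repeats are considered.

**Pairwise alignment.** The two LTR copies are re-aligned with an exact
affine-gap global aligner (Gotoh's three-state recursion; a length-*L* gap
costs `gap_open + (L-1)·gap_extend`). Defaults: match +2, mismatch −1,
gap open −5, gap extend −1, terminal gaps charged like internal ones —
near-identical complete repeat units should not be teased apart by free end
gaps, though a `free_end_gaps` switch exists for semi-global use. Traceback
ties resolve diagonal → up → left, fixed for reproducibility. The fill runs
under numba; the brute-force enumeration oracle in the test suite verifies
optimality for short strings.

**Distance columns.** "Complete deletion" removes every column holding a
gap or N in either row (dating) or in any row (matrix mode); "pairwise
deletion" removes them per compared pair. Distance trees default to
pairwise deletion, dating to complete deletion. N is treated exactly like a
gap everywhere: missing data, never a match or mismatch.

**Neighbor joining.** Saitou–Nei agglomeration with the Studier–Keppler
criterion Q(i,j) = (N−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k). Ties take the
smallest (i,j) with taxa in label-sorted order, so runs are deterministic.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sister branch, preserving path lengths — required by downstream
Newick consumers and harmless on additive inputs, where NJ is exact (the
acceptance suite verifies exact topology and path-length recovery on random
additive matrices up to 8 taxa).

**Bootstrap.** Columns are resampled with replacement (`n_cols` draws,
seeded NumPy generator), the K2P + NJ pipeline is rebuilt per replicate, and
support for each internal split of the point-estimate tree is the
percentage of usable replicates containing it. Replicates whose resampled
matrix saturates are skipped and counted; more than half skipped aborts.
The bootstrap resamples the NJ pipeline itself — the tree method used —
rather than any likelihood model.

**Genome groups.** Both sides of every internal edge are candidate clades.
A side is genome-specific for genome G if it holds ≥ `min_size` tips
(default 5) and ≥ `purity_threshold` (default 0.90) of its labelled tips
carry G; unlabelled tips join clades but never count toward purity. Maximal
mutually disjoint genome-specific sides are reported (largest first); all
remaining tips form one mixed group — pruning whole one-side-of-an-edge
clades provably leaves a connected remainder. The defaults allow a handful
of foreign tips inside a large genome-specific radiation, which is the
pattern reported for these wheat element families.

**Composition accounting.** Category fractions are 100·bp/total rounded
half-up to one decimal (banker's rounding would flip .x5 cases and make
printed tables platform-dependent). The gene-island span is a coordinate
difference (last end − first start), not an inclusive length; gene density
is total/n·genes rounded to whole kb. Protein length assumes an intronless
CDS including the terminal stop: (span/3) − 1. Note the bundled tables
carry one internal inconsistency of their source: the five CDS spans sum to
4 914 bp while the annotation total prints 4 913 bp; both give 4.3 %. The
rolled-up TE total is reported bp-based (55.5 %), which differs from the
sum-of-rounded-class figure (55.6 %) by a rounding artifact. In-silico PCR
is exact-match: forward primer on the plus strand, reverse-complemented
reverse primer downstream, product = rev-site end − fwd-site start + 1,
capped at 5 kb by default.

## The synthetic-data generator

`synthetic_data` emits the study conditions the estimators assume: elements
with 1 500-bp LTRs (the scale of the gypsy solo LTRs in the clone
annotation) and a 6 000-bp internal region; substitutions under K80 with
r = 1.3 × 10⁻⁸/site/year and κ = 2 (no transition/transversion ratio is
reported for these elements; κ = 2 is the conventional default) at uniform
base composition; families as a two-level tree — a shared ancestral domain
(800 bp, the scale of a conserved RNase-H/RT domain), deep group stems and
shallow member crowns — with per-member times drawn uniformly up to the
crown bound, mirroring group radiations in the 0.5–2.5 MYA range.
Substitution uses the closed-form K80 site-change probabilities at total
divergence *rt* per branch rather than explicit event sampling; this is the
exact marginal distribution per site.

Deliberately **not** modelled: indels (families stay natively aligned, so
alignment quality is cleanly out of the estimators' test scope), rate
heterogeneity across sites, base-composition bias, nested insertions, gene
conversion between LTRs, and solo-LTR formation. Passing tests therefore
demonstrate estimator correctness under the matched model — they do not
certify accuracy on real elements where those processes operate; on real
data, gene conversion and rate variation both bias LTR ages downward.

## Problem sizes and determinism

The age-recovery checks use 200 simulated elements per age point
(0.5/1.0/1.6/2.5 MYA) — enough for the standard error of the cohort mean
ratio to sit near 1 %, so the ±5 % recovery band is a real test of bias and
not of noise. Boundary accuracy uses 100 elements at 4 % LTR divergence;
NJ oracle trials use 100 random trees of 4–8 taxa; bootstrap checks use 100
replicates. Analysis drivers use 50 elements per cohort. All randomness
flows through seeded NumPy generators; `scripts/acceptance.py` derives all
of its streams from the single `--seed` argument, and identical seeds give
byte-identical outputs everywhere (FASTA emission, bootstrap resampling,
Newick serialisation with its deterministic child ordering).

## Known limitations

* Detection assumes the element's boundaries coincide with its LTR termini
  (excised-element input, as produced by annotation); it does not discover
  elements de novo in genomic contigs and does not handle inverted repeats
  or target-site duplications.
* The K2P saturation boundary (P + Q approaching 0.5–0.75) limits datable
  ages to roughly D < 1, i.e. tens of MY at plant rates — far beyond the
  range of interest here, but batch reports should still expect typed
  saturation errors on degenerate alignments.
* `classify_genome_groups` reports maximal disjoint genome-specific clades;
  genome-specific *subgroups nested inside mixed groups* (a pattern seen in
  real family trees) appear only through the mixed group's purity field.
* In-silico PCR is exact-match by design; primer-template mismatches
  tolerated by real PCR are not modelled.
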