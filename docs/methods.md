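# Methods

This note documents the statistical machinery, the generative model behind
the synthetic data, the numerical conventions, and the design choices that
were genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Relative-rate framework

For a duplicate pair (A, B) with outgroup O, every alignment column with an
unambiguous, ungapped state in all three sequences is scanned. A column is
*unique to A* when A differs from B and O while B = O — under parsimony, a
substitution on A's branch since the duplication — and symmetrically for B.
Columns where all three states differ are tallied separately (`n_alldiff`),
kept in the usable length L but excluded from m_A/m_B; this follows the
classical construction of the unique-site relative-rate test. Because the
convention is not universal, `count_unique_sites(include_all_different=True)`
adds such columns to both counts instead.

The test statistic is χ² = (m_A − m_B)²/(m_A + m_B) with 1 df, upper tail, no
continuity correction; m_A + m_B = 0 is defined as χ² = 0, p = 1. The test is
conservative at the divergences this pipeline targets — with 10 substitutions
per copy (20 unique sites), only an absolute difference ≥ 9 rejects at
α = 0.05 — which is why the continuous variable below carries the inference.

**Asymmetry/site** = |m_A − m_B| / L standardizes the count difference for
gene length. L is computed at each level independently (nucleotide columns vs
amino-acid columns). For pairs with an identified ancestral copy, the signed
**standardized asymmetry** = (m_ancestral − m_derived)/L; negative values
mean the derived copy accumulated more unique sites.

Triplets are aligned at the protein level (Needleman–Wunsch on the
translations; the outgroup threaded onto the A/B alignment via its alignment
to A) and the nucleotide-level alignment is the codon expansion of the
protein one. This profile shortcut is exact when indels are rare and
anchored, as here; it would degrade for heavily shuffled proteins.

For structurally heterogeneous pairs all sequence statistics (unique sites,
asymmetry, K_S) are restricted to the homologous region: codons of paralog A
are masked by mapping them through the exon structure into the detected
homology bounds. Masking on A's coordinates suffices because non-homologous
columns involving only B are either gapped (excluded anyway) or aligned
against masked A codons.

## K_S estimation

K_S and K_A use Nei–Gojobori (1986) counting with Jukes–Cantor correction:
per-codon synonymous site fractions (changes to stop codons count as
nonsynonymous) averaged over both sequences; observed differences averaged
over all minimal substitution pathways, excluding pathways through stop
codons (if every pathway is blocked, all are used); d = −3/4 ln(1 − 4p/3),
flagged saturated at p ≥ 3/4. Codon pairs containing gaps, ambiguity codes or
stop codons are skipped. A likelihood codon-model estimator would be the
usual choice for publication-grade K_S, but at K_S ≤ 0.14 counting and ML
estimates agree closely, and here K_S serves only as a regression covariate
and cohort key; implementing codon ML is out of scope by design. The
implementation is cross-checked in the tests against Biopython's independent
NG86 routine and against hand-enumerated codon fixtures.

Age cohorts are the half-open bins [0,0.01), [0.01,0.03), [0.03,0.05),
[0.05,0.08), [0.08,0.14); K_S ≥ 0.14 is flagged out of range, excluded from
cohort summaries but retained in regressions.

## Duplication span and structure

The duplication span is the length of the homologous tract shared by the two
paralogs between their duplication termination points. Termination is a
human-judgement notion ("no apparent homology"); it is operationalized as:
sliding 100 bp windows (stride 50) along A's genomic context, a window is
homologous if its best *gapless* offset in B's context reaches 60% identity.
Gapless identity is deliberate: with gap-tolerant alignment, unrelated DNA
attains ~55–60% identity by chance, while ungapped random matches above 60%
are vanishingly rare; an edlib infix alignment (whose edit distance
lower-bounds the mismatch count at any offset) serves as a fast rejection
screen. Windows are accreted outward from the ORF until a homology-free
stretch ≥ 1 kb (termination) or sequence exhaustion (logged, flag left
false). Both `window_bp`, `min_identity` and `step_bp` are configuration
keys; the defaults are permissive at the ≤ 14% divergence this pipeline
targets. Bound accuracy is limited to roughly one window (±100 bp).

Two spans are computed by treating each paralog as ancestral (they differ
when indels accumulated); the reported span is the conservative minimum.

Structural classes: an exon is *unique* to a paralog when less than half its
length (configurable `overlap_fraction = 0.5`; a symmetric, testable
threshold for an otherwise verbal criterion) lies inside that paralog's
homology bounds. No unique exons on either side → complete; one side →
partial; both → chimeric. For regression the classes collapse to homogeneous
(complete) vs heterogeneous (partial + chimeric); the three-class resolution
is kept for the span comparison and pseudogene table.

## Ancestral vs derived assignment

Synteny rule: if exactly one paralog shares the outgroup ortholog's
chromosome label, it is called ancestral (parsimony — relocation happened to
the other copy; secondary translocations would violate this, and the caveat
is propagated into the report). Structure rule: the paralog sharing more
internal exon boundaries with the ortholog, compared in spliced coordinates
within ±6 bp (absorbs annotation jitter; configurable), is ancestral. When
both rules apply they must agree, otherwise the pair is flagged conflicting;
pairs where neither rule discriminates stay unassigned and are excluded only
from the signed-rank analysis.

## Inference battery

* Stepwise mixed selection: at each step the candidate with the smallest
  partial-F p-value (equivalently the t-test of its coefficient) enters if
  p ≤ 0.15; then any included term with p > 0.10 leaves; the procedure stops
  when nothing moves or a selection state repeats, and the selected terms are
  refit by ordinary least squares, reported as summary-of-fit / ANOVA /
  parameter-estimate blocks. Nominal predictors are coded 0/1 with reference
  levels "same" chromosome and "homogeneous" structure, so coefficient signs
  read directly as relocation/heterogeneity effects. Ties in entry p-values
  (within 1e-12, which also catches mathematically tied candidates that
  differ only in floating-point noise) resolve to the earlier candidate in
  the documented order (structure, location, span, K_S). A model that fits to
  machine precision stops further entry, since partial tests on a zero
  residual are meaningless.
* Kendall's τ-b with tie correction; exact p for n ≤ 30 without ties, normal
  approximation otherwise.
* Wilcoxon two-sample: Z from the rank sum with tie-corrected variance,
  two-sided normal p; continuity correction available but off by default.
* Wilcoxon signed-rank: zeros dropped, midranks on |d|; exact null for n ≤ 25
  without ties, else tie-corrected normal approximation. The reported T is
  the smaller rank sum signed by the direction of the median difference (a
  fixed, documented convention; legacy software prints a signed T without
  stating its construction).
* Kruskal–Wallis H with tie correction, p from χ² with k − 1 df.
* G-test of independence with Williams' correction
  q = 1 + (NΣ1/r_i − 1)(NΣ1/c_j − 1)/(6N·df).
* No multiple-testing correction anywhere: each test is reported at its own
  α = 0.05, matching the per-test design this battery reproduces. A
  correction could be layered on by the caller; the per-pair p-values are all
  exported.

Rank statistics and the stepwise path are validated against exhaustive
enumeration / independent reimplementation oracles in the test suite.

## Synthetic-data generator

The generator realizes the same model the analysis assumes, with truth
recorded per pair:

* Ancestral CDS: uniform random sense codons (no start/stop realism — the
  statistics are position-exchangeable, so none is needed).
* Substitutions: Poisson counts per branch, placed uniformly with uniform
  alternative nucleotides (Jukes–Cantor-like); substitutions creating stop
  codons are redrawn. Calibration: under uniform substitution the synonymous
  fraction of changes equals the synonymous fraction of sites, so the total
  expected pairwise count is K_S^target × L. The derived branch's expectation
  is multiplied by the asymmetry factor f ≥ 1; the outgroup branch carries
  `outgroup_depth_multiplier` (default 3, congeneric outgroups being strictly
  older than these young duplications) × half the pairwise total.
* Asymmetry model: f = max(1, exp(b₀ + b_ks·K_S + b_rel·relocated +
  b_span·span)), defaults (1.0, 4.0, 0.5, −1e-4). The log-linear form gives
  one interpretable knob per feature and keeps f ≥ 1; defaults were chosen
  once to make all three effects recoverable at n = 500 while staying within
  a factor-≈3 rate contrast.
* Features: K_S drawn from a truncated exponential on [0, 0.1363] (scale
  0.05 — young pairs over-represented, as observed in real duplicate-age
  distributions); relocation probability 34/130; structure probabilities
  65/130, 25/130, 40/130; pseudogene probability 20/130 assigned to the
  derived copy independently of asymmetry (a coupling knob is the natural
  extension for power studies); spans lognormal (median 1670 bp, log-sd 0.8)
  floored at 128 bp and capped at 10646 bp.
* Genomic realization: each gene gets 2–5 exons with splice sites at codon
  boundaries (a simplification that keeps truncated copies in frame), introns
  of 50–90 bp, 2 kb of flanking context; the duplicated tract covers the
  whole gene plus margins (complete), truncates inside an intron (partial),
  or additionally recruits a novel random exon into the derived copy
  (chimeric) — so heterogeneous pairs naturally have shorter spans, complete
  pairs longer ones. Noncoding tract sequence diverges at K_S/2 per branch.
  Context FASTA descriptions carry `ctx_start=` so annotations (chromosomal,
  0-based half-open) map into context coordinates.
* The manifest's A/B labels are randomized relative to ancestry.

`simulate_feature_table` is a fast path for power studies: it evolves the
same CDS triplets and computes every statistic from sequence (unique sites,
χ², NG86 K_S), but skips the genomic-context realization — exact here because
these triplets contain no indels and are positionally aligned by
construction. The full realization (`simulate_dataset`) exercises homology
detection, span and structure recovery at 130-pair scale.

What the generator does *not* emulate: codon-usage and GC bias,
transition/transversion bias, rate heterogeneity across sites, gene
conversion, within-tract indels (beyond the exon-level structural edits),
selection on the derived copy, and annotation error. Passing recovery tests
therefore demonstrate the pipeline's internal consistency under its stated
model, not robustness to those real-data complications. In particular the
default generator is signal-rich: dataset-scale summaries it produces
(fractions of significant pairs, R²) exceed what comparable biological data
show.

## Numerical choices and degenerate inputs

* Alignment scoring: nucleotide match +1 / mismatch −1 / gap open −4 /
  extend −1 (a gap of length k costs open + (k−1)·extend); protein BLOSUM62
  with −10/−1. Ties break deterministically: substitution over gap-in-A over
  gap-in-B. Scores are validated against full alignment enumeration (≤ 8
  residues) and an independent implementation (≤ 40).
* N/X/stop columns are excluded from all counts, including L.
* Zero usable columns, empty exon lists, constant vectors, all-zero
  differences, zero table marginals: explicit errors naming the offender.
* A pair failing any stage is logged, flagged in the report, and excluded
  without sinking the remaining pairs; blocks with insufficient data are
  marked skipped with a reason.
* Type-I calibration of the relative-rate test is assessed at 400 codons and
  K_S = 0.10 (~100 unique sites per triplet): at much smaller counts the χ²
  approximation on discrete data is conservative by construction, which is a
  property of the test, not of the implementation.

## Known limitations

* The homology detector's ±1-window bound accuracy propagates into spans;
  spans are not meaningful below ~2 windows.
* The outgroup-threaded triplet alignment assumes the outgroup aligns to A
  without large rearrangements.
* Ancestral assignment ignores translocations affecting the outgroup lineage.
* NG86 saturates near K_S ≈ 0.75 and is biased relative to ML estimators for
  divergent pairs; the pipeline's scope is K_S ≤ 0.14 where this is
  immaterial.
* Manual curation of alignments is not emulated; low-identity alignments are
  carried through flagged rather than edited.
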