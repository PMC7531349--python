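# Methods

This note documents the models, conventions and numerical choices behind
`centrodyad`, and what the synthetic-data generators do and do not emulate.

## Dyad detection

A dyad is parameterised by `(left_start, arm_length, spacer_length)` in
0-based, half-open coordinates; the right arm starts at
`left_start + arm_length + spacer_length` and must equal the exact
Watson–Crick reverse complement of the left arm. IUPAC ambiguity codes
(including N) are never treated as complementary to anything — a
conservative rule that can only under-count dyads in ambiguous sequence.

External palindrome finders differ in undocumented ways in which nested or
extendable repeats they suppress, so maximality is defined here explicitly
and testably. A candidate dyad is **maximal** when

* it cannot be extended *outward*: the flanking pair
  `(left_start − 1, span_end)` is out of bounds, non-complementary, or the
  extension would exceed `max_arm`; and
* it cannot be extended *inward*: the spacer is shorter than 2, the two
  innermost spacer flanks are non-complementary, or the extension would
  exceed `max_arm`.

`find_dyads` enumerates candidates by their innermost complementary pair
(O(n · max_spacer · mean-arm)); an exhaustive triple-enumeration oracle in
the test suite confirms exact agreement on hundreds of seeded sequences.
Dyads capped at `max_arm` count as maximal. With `allow_overlap=False`,
dyads are retained greedily by decreasing arm length (ties: leftmost first)
subject to disjoint spans; the default keeps overlaps, matching how dyad
coverage is normally scored.

**Dyad density** counts arm positions only, by default: the inverted repeat
is the two arms; the spacer is not repeated sequence. Because figure-level
conventions for "covered by a dyad" vary, `include_spacer=True` is provided
and is monotonically ≥ the arms-only value. Parameters default to
`min_arm=5, max_arm=100, max_spacer=20, allow_overlap=True` — the standard
settings for palindrome scans of point centromeres.

## Rank statistics

* **Kendall tau-b** with the usual tie corrections. Exact two-sided p by
  full permutation enumeration when n ≤ 8 and both vectors are tie-free;
  otherwise the tie-corrected normal approximation on C − D. The thresholds
  cover the group sizes arising in centromere tables (≤ ~16 per group) with
  exact inference wherever the data permit it. Constant vectors are
  rejected rather than returning an undefined coefficient.
* **Wilcoxon rank-sum** (Mann-Whitney), two-sided. Exact null distribution
  when both groups have ≤ 25 observations and the pooled sample is
  tie-free; otherwise normal approximation with tie-corrected variance and
  continuity correction. The numerical engines are scipy's, wrapped behind
  this method-selection policy; independent enumeration oracles in the test
  suite verify the exact branches.
* **Holm adjustment** is the classic step-down
  q₍ᵢ₎ = max₍ⱼ≤ᵢ₎ min(1, (m − j + 1)·p₍ⱼ₎). For the within-species
  old-versus-new centromere contrast the family is the two within-species
  tests (m = 2) — the most direct reading of a per-species comparison;
  all-pairs families are available through `compare_groups(pairs=...)`.

## Conservation scoring

Frequencies exclude gaps from the denominator; an all-gap column has no
frequencies and is masked. Columns with gap fraction ≥ `gap_threshold`
(default 0.5, configurable) are masked from every measure. Six measures are
implemented — {entropy, variance, sum-of-pairs} × {unweighted, Henikoff} —
of which the unweighted entropy measure is the primary profile; parity with
any particular external tool's full measure set is a non-goal. Orientation:
all measures are reported so that higher = more conserved (entropy is
Σ f ln f ≤ 0 with maximum 0 at a pure column; its lower bound is −ln 20 at
uniform). Raw scores are the default so the bounds are testable;
`normalize=True` z-scores each measure over unmasked columns for plotting.
The sum-of-pairs matrix defaults to BLOSUM62; Henikoff–Henikoff weights are
w_k = (1/L′) Σᵢ 1/(rᵢ·s₍ᵢ,ₖ₎) over non-all-gap columns, gap positions
contributing zero, normalised to mean 1.

## Gene-loss screening

Copy counts are kept as integers (0/1 pre-WGD, 0/1/2 post-WGD) rather than
booleans because "both ohnologs lost" and "one ohnolog lost" are different
events; loss means count 0, and the stricter reading (single-copy retention
as loss) is exposed as a flag. Dollo mapping collapses post-WGD counts to
presence (≥ 1), then reports the stems of maximal all-absent clades — the
unique minimum-event reconstruction under irreversible loss. A gene absent
everywhere maps to the root's child branches (the root has no stem).
Branch identifiers are the `|`-joined sorted leaf names below the branch,
which keeps reports stable across tree serialisations.

ORF scanning reports ATG-initiated, stop-terminated frames (stop inside the
coordinates, excluded from the protein), the 5′-most ATG per
(strand, frame, stop), default minimum 75 nt, both strands; ORFs running
off the sequence end appear only with an explicit flag. Homology
confirmation of candidate ORFs requires online database searches and is out
of scope: the screen reports ORFs and leaves identity judgments to the
user.

## Synthetic data

The generators are first-class, seeded (bit-reproducible) and emit truth
tables sufficient to score every downstream stage.

* **Centromere-like sequences**: i.i.d. bases at a GC drawn uniformly from
  `gc_range` (default 15–45 %, the AT-rich regime of point centromeres),
  lengths uniform in 100–500 bp. Planted inverted repeats (arms 5–12 bp,
  spacers 0–20 bp, right arm = revcomp(left)) arrive at an expected rate of
  `max(0, a − b·gc)` dyads **per 500 bp** with defaults a = 2.5, b = 0.05 —
  the simplest mechanism producing a monotone negative GC–density trend for
  power testing, not a claim about centromere biology. The per-length
  scaling keeps short sequences from saturating. Placement draws a
  geometry, then places uniformly among non-overlapping feasible positions;
  a sequence with no feasible slot after 100 draws is saturated and simply
  receives no further dyads (the truth table records exactly what was
  planted). Because the i.i.d. AT-biased background itself generates many
  short dyads, planted-repeat recovery is scored by span coverage (a
  detected dyad at least as long covering the planted span), not by exact
  identity.
* **Protein alignments**: an ancestral sequence mutated independently per
  column at block-structured rates (conserved C-terminal block 0.01,
  divergent N-terminal block 0.5, baseline 0.1 substitutions per site by
  default, or an explicit per-column profile). A lineage-restricted
  N-terminal insertion is realised post-alignment as a gap block in
  non-carrier rows, since alignment construction is out of scope. No
  phylogenetic rate matrices or branch lengths are modelled — passing tests
  show the scorer separates planted regimes, not that it handles real
  phylogenetic correlation.
* **Presence matrices**: each branch of a supplied species tree
  independently hosts a loss with fixed probability; leaves below any loss
  branch get count 0. Planted losses can be mutually redundant (e.g. two
  sibling branches jointly covering their parent clade), in which case the
  Dollo reconstruction returns the smaller minimal explanation; tests
  therefore assert exact recovery only where the planted set is itself
  minimal, plus leaf-set identity and minimality everywhere.
* **Naumovozyma panel**: per-group GC drawn from a normal centred on the
  reported group mean, truncated to the reported extremes, with
  sd = range/3.2 (the expected range of a normal sample of 10–12); group
  sizes 10 (*N. castellii*) and 12 (*N. dairenensis*) per category. This
  reproduces the within-species old-versus-new GC contrast pattern: the
  *N. castellii* contrast is decisive and the *N. dairenensis* one
  marginal. Acceptance checks summarise q-values by the median over 30
  panel replicates because a single 10-vs-10 exact rank-sum test at this
  effect size is not guaranteed significant on every draw.

## Problem sizes and determinism

The test suite uses 200 sequences of ≤ 80 bp for oracle equivalence, 100
seeds for the Monte-Carlo recovery and anticorrelation properties, 30
replicates for the panel contrast, and 200 replicates for the group-test
power check; the full suite runs in about a minute on one CPU, and
`scripts/acceptance.py` in well under one. All randomness flows from
explicit seeds; identical inputs and configuration give byte-identical
pipeline outputs (the run manifest records parameters and input checksums).

## Known limitations

* Mismatch-tolerant inverted repeats are not detected (arms must be exact
  complements); thermodynamic cruciform/DNA-melting scores are out of
  scope.
* The i.i.d. background model ignores dinucleotide composition and repeat
  structure of real intergenic DNA, so synthetic dyad densities are not
  calibrated to genomic base rates.
* The conservation module consumes alignments; it does not build them, and
  alignment uncertainty is not propagated.
* Dollo mapping assumes presence at the root and no regain; horizontal
  re-acquisition or assembly artefacts masquerading as loss must be handled
  upstream.
* The packaged kinetochore copy matrix
  (`data/kinetochore_copy_matrix.synthetic.tsv`) is a synthetic stand-in:
  it encodes the documented loss pattern exactly, and fills every otherwise
  unconstrained cell with presence, so per-species copy numbers outside the
  loss calls are placeholders.
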