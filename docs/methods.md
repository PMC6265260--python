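# Methods

This note documents the models and procedures `circdigit` implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Backsplice junction calling

A backsplice junction joins the 3′ end of a downstream exon (splice donor)
to the 5′ end of the same or an upstream exon (splice acceptor), so a read
spanning it is non-colinear: its prefix matches the genome near the donor
and its suffix matches *upstream* of it. The caller takes the anchor-pair
approach:

1. Extract head (`read[:anchor_len]`) and tail (`read[-anchor_len:]`)
   anchors; look both up in an exact k-mer index of the genome (both
   strands). Reads whose anchors do not map **uniquely** to the same
   chromosome and strand are discarded — the stringency that keeps calls
   unambiguous on a repeat-free genome.
2. Anchors in head-to-tail order (tail genomically upstream of head) signal
   a backsplice. Every breakpoint position `b` consistent with ≤
   `max_mismatch` mismatches in the two extended alignments is enumerated;
   junction-edge sequence repeats make several `b` equivalent (the
   ambiguity window).
3. The breakpoint is chosen as the first (leftmost) `b` flanked by canonical
   splice signals in genomic orientation — `AG|acceptor … donor|GT` for a
   plus-strand gene, `AC|acceptor … donor|CT` for a minus-strand gene (the
   reverse complement of GU..AG read on the transcribed strand). The signal
   also assigns the junction's strand, which read orientation cannot
   (libraries are unstranded). Without any signal-consistent position the
   leftmost `b` is used (or the read dropped under `require_gt_ag`).
4. The chosen breakpoint must have at least `min_overhang` nt of read on
   both sides, enforced *after* breakpoint selection. Enforcing it on the
   scan range instead is subtly wrong: a read whose true breakpoint misses
   the window by one base can still anchor-map through a one-base ambiguity
   and would then be assigned to a shifted coordinate inside the window,
   fabricating an off-by-one junction.
5. Junctions are aggregated by (chrom, strand, acceptor_start, donor_end),
   0-based half-open, minus-strand junctions kept in genomic coordinates. A
   read id contributes at most one count per junction, so a fragment whose
   two mates both span the junction, or a rolling-circle read crossing it
   twice, is one molecule of evidence. (With exact anchors and
   `max_mismatch=0` a read containing a full circle wrap cannot be covered
   by the two-segment alignment at all and is dropped — it contributes 0,
   never 2.)
6. Junctions supported by fewer than `min_support` reads (default 5) are
   discarded.

Defaults — `anchor_len=20`, `max_mismatch=0`, `min_overhang=8`, optional
GT/AG requirement — are the package's stringent configuration; all are
exposed because "stringent" is a spectrum, not a single published setting.
Effective overhang is `max(min_overhang, anchor_len)` since both anchors
must clear the breakpoint; tests that compare against truth labels simulate
with `min_overhang=anchor_len` so both sides share one definition of
"spanning".

### Quantification

* `rpm = n_junction_reads / total_raw_reads × 10⁶`.
* `ctl = n_junction_reads / ((n_linear_donor + n_linear_acceptor)/2)`,
  undefined when both linear counts are zero (serialized `NA`) — this is
  the case for circles whose host produces no linear transcript.
* Linear spanning counts accept either genomic continuation across a site
  (one aligned segment covering it with `min_overhang` on both sides) or an
  exon-aware spliced continuation whose splice lands exactly on the site;
  backsplice-supporting reads are excluded. The same overhang applies to
  linear and backsplice evidence, for symmetry.

## Probe design

The junction target is the last `window/2` nt of the spliced circle joined
to its first `window/2` nt (default window 100), i.e. the junction-centered
substring of the doubled circle sequence. Circles shorter than the window
wrap — the target is the junction-centered stretch of length
`min(window, circle length)`, flagged `wrapped_target`; the molecule is
circular, so wrapping (not truncation) is the faithful geometry. The target
is split at its midpoint into capture and reporter target halves; a split
away from the junction is flagged `off_center_junction`. Centering
maximizes the junction dependence of the adjacent-binding requirement: on
any linear transcript the two probe binding sites are separated by the rest
of the transcript, so no adjacent hybridization — and no count — occurs.

QC flags: per-half GC content outside `(0.3, 0.7)`, homopolymer runs longer
than 6, and — the specificity criterion — occurrence of the
junction-centered 40-mer anywhere in the linear genome or its reverse
complement. On a repeat-free genome a true backsplice 40-mer can never
occur colinearly, so this flag catches design errors and degenerate
circles. Linear reference-gene probes are any QC-passing exonic 100-mer
(their placement is unconstrained by the junction logic). Serialized
codesets carry both target-sense sequences and their reverse complements
(the actual probe oligos) to avoid orientation ambiguity.

## Digital-count normalization

The cascade is a fixed-order stage machine (`raw` →
`background_subtracted` → `positive_normalized` → `reference_normalized`);
calling a stage out of order raises, and every matrix carries its stage tag.

1. **Background**: per lane, subtract the mean of the negative-control
   counts from every biological target, floored at 0 (counts cannot be
   negative); `mean + 2 SD` is available as a stricter alternative.
   Control rows are retained unmodified for audit.
2. **Positive controls**: lane factor = (arithmetic mean across lanes of
   per-lane geometric means of the positive spikes) ÷ (this lane's
   geometric mean). Endogenous, housekeeping *and* positive rows are
   scaled, so post-normalization positive geometric means agree across
   lanes to machine precision. Factors outside the conventional [0.3, 3]
   band trigger a warning, not a failure.
3. **Reference genes**: the same construction on the geometric mean of the
   chosen stable linear reference genes; the output is the "normalized
   count" used by all downstream comparisons.

Geometric means use a pseudocount of 0.5 for zeros by default (keeping
lanes comparable when a control drops out); exclusion is available.
Reference genes are chosen as the `k=4` most stable of 5 candidates, by
default the standard deviation of log₂ counts across lanes (deterministic,
ties broken by name); a geNorm-style iterative pairwise-variation ranking
is provided as an alternative since commercial software does not publish
its criterion.

**Scale invariance.** Writing `g_l`/`r_l` for a lane's positive/reference
geometric means, the cascade composes to
`final_l = raw_l × P × mean_l(r/g) / r_l` with `P = mean_l(g_l)`: the
positive-stage factor cancels within the reference stage. Rescaling one
lane's raw counts leaves `r_l/g_l` unchanged for every lane, so all
cross-lane and cross-target ratios are exactly preserved; only the single
global gain constant `P` moves. Invariance therefore holds up to one
uniform multiplicative factor, and that is the form the tests assert —
per-entry invariance is impossible for any cascade whose anchor is a
data-driven mean, and the absolute scale of normalized counts is arbitrary
anyway.

## RNase R validation

RNase R is a 3′→5′ exonuclease that degrades linear RNA; circRNAs, having
no free ends, generally resist it (though some circRNAs are known to be
RNase R sensitive). Treated and mock-treated lanes are compared per target
with a signed fold change: `treated/mock` when treated > mock,
`-(mock/treated)` when treated < mock, `+1` at equality, undefined when
either side is zero — so `|fc| ≥ 1` always and the sign encodes direction.
Classifications: `enriched_2x` (treated > 2 × mock, on normalized counts by
default) and `enriched_50ct` (raw increase > 50 counts, a detection-level
criterion robust for low-expressed targets). Class averages are means of
signed fold changes over *expressed* targets (normalized mock ≥ 20 by
default — unexpressed circRNAs cannot be enriched and would only add
ratio noise); under the default simulated treatment (sixfold circRNA
enrichment, fourfold linear depletion) the circRNA class average recovers
≈ +6 and the linear class ≈ −4.

## Concordance and clustering

Cross-platform agreement is assessed on paired per-target values
(normalized counts vs RPM): OLS regression reporting R² (the squared
Pearson correlation) and the two-tailed slope-t p-value; and a dichotomous
comparison — expressed iff value ≥ the platform's cutoff (defaults:
normalized count ≥ 20; ≥ 2 junction reads, i.e. RPM ≥ 2/total × 10⁶) —
cross-tabulated and tested with a two-tailed Fisher's exact test
(point-probability summation convention, via scipy; validated in the test
suite against an exact integer-enumeration oracle on all tables with
margins ≤ 30). Platform-specific detection lists (A-only / B-only) are
returned alongside the table. An explicit per-analysis exclusion list
supports documented outlier removal; exclusions are configuration, never
silent.

Expression profiles are clustered by z-scoring each target across samples
(population-SD denominator by default; sample-SD by flag; constant rows are
zeroed and flagged) and running agglomerative UPGMA (unweighted average
linkage) on the Pearson correlation distance d = 1 − r. Labels are sorted
lexicographically before clustering so ties break deterministically.
Dendrograms serialize to Newick (via scikit-bio) and support flat cuts.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the analysis assumes:

* **Genomes**: a single chromosome with non-overlapping multi-exon genes
  (defaults: exons 80–120 nt, introns 50–100 nt), canonical splice signals
  flanking every exon on both strands, and genome-wide-unique exonic
  20-mers (regenerated until true) so anchor mapping is unambiguous.
* **Truth**: log-normal linear and circular abundances (default μ=0,
  σ≈1.2–1.5, so circular-to-linear ratios span both sides of 1); one circle
  per selected host over a contiguous exon run — internal exons when the
  gene has ≥ 3 (so linear reads can span both backsplice sites), the whole
  gene otherwise; an optional RNase-R-sensitive subset.
* **Reads**: fixed-length fragments sampled from spliced linear transcripts
  and wrap-around circle sequences in proportion to abundance, from either
  strand with p = 0.5, with uniform per-base substitution errors and
  constant FASTQ qualities. Rolling-circle concatemer fragments (longer
  than the circle) are generated at a configurable rate and labelled
  distinctly. Truth labels ride in read names.
* **Counts**: `round(lane_scale × expected × lognormal(sd=noise)) +
  Poisson(neg_mean)` per target and lane, with expected values proportional
  to truth abundance (endogenous), fixed bases (5 housekeeping candidates),
  or a 6-point geometric positive ladder (ratio 4; the positive gain is
  chosen so noiseless ladder expectations are integral, keeping the
  noiseless contract exact under integer rounding). RNase R multiplies
  expectations by the enrichment/depletion factors and Poisson-resamples.
* **DV200** takes an empirical fragment-length distribution and returns the
  fraction of fragments above 200 nt; degradation is emulated only through
  that distribution.

Not emulated: position- or quality-dependent sequencing error, adapter
contamination, insert-size distributions, GC or length bias in library
prep, probe cross-hybridization, lane binding-density effects, and FFPE
chemical damage beyond fragment length. Passing tests therefore demonstrate
the correctness of the algorithms under their stated assumptions — unique
anchors, canonical signals, unbiased sampling — not performance on real
libraries, where anchor multi-mapping and biased coverage dominate error.

## Numerical and design choices

* Coordinates are 0-based half-open internally and in BED; GTF output is
  1-based inclusive. Junction identity is (chrom, strand, acceptor_start,
  donor_end).
* Random draws flow from one seeded NumPy generator per operation call; no
  global state. The pipeline expands a single global seed into per-stage
  seeds by SHA-256, so changing one stage's parameters does not perturb
  another's randomness. Pipeline reruns are byte-identical (manifests
  record SHA-256 checksums of every output).
* Breakpoint ties: splice-signal-consistent position first, then leftmost
  genomic — deterministic, reproducible coordinates.
* `signed_fold_change(7, 7) = +1` (ties count as unchanged, positive by
  convention); zero-count cases are undefined rather than infinite.
* Fisher two-tailed p uses the point-probability summation convention with
  a small relative slack for floating-point ties at the boundary.
* The test-suite problem sizes (toy genomes of a few kb, hundreds to a few
  thousand reads, 52-probe codesets, 3 lanes) were chosen as the smallest
  scales at which every property is statistically sharp — binomial checks
  use 3-SD bands at n ≥ 500, clustering designs were verified robust across
  hundreds of seeds before freezing.

## Known limitations

* The caller is exact-anchor based and intended for repeat-free synthetic
  genomes; it does not handle multi-mapping anchors, indels, or
  genome-scale inputs (no BWA/Bowtie2 backend).
* Paired-end simulation is minimal (two mates of a fixed-length fragment);
  single-end suffices for every analysis here.
* Fusion/trans-splicing detection and inference of a circle's internal
  structure are out of scope.
* The 2×2 concordance test is only informative when both platforms' cutoffs
  sit at comparable detection levels; with mismatched cutoffs one margin
  empties and the Fisher p is vacuously 1.
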