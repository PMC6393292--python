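# Methods

This note documents the model behind `okaseq`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Fragment model and coordinate conventions

A mapped Okazaki fragment is an interval `[start, end)` (0-based half-open)
with a mandatory strand. Synthesis runs 5′→3′, so the 5′ terminus (first
synthesized nucleotide) is `start` on `+` and `end − 1` on `−`; the 3′
terminus mirrors. The 3′ terminus is defined as the last synthesized
nucleotide (`end − 1` on `+`), not the open endpoint, which makes 5′/3′
offsets integer-symmetric under strand flips. Fragments without strand are
rejected rather than split: synthesis orientation is the substance of every
downstream statistic, and an unstranded record cannot contribute to it
meaningfully.

Simulated records carry one extra annotation, the junction state at the
fragment's 5′ end (`nick`, `gap:<n>`, `flap:<n>` in an optional seventh BED
column), so generative ground truth survives serialization and the ligation
module can run on files.

## Meta-profiles

For terminus position *t* of a fragment with strand sign *s* and a feature
midpoint *m* on the same chromosome, the synthesis-oriented offset is
Δ = *s*(*t* − *m*); the profile counts terminus–feature pairs with
|*t* − *m*| ≤ *W*. Design choices:

* **Composite counting.** A terminus within *W* of several features counts
  toward each; there is no nearest-feature assignment. This is the simplest
  rule consistent with a composite ("meta") profile and makes raw profiles
  conserve pair counts exactly (a tested invariant). With the default dyad
  window *W* = 100 nt — smaller than the 165-nt repeat — multiple counting
  across neighbouring dyads is rare anyway.
* **Windows.** *W* = 100 nt for dyads (covers the 147-nt nucleosome core
  plus linker) and 250 nt for TF sites (captures flanking sequence needed
  by median normalization). Both are configurable.
* **Feature orientation is ignored** for profile orientation; only fragment
  strand orients the offsets. TF-site motif strand handling is left to the
  caller (sites are treated as points).
* **Smoothing** is a centered moving average of odd width (default 5 bp),
  truncating at the window edges (the average is over available offsets
  only; mass is not conserved at edges). Even widths are rejected as they
  have no unambiguous center.
* **Normalization** divides by the in-range maximum (nucleosome profiles)
  or the in-range median (TF-site profiles, where the question is
  enrichment at the site relative to nearby sequence). Max-normalized
  profiles have maximum exactly 1; median-normalized ones median exactly 1;
  both operations are idempotent and error on degenerate (all-zero or
  zero-median) inputs.

## Shift and decoupling statistics

The displacement of profile *b* relative to profile *a* is the integer lag
maximizing the Pearson correlation of the two max-scaled profiles, refined
by fitting a parabola through the correlation at the best lag and its two
neighbours. Cross-correlation was chosen over a difference of peak
positions or means because it is robust to peak-shape changes between
conditions and to the multi-modal structure that TF barriers introduce.
Negative estimates mean displacement toward negative (fork-proximal)
offsets. Lags are searched over ±*W* with a minimum overlap of 25 offsets;
the parabolic step is only applied at a proper local maximum.

The decoupling statistic is δ = shift of the 5′ profile relative to the 3′
profile of the same sample. A rigid (nick-translation) shift moves both
ends together, so δ stays near the +1 nt that interval geometry implies
(each 5′ end abuts, one nucleotide downstream, the 3′ end of the fragment
terminating at the neighbouring nucleosome). Ongoing strand displacement
pulls 5′ ends upstream by the flap length, making δ negative by roughly the
mean flap length. The verdict threshold |δ| > 5 nt is a package default:
the underlying dichotomy is qualitative, and 5 nt sits well above the
estimator's sampling error at the ensemble sizes used (≈0.5 nt at
n = 50 000) and well below any flap length of interest.

## Length periodicity

Fragment lengths are binned at 1 nt on [50, 2000]. The histogram is trimmed
to its occupied range and detrended by subtracting a centered moving
average (default width 101 nt, odd and below the repeat length so that
repeat-scale structure survives); the statistic is the autocorrelation of
the residual, normalized by its zero-lag value, maximized over lags in
[100, 400]. Detrending matters: the raw mean-centered histogram of *any*
compact length distribution autocorrelates strongly at short lags through
its envelope alone, which would let an unstructured control outscore a
genuinely periodic ensemble. With detrending, unstructured controls score
near the noise floor while repeat-phased ensembles recover the repeat
length exactly (tested at n = 50 000).

## In-silico ligation

Junctions between consecutive same-strand fragments are `nick` when the
intervals abut exactly (`downstream.start == upstream.end`; the condition is
strand-symmetric), `gap` when separated, `flap_overlap` when overlapping.
Two deliberate strictness rules model purified DNA plus T4 ligase with no
nuclease present: near-abutment (±1 nt) is never merged, and overlaps are
never trimmed-then-ligated.

When fragments carry simulated junction annotations, the annotation of the
5′-side fragment takes precedence over geometry. This is necessary because
the generator places fragments independently at dyads (see below), so
sorted-adjacency geometry is not informative about the drawn junction
state; a geometric cross-check is only meaningful for chain-structured
(real or constructed) input and is available via `prefer_annotation=False`.

`ligate_in_silico` merges maximal runs of nick-joined fragments. A merged
molecule's length is the sum of its constituents' lengths — for abutting
runs this equals the genomic span exactly (covered length is conserved, a
tested invariant); for annotation-driven merges it is the physically
meaningful quantity (ligation joins molecules end to end). The signal model
is one unit per molecule shorter than the size cutoff (default 1000 nt):
end-labeling marks termini, and the gel quantifies labeled molecules in a
size window. Whether real gel signal scales per labeled end or per
incorporated nucleotide is not derivable from first principles here; the
per-end model is a stated simplification. Replicate pairs (signal without
ligase, with ligase) are compared by a standard two-sided paired t-test
(df = n − 1), which errors on fewer than two pairs or zero difference
variance.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes; it
contains no polymerase/nuclease kinetics, no sequence, and no read-level
error model. Per configuration (all defaults below are package choices,
stated once and used by tests and the acceptance script alike):

* **Genome.** One 1-Mb chromosome; dyads tiled every `nucleosome_repeat`
  (165 nt) with Gamma(2, 1) occupancy scores (a right-skewed positive
  distribution so "top fraction by occupancy" selection is non-trivial);
  ten origins 100 kb apart. Fork direction is `+` right of the owning
  origin and `−` left of it, with ownership boundaries at inter-origin
  midpoints — the minimal structure sufficient to exercise strand
  orientation, chosen over a replication-timing model on purpose.
* **Strand.** A fragment's strand equals the fork direction at its assigned
  dyad, so synthesis proceeds left-to-right in `+` domains and the two
  strands contribute mirror-image genomic offsets that the orientation
  convention folds together (a tested symmetry).
* **3′ terminus.** Dyad midpoint + *s*·(shift + Normal(0, σ)), rounded.
  Per-condition shifts (nt): WT 0, rad27 −20, exo1 −10, dna2 0,
  rad27_exo1 −30, rad27_dna2 −20, exo1_dna2 −10, triple −30; σ = 15
  throughout. The orderings encode the qualitative severity ranking of the
  depletions (Rad27 ≫ Exo1 > Dna2 ≈ none, with Rad27+Exo1 additive and
  Dna2 adding nothing); the magnitudes themselves are free parameters of
  the simulation, documented as such.
* **Length.** k·repeat + Normal(0, 15), k ∈ {1, 2, 3} with weights
  0.7/0.2/0.1 (the mono-/di-/tri-nucleosome ladder), minimum 50 nt to
  avoid degenerate records. The 5′ terminus sits length − 1 nt upstream of
  the 3′ terminus in synthesis direction, so both termini shift together —
  the reduced-nick-translation regime.
* **Junctions.** Nick with probability `ligatable_fraction` (0.9 for
  Rad27-proficient conditions, 0.8/0.75 with exo1Δ, ≤0.05 for
  Rad27-depleted), otherwise gap or flap with equal odds and length
  1 + Poisson(4) — guaranteed ≥1 nt and short, since no length
  distribution for residual gaps/flaps is established.
* **TF hard barriers.** 100 sites 10 kb apart. A fragment assigned within
  one repeat of a site relocates its 3′ terminus to the fork-proximal site
  edge (`midpoint − s·8` nt) with probability 0.8, producing the sharp
  terminus peak immediately upstream of the site.
* **`decoupled_flap_mode`.** The alternative mechanism: 3′ termini at their
  wild-type positions, every 5′ terminus extended upstream by a flap length
  (1 + Poisson draw), junctions all flaps. This exists so both competing
  hypotheses — coupled shift vs 5′/3′ decoupling — are simulable and the
  classifier can be validated against ground truth.
* **Determinism.** Genome draws and per-condition fragment draws come from
  separate, condition-indexed child streams of the seed, so a panel shares
  one genome, conditions are independent, and identical configurations are
  bit-identical. Fragments falling off a chromosome end are clipped and
  flagged in the ground truth (≈0.03% at defaults; summary statistics
  exclude them, as they exclude TF-relocated fragments).

**What passing tests do and do not show.** The generator produces exactly
the structure the statistics assume: Gaussian terminus placement, iid
fragments, uniform dyad usage, ideal strand assignment, no mappability
gaps, no duplicate reads, no replication-timing or origin-efficiency
heterogeneity, no sequence bias. Parameter-recovery results on it validate
the *estimators* (aggregation, cross-correlation, autocorrelation, merge
accounting) — they do not validate the biological parameter values, and
performance on real libraries will additionally depend on everything the
generator idealizes away.

## Problem sizes

Statistical tests and the acceptance script use 50 000 fragments per
condition over the 1-Mb genome (≈6 000 dyads, 3 000 after occupancy
filtering), 20 000 per point for the ligation monotonicity sweep, and three
replicates for the paired t-test — sizes at which the estimators' sampling
error is comfortably below the tolerances being checked (e.g. shift
recovery to ±2 nt) while the whole suite runs in seconds.

## Known limitations

* Real paired-end data must be reduced to fragment intervals upstream;
  outer-coordinate collapsing is assumed but not performed here (no
  BAM/FASTQ handling by design).
* The per-end signal model ignores label incorporation proportional to
  fragment length; percent-lost values are therefore comparable within the
  model, not calibrated to densitometry.
* Junction-state inference from real intervals sees only exact abutment;
  sequencing-end artifacts (soft-clipping, untrimmed adapters) would
  misclassify junctions and are assumed resolved upstream.
* The TF-barrier model pins termini to a fixed edge offset; real barrier
  footprints vary by factor and site.
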