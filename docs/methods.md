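# Methods

This note records the models behind each `cisreg` module, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Coordinates, variants and descriptive statistics

Genomic positions written as "g." coordinates are treated as GRCh37-style
1-based fully inclusive; BED/BEDPE input is 0-based half-open.  Both
conventions live on the interval object and convert bijectively, so the
length of a region is convention-independent (a 1-based inclusive region
spans `end − start + 1` bp; the 397 bp amplicon chr10:71,108,536-71,108,932
is the standing example).

`minimal_overlap` returns a distinguished empty value (`None`) instead of
raising on disjoint inputs, because "the deletions share no region" is an
analysis result, not an error.  `variant_span` covers the first through
last *affected* reference base of every variant: VCF padding bases are
stripped, so a padded deletion `pos=119 GACT>G` affects bases 120–122 and a
pure insertion is anchored at the base left of its junction.  Duplicate
(chrom, pos, ref, alt, sample) records are collapsed on entry to the
variant table, so recurrence counts (distinct variants, probands per
variant, substitutions and carriers per position) cannot double-count
multi-file input.

Quartiles use linear interpolation between order statistics (the most
common convention; nothing in the source analyses pins one down), whiskers
extend to the furthest data point within 1.5×IQR of the box, and printed
percentages round half-away-from-zero (374/46,885 → 0.8%).

## Motif disruption scoring

A PWM is stored as per-position base probabilities after adding a total
pseudocount of 0.8 per column distributed proportionally to the background
(the MEME-style convention).  Scores are natural-log likelihood ratios
against a single-nucleotide background; probabilities are floored at 1e-10
before the log so an impossible base is heavily penalised but never −∞.
Each PWM's `max_score` (the argmax path) must be positive — a PWM with no
information over the background is rejected at load time because its
normalised scores would be meaningless.

Both strands are scanned; a reverse-strand hit is the score of the reverse
complement of a forward window and must still span the variant locus in
forward coordinates.  The locus is: the substituted bases for an SNV/MNV;
the deleted bases (reference) or the retained-flank junction, both flanks
required (mutated sequence) for a deletion; the inserted bases plus both
junction bases for an insertion.  Ties break to the smaller start offset,
then the + strand.

Tier assignment uses the **reference-sequence** normalised score: a
candidate binding site has to exist before the variant can disrupt it.
Tier 1 is ≥ 0.6 and Tier 2 is [0.45, 0.6); variants that only *create*
sites appear with tier `none` and negative disruption.  Within a tier,
records of the same family with overlapping reference alignments collapse
to one family entry carrying the maximum member disruption; the family
map strips one trailing digit run and an exposed hyphen (NKX2-2 → NKX2,
HIC2 → HIC) and pools all FOX factors.  Note this map is deliberately a
single-pass rule: applying it twice would turn NKX2 into NKX, so family
names are not fixed points of the map and it is applied exactly once, to
gene symbols.

## Read-pair structural-variant calling

The insert-size model is the median and robust sigma (1.4826×MAD) of
proper-orientation intrachromosomal pairs (≥ 100 required), with
concordance bounds median ± 4σ.  Classification order: interchromosomal,
then same-strand (inversion signal), then insert size against the bounds.
Pairs with identical aligning coordinates collapse to one (PCR/optical
duplicates) before calling, and only reads with mapping quality > 30 are
used.

Clusters are single-linkage on the left-anchor coordinate (sorted first,
so calls are invariant to input record order) with a 1 kb linkage window;
interchromosomal clusters split further on the partner-chromosome anchor
and on pair orientation, which keeps the two junctions of a reciprocal
translocation apart.  Calls require ≥ 3 supporting pairs and ≥ 1 kb size:

* deletion — size is the mean insert excess over the library median;
  breakpoints are the innermost uncovered span (max left-read end + 1,
  min right-read start − 1),
* inversion — the left breakpoint from +/+ pairs (max left end + 1), the
  right from −/− pairs (min right start − 1),
* translocation — one anchor per chromosome, direction-aware (reads on a
  `+` anchor approach the junction from the left),
* insertion — novel sequence can only be sized up to the insert-size
  scale, so the size is the insert deficit, flagged as a lower bound.
  A ≥ 1 kb novel insertion exceeds the ~400 bp fragment span entirely:
  no flanking pair sees both sides, and pair-only evidence cannot call
  it.  The recovery benchmarks therefore cover deletions, inversions and
  translocations; sub-insert-scale insertions are exercised in unit tests
  with a lowered size floor.

Refinement: a stack of ≥ 2 reads clipped at the same reference base
within the breakpoint confidence interval (2σ/√support) snaps the
breakpoint there (most-supported stack wins, then leftmost); the
depth-discontinuity flag is set when interior depth differs from the
flanking mean by ≥ 25% (a heterozygous deletion halves interior depth).
With neither signal the call keeps its pair-derived breakpoints and is
flagged ambiguous — the behaviour appropriate for deletions between
matching repeats, where the junction produces neither clips nor a depth
step at the reported boundary.

## Contact-matrix balancing and loop strength

Balancing finds positive weights w so that diag(w)·M·diag(w) has equal
row sums over unmasked bins (zero-marginal bins are masked and excluded).
The implementation iterates the symmetric fixed point
`w ← w / sqrt(rowsum ratio)` until the maximum relative deviation of row
sums from their mean is below 1e-8 (1000-iteration cap; non-convergence
raises with the residual).  Row sums are normalised to their *mean* —
the overall scale of a balanced matrix is arbitrary, and fixing it makes
strengths comparable across runs.

Loop strength extends each BEDPE anchor's covering bin range by two bins
on each side (at the default 5 kb resolution) and averages the balanced
entries of the anchor1×anchor2 block.  Masked bins are excluded from both
numerator and denominator rather than zero-filled; zero-filling would bias
strengths downward next to sparse or unmappable regions.  A fully masked
block yields NaN.  Percentile rank is inclusive
(`100·#{s ≤ v}/N`, rounded to the nearest integer), so the strongest loop
is always the 100th percentile and a singleton list ranks itself 100.

## Expression trends

Counts are depth-normalised per cell (divide by the cell total, rescale
by the median cell total so values stay count-like).  The
variance-stabilising transform is `t = ln(α·y + β)` with α = 100, β = 1,
chosen so t(0) = 0 and the inverse `(e^t − β)/α` is exact.  A GP with
kernel `amplitude × Matern(ν=5/2) + white noise` is fitted to t against
pseudotime by marginal-likelihood maximisation (3 seeded restarts;
noise variance bounded below at 1e-6; length scale bounded to
[span/100, 10·span]).  The posterior mean ± 1.96·sd band on the
transformed scale maps through the monotone inverse; because the inverse
is monotone, the transformed-scale mean maps to the *median* of the
implied posterior on the count scale, which is what is reported.  The
inverted lower band clamps at 0 (counts cannot be negative).

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of a scenario (seed plus parameters);
RNG streams derive from (seed, stage id), so adding a stage never shifts
another stage's draws, and identical scenarios give byte-identical files.

* **Motif stage** — i.i.d. background DNA at stated base frequencies with
  one consensus site planted per case (random interior position, random
  strand) from a built-in set of 12 synthetic PFMs named for beta-cell
  transcription factors (17-of-20 consensus counts per column).  The
  ablating SNV sits at the motif's most informative column and changes
  the consensus base to the least likely base.  Not emulated: dinucleotide
  structure, conservation, overlapping real motifs, indel disruptions.
* **SV stage** — fragments sampled uniformly per haplotype at 30×
  sequence coverage with Normal(400, 50) fragment lengths and 100 bp
  reads, mapped back through a donor-to-reference segment map.  This
  reproduces the real signatures mechanically: inflated/deflated inserts,
  same-strand and interchromosomal pairs, soft-clips at junctions (a read
  maps to whichever side holds its majority), unmapped mates inside novel
  insertions, and halved interior depth for heterozygous deletions.  Not
  emulated: sequencing errors, mapping ambiguity and repeats, GC coverage
  bias, chimeric artefacts — so the benchmarked recovery rates are upper
  bounds on real-data performance.
* **Hi-C stage** — expected counts `c/(1+|i−j|)^γ` (γ = 1) times an
  outer product of per-bin biases uniform in [0.5, 2], Poisson sampled on
  the upper triangle and mirrored.  A planted loop multiplies a
  (2h+1)² block (default h = 2, matching the 5×5 extended-anchor
  measurement window at 5 kb) by the enrichment; distance-matched decoy
  anchor pairs with enrichment 1 provide the null.  Not emulated: TADs and
  compartments, fragment-level structure, translocated contacts.
* **Expression stage** — `y = f(t)·exp(N(0, σ))` with f a falling or
  rising sigmoid (plateau 5.0, floor 0.02, midpoint 0.5, steepness 12 on
  a [0,1] pseudotime axis) or a constant, σ = 0.3 by default.  This is
  the silenced-vs-induced gene pattern over differentiation.  Not
  emulated: zero inflation/dropout, cell-type mixture, pseudotime
  estimation error.

## Benchmark problem sizes

The standing benchmarks (`cisreg.benchmarks`, asserted in the test suite
and reported by `scripts/acceptance.py`) use: 24 planted-motif cases; 50
SV replicates of three events each (sizes 1.5–8 kb) over a 120 kb
three-chromosome genome, plus a 1 Mb SV-free genome for the false-call
rate; three 150-bin balanced matrices for the row-sum residual and one
600-bin matrix with 200 planted and 200 null loops at 3× enrichment; 50
GP replicates of 100 cells each.  These sizes give stable pass/fail
behaviour across seeds while a full run stays around one minute.

## Known limitations

* Insertions at or above the library insert size are invisible to
  pair-only evidence (flagged lower-bound sizes; see above).
* The balancing iteration assumes the matrix has support enough for a
  balanced scaling to exist; pathological block structures can exceed the
  iteration cap, which raises rather than returning a bad scaling.
* GP hyperparameters are point estimates; the 95% band does not account
  for hyperparameter uncertainty.  Coverage is validated empirically on
  the generator's noise model.
* The motif family rule is a surface operation on gene symbols; it does
  not consult a curated TF-family ontology.
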