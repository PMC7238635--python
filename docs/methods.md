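# Methods

`mapweaver` reconciles two independent long-read contig assemblies of the
same genome around consensus optical maps, producing gapless (or nearly
gapless) pseudomolecules, and annotates the tandem-repeat landscape of the
result — knobs, CentC arrays, CENH3 centromeres — with rule-based callers.
This note describes the models, the parameters that matter, the numerical
choices, and what the bundled simulator does and does not emulate.

## The anchoring model: label maps and their alignment

A *label map* is the ordered list of positions at which a labelling motif
(default `CTTAAG`, the DLE-1 recognition site; it is its own reverse
complement, so one strand scan suffices) occurs on a molecule or contig.
Contigs enter the pipeline as in-silico digests; optical consensus maps
carry the same label pattern with three error processes: interval sizing
error with standard deviation `sizing_sd_coeff * sqrt(interval bp)`
(default coefficient 3.0 bp^0.5), missed labels, and false labels.
Occurrences closer than `min_label_spacing` (default 800 bp, the optical
resolution limit) collapse to their midpoint.

Alignment is a local dynamic programme over monotone label pairings.  Each
matched pair earns a fixed bonus (5.0); each transition between consecutive
pairs pays the squared sizing z-score `delta^2 / (coeff^2 * mean_interval)`
plus `miss_penalty` (3.0) per skipped label on either side.  Both
orientations are tried; consecutive skips are limited to `band_labels`
(default 6) per side for speed — with the band at least the map size the
DP searches the full pairing space and is exact against enumeration.
Confidence is `score / ln 10` (decibans), so a perfect 10-pair alignment
scores ~21.7; the default reporting floor is confidence 20 with at least 8
pairs, which suppresses the short chance chains that a local DP over a
large label matrix inevitably contains.  Because the DP may restart rather
than carry a deficit, an alignment whose total score does not exceed one
isolated matched pair's bonus is not representable — nor reportable: the
floor sits above that regime by construction.

Rescaling fits one least-squares stretch factor per map (regression of
matched intervals through the origin, median over contigs) once per run;
more rounds are configurable but one suffices at this noise level.

## The five-stage merging procedure

1. **Conflict cutting.**  A chimeric join shows up as an alignment that
   terminates mid-contig with at least `min_overhang_labels` unaligned
   labels *and* `min_overhang_bp` unaligned sequence on both the contig and
   the map beyond the terminus (desk-scale defaults 4 labels / 12 kb; the
   full-scale convention is 5 / 50 kb).  Junction support is the fraction
   of window-spanning maps (+/-3 labels) that align contiguously through
   the junction; support below 35 cuts the *sequence* at the terminal
   paired label — the maps are the anchor and are never cut.  Junctions
   within 10 kb deduplicate (the same break seen from replicate maps or
   from both partner chromosomes' maps).  A note on direction: the
   convention here is that low support means chimeric and triggers the
   cut; descriptions that phrase the rule as a score *above* a threshold
   refer to a chimera score that is high for chimeric junctions — the two
   are the same rule with opposite polarity, and this package documents
   its own polarity explicitly.

2. **Error curation.**  Discrepancies between the primary assembly and the
   rescaled maps are step changes in the cumulative contig-minus-map drift
   along an alignment.  Windows of up to 8 transitions are scanned and the
   window maximising the step's margin over a noise floor is emitted; the
   floor is `max(1000 bp, 4 * sizing_sd * sqrt(window span))`, so the
   stated 1-kb rule binds for well-resolved loci while long label-free
   intervals (satellite arrays) require proportionally larger steps.  The
   windowed scan matters because the aligner smears a collapse across
   skipped labels rather than concentrating it in one transition.
   Confidence is the mean flanking-transition match score scaled to [0,1]
   (floor 0.1).  Zygosity is adjudicated across maps: a call echoed by all
   (at least two) covering maps is homozygous; disagreement is
   heterozygous; a single covering map leaves it unknown.  Only homozygous
   calls are patched, and only when an alternate-assembly contig covers
   the same label interval with no discrepancy of its own (same
   noise-aware floors).  Patch boundaries snap to matched labels and then
   to the nearest exact shared 20-mer within 500 bp, avoiding junction
   artifacts.  Overlapping calls from different maps are merged by contig
   interval overlap, since step boundaries jitter by a few label intervals
   between replicate maps.

3. **Contig merging.**  Overlaps between the two assemblies are found by
   exact shared k-mers (k = 21) sampled with a hash-mod rule (a k-mer is
   kept when its hash is 0 mod 4) — unlike fixed-stride sampling this is
   insensitive to each contig's coordinate frame.  Anchors are restricted
   to the dominant diagonal and made co-monotone; identity is the
   chained-anchor coverage of the overlap span, which is ~1 for identical
   sequence, ~0.99 at polished-assembly error rates, and collapses for
   diverged repeats — a deliberately conservative estimator that assumes
   polished inputs.  Desk-scale defaults are min_overlap 5 kb, identity
   0.9, max_overhang 2.5 kb; the full-scale preset mirrors the 25-kb
   overlap floor and ~250-kb overhang allowance used for gigabase inputs.
   Dovetails form an overlap graph; maximal unbranched paths merge into
   unitigs spliced at exact shared-anchor k-mers, keeping primary-assembly
   bases across each overlap (the backbone-plus-patcher donor policy).
   Branching ends merge nothing; contained contigs are absorbed; cycles
   are reported and left unmerged.  Unitig orientation is canonicalised by
   terminal contig id, so the result is independent of input order.
   Map-guided adjacency separately flags placement overlaps above a
   detectability floor (~200 kb full scale) for immediate merging.

4. **Hybrid scaffolding.**  Contigs are placed on maps by their best
   alignments, with the ref span extended by unaligned contig tails.  A
   contig with two equal-scoring placements at distinct loci *on one map*
   is ambiguous and goes to the leftover set rather than being placed
   arbitrarily.  Maps are chosen greedily by newly-anchored span, so
   replicate maps of one chromosome cannot split it across scaffolds.
   Positive inter-contig gaps become N runs of the map-estimated size
   (minimum 100); junctions whose placements overlap get exactly 13 Ns —
   the conventional mark of an identified-but-unmerged overlap — and are
   revisited by sequence-level merging; junctions configured unmergeable
   (the rDNA/NOR analogue) keep their 13 Ns.  Scaffold length equals the
   sum of placed contig lengths plus gap sizes, checked on every run.

5. **Finishing.**  Gap filling runs up to three iterations.  Reads anchor
   by globally unique shared k-mers (hash-mod sampled, modulus 32; a
   read's anchors must form a single diagonal cluster).  A read anchored
   to both flanks of a gap (>= 250 estimated matched bp per flank) closes
   it when its implied span is within a factor 2 of the estimate; reads
   anchored to one flank shrink the gap by at most 5 kb per iteration and
   never close it — at least 13 Ns remain without a spanning read.
   Telomere extension takes, per scaffold end, the longest uniquely
   anchored read whose outer end carries a tandem `TTTAGGG`/`CCCTAAA`
   tract of at least 1 kb at >= 90% unit identity (C-rich strand at 5'
   ends); tract length counts the *matching* bases inside the qualifying
   terminal window, so random flanking sequence cannot inflate a 0.9-kb
   tract past the floor.  Markers are filtered (unique, mapq > 30, more
   than 20 per scaffold, capped at 100 evenly spaced); scaffolds are
   ordered and oriented per linkage group by maximising the weighted
   |Spearman| concordance between genetic and physical marker order —
   exhaustively for groups of up to 8 scaffolds (a sum-of-squared-rank
   decomposition makes all orders x orientations affordable), greedy
   insertion with 2-opt and single-flip passes beyond that, and the
   arrangement's global direction canonicalised so signed concordance is
   non-negative.  Pseudomolecules join scaffolds with 100 Ns (a common
   convention; configurable) and the AGP reconstructs the FASTA exactly.

Bookkeeping invariants hold exactly and are asserted in the tests: cutting,
merging and scaffolding neither create nor destroy non-N bases (merged
overlap spans are itemised), and patches, fills and telomere extensions
itemise every added or removed base.  Every output is byte-reproducible
from (config, seed).

## Annotation

* **Monomer scanning** is seed-and-extend: exact 12-mers of the consensus
  locate candidate regions; within each, the consensus is tiled greedily
  by banded infix alignment (edlib), accepting units at >= 0.7 identity —
  a floor reflecting satellite divergence.  When the tiling window's best
  copy is the next unit over, the skipped prefix gets its own alignment
  before the scan jumps, which keeps unit counts honest at high
  divergence.
* **Array calling** single-links hit blocks with gaps <= 100 kb and keeps
  clusters with span >= 500 kb (knobs; knob180 + TR-1) or >= 100 kb
  (CentC) at >= 10% consensus density; knob calls inside configured
  subtelomeric windows (default: the outermost 200 kb of each chromosome
  end) are dropped.  All thresholds are sharp to the base pair.
* **Effective genome size** is the fraction of unique canonical
  (strand-folded) 150-mers, computed by 128-bit rolling hashes; it matches
  an explicit dictionary count exactly.
* **CENH3 island calling**: per 5-kb bin, a Poisson upper-tail -log10 p of
  the ChIP signal against an input-scaled background with a floor of the
  genome-average rate divided by the effective genome fraction; bins with
  p < 0.01 merge across at most `gap_size` (default 0) quiet bins; an
  island's score is its summed bin scores (capped at 1e6 per bin) and it
  is kept when score > 250 and depth-normalised ChIP/input fold change
  > 4.  Absolute scores depend on this construction; the 250 default is
  retained as the conventional cutoff for broad-domain callers of this
  family.
* **Mappability** (<= 2 or >= 101 reads is non-unique, merged within
  1 kb), **low-coverage regions** (< 3 reads for accurate data, < 2 for
  long-noisy), and **RPKM enrichment ratios** (exactly depth-normalised;
  zero-input features report absent, never infinity) follow the standard
  definitions.
* **Fisher co-occurrence** expands one interval set by a 500-kb flank,
  tabulates genome bp into a 2x2 table, and computes the two-sided p
  exactly (integer-binomial tail summation for tables up to N = 2000;
  scipy's implementation beyond).  The sample odds ratio `ad/bc` is
  reported, `None`/infinite when a zero cell makes it undefined or
  unbounded.

## The simulator: what it emulates and what it does not

The default configuration builds three 5-Mb chromosomes with telomere
tracts (C-rich strand at 5' ends), subtelomeric blocks, one CentC
centromere array per chromosome, knob180 and TR-1 knobs, and labelled
retroelement-like insertions interrupting every array — so composition
statistics have exact truth.  Array spans are scaled ~100x down from their
real megabase counterparts (an 850-kb knob becomes 8.5–100 kb); monomer
lengths are real (CentC 156 bp, knob180 180 bp, TR-1 ~360 bp, the bundled
TR-1 consensus verbatim, telomere 7 bp); retroelement insertions keep
their real ~5-kb sizes, so the cluster-spacing threshold is not scaled
below them.  Synthetic monomers and TE blocks are deterministic labelled
sequences, not real repeat libraries, and are generated free of the
labelling motif (satellite arrays are label-poor in practice).

The accurate-short profile breaks contigs inside arrays longer than 15 kb
(losing the interior beyond a 5-kb kept edge), collapses the designated
CentC array by half, plants two chimeric joins between repeat-adjacent
loci on different chromosomes, breaks at the heterozygous region, and
carries 1e-4 substitutions.  The long-noisy profile breaks only above
40 kb, keeps arrays intact, and carries 5e-4 substitutions plus 2e-4
indels — post-polishing error rates, consistent with assemblies that have
been consensus-polished before merging; the overlap-identity estimator
assumes this.  One knob (100 kb) exceeds both thresholds, so its
chromosome must retain a gap: the interior is longer than any read (reads
are real-length, log-normal with N50 anchored at 22.3 kb / 29.3 kb and
capped at 60 kb), and the per-iteration extension cap keeps iterative
flank extension from walking across it.  Maps come in two replicates per
chromosome (so zygosity adjudication and junction support have independent
evidence), with sizing noise, 5% missed and 0.5/100 kb false labels.
ChIP coverage is uniform Poisson input with an 8-fold rate multiplier
inside CENH3 domains (the CentC array +/- 10 kb); markers are
monotone-plus-Gaussian with configured non-unique and low-mapq fractions,
split between two equally weighted sources.

Not emulated: polymerase/pore-specific error profiles, optical-map
assembly from raw molecules, haplotype-aware map phasing, recombination
beyond monotone-plus-noise markers, and real transposon sequence.  Passing
tests therefore demonstrate the pipeline's logic — conflict geometry,
drift detection, overlap-graph merging, threshold behaviour, bookkeeping —
under controlled error processes, not performance on any particular real
dataset; at full scale the thresholds revert to the documented real-data
values and the aligner's stand-in role would be played by a production
map aligner.

## Problem sizes and determinism

The default bundle (3 x 5 Mb, ~16x combined read depth, 6 maps) runs end
to end in about two minutes on one CPU; the test suite additionally runs
it at three seeds, and unit tests use a 3 x 1.5 Mb miniature with the same
threshold topology.  All randomness flows from a single integer seed
through named child streams (`numpy.random.default_rng([seed, salt, ...])`),
so every artifact is byte-reproducible.  Degenerate inputs are handled
explicitly: empty label maps are valid, maps with too few labels yield no
alignments rather than errors, zero-depth input tracks and empty marker
groups raise, and ties in placement scoring leave contigs unplaced rather
than placed arbitrarily.
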