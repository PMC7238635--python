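# mapweaver

Merging two independent long-read assemblies into gapless chromosomes
around an optical map, with rule-based annotation of the tandem-repeat
landscape that makes such genomes hard in the first place.

## The problem

The hardest regions of complex plant genomes are megabase-scale tandem
repeat arrays — centromeric satellites (CentC, 156-bp monomer), knob
repeats (knob180, 180 bp; TR-1, ~360 bp), rDNA — that exceed any read
length.  Two assemblies of the same genome fail in *different* places: an
accurate-short-read-profile assembly breaks inside long arrays and
collapses tandem repeats, while a longer-noisier-profile assembly walks
through many of them.  A consensus optical map (ordered fluorescent labels
at a motif's genomic positions, default `CTTAAG`) sees across all of them
and is the neutral anchor that lets the two assemblies repair each other.

`mapweaver` implements that reconciliation as a five-stage pipeline:

1. **conflict cutting** — chimeric contigs show up as map-versus-sequence
   alignment conflicts; unsupported junctions are cut (the sequence, never
   the map);
2. **error curation** — homozygous insertion/deletion discrepancies
   (> 1 kb, confidence >= 0.1) between the primary assembly and rescaled
   maps are patched from the alternate assembly where it is concordant;
3. **contig merging** — dovetail overlaps between the assemblies merge
   into unitigs along unbranched overlap-graph paths;
4. **hybrid scaffolding** — contigs are ordered and oriented along the
   maps; positive gaps get map-estimated N runs, overlapping placements
   get exactly 13 Ns and are resolved by sequence-level merging;
5. **finishing** — iterative read-based gap filling, telomere extension
   with `TTTAGGG`/`CCCTAAA`-tract reads (>= 1 kb), and pseudomolecule
   construction from genetic markers (unique, mapq > 30, > 20 per
   scaffold, capped at 100) by maximising weighted |Spearman| rank
   concordance between genetic and physical order.

The annotation layer provides the field's standard rule-based callers:
knobs (clusters >= 500 kb at >= 10% knob180/TR-1 density, <= 100 kb unit
spacing, subtelomeric arrays excluded), CentC arrays (>= 100 kb), the
effective genome size as the unique-150-mer fraction, CENH3 centromeres as
broad ChIP enrichment islands (5-kb bins, score > 250, fold change > 4),
mappability and low-coverage islands, RPKM enrichment ratios, and exact
two-sided Fisher co-occurrence of interval sets.

Everything is validated end to end on a bundled simulator that builds a
truth-annotated repeat-rich genome (desk scale: 3 x 5 Mb, array spans
scaled ~100x down) and derives both assemblies with planted chimeras,
collapses and breaks, noisy optical maps, reads, ChIP tracks and markers.

## A worked example

```bash
python examples/01_merge_two_assemblies.py
```

builds the default synthetic bundle at seed 1 and runs the whole pipeline.
It prints:

```
genome: 3 chromosomes, 15.0 Mb
assembly A: 15 contigs; assembly B: 16
planted events:
profile contig_id    event  pos_contig chrom  pos_chrom  size
     pb    pb_001  chimera      505000  chrA    1205000     0
     pb    pb_002  chimera      705000  chrB    1505000     0
     pb    pb_005 collapse      503000  chrA    2503000  6000

conflicts cut: 8 (the two planted chimeras, seen from both chromosomes' maps)
collapses patched: 1 (+6002 bp restored from the alternate assembly)
unitigs merged: 4; 13N junctions resolved: 0
gap filling: 0 closed, 3 shrunk; telomere ends extended: 2

pseudomolecules (residual N gaps > 10 bp in brackets):
  chrA: 4.996 Mb, gaps []
  chrB: 4.998 Mb, gaps []
  chrC: 4.997 Mb, gaps [59248]
```

Reading: the two planted chimeric contigs were each cut at the junction
(once per partner chromosome's map, hence 8 conflict cuts for 4 junction
sides), the planted 6-kb CentC collapse was restored from the alternate
assembly, and the two chromosomes whose arrays fit inside the long-read
profile's reach assembled gaplessly telomere to telomere.  `chrC` carries
a 100-kb knob that exceeds both assembly profiles *and* the read length,
so it correctly retains one N gap, shrunk from ~89 kb to ~59 kb by
flank-anchored read extension but honestly never closed.

The other examples exercise single capabilities: `02` label-map alignment
and rescaling, `03` satellite-array annotation, `04` CENH3 island calling.

The same pipeline is available as a shell tool:

```bash
mapweaver simulate --seed 1 --outdir bundle/
mapweaver run-all --bundle bundle/ --outdir run/ --seed 1
mapweaver annotate run/final.fasta --outdir ann/ \
    --knob-span 5000 --centc-span 1000 --max-spacing 10000
```

with per-step subcommands (`digest`, `align`, `cut-conflicts`,
`fix-errors`, `merge`, `scaffold`, `resolve-overlaps`, `gap-fill`,
`telomere`, `pseudo`, `fisher`, `liftover`, `metrics`, `validate`) for
running stages individually; every threshold is a named key in an optional
YAML config.

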