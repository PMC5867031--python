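# Methods

## Scope and model

`famedit` genotypes CRISPR/Cas9 editing of a multicopy gene family from
deep paired-end amplicon sequencing.  The concrete system is the wheat
α-gliadin family: several dozen paralogs and pseudogenes, all cut by a
guide (sgAlpha-2 by default, `GGTTGTGATGGAAATGGTTG` + NGG) directed at a
region conserved across the family, each copy repairing independently by
NHEJ.  The analysis model is deliberately simple and transparent:

* a **variant** is an exact merged-read sequence (100%-identity
  dereplication; no denoising, no OTU radius, no chimera removal);
* a variant is **real** when it has ≥ `min_reads` (5) reads in a sample
  and a frequency `n/N` strictly above `min_frequency` (0.3%);
* a mutant variant descends from the wild-type reference gene with the
  best global affine alignment score; an indel within ± `cut_window`
  (20 bp) of the blunt cut (3 bp 5′ of the PAM — the SpCas9 convention)
  makes it a **mutant read**;
* per-sample `NHEJ% = 100 × mutant reads / assigned reads` (variants
  below the identity floor are excluded from the denominator and
  counted separately as unassigned).

## Read QC

Mates are merged over the ungapped overlap (≥ `min_overlap` = 20 bp)
with the lowest mismatch *fraction*, ties going to the longer overlap.
Ranking by fraction rather than by matches-minus-mismatches matters in
this amplicon: the epitope region is an 81-nt tandem repeat, and a
repeat-shifted longer overlap otherwise outscores the true shorter one,
systematically collapsing three-repeat amplicons into two-repeat
chimeras.  Candidate overlaps are seeded from exact 16-mer anchors with
an exhaustive fallback, so the anchored search is equivalent to the full
scan (property-tested).  In the overlap, agreeing bases take
`max(Q1, Q2)` capped at `qmax` = 41 (the Phred+33 MiSeq ceiling);
disagreeing bases take the higher-quality base with quality `|Q1 − Q2|`.
A disagreement between two equal-quality bases therefore carries Q0
(error probability 1), which is what pushes reads with overlap conflicts
over the expected-error threshold.

Expected errors `E = Σ 10^(−Q/10)` are computed per merged read; reads
are retained iff `E ≤ max_ee` = 1 (inclusive, the usual maxEE
semantics).  Adapter/primer trimming and gapped overlap merging are out
of scope; indel sequencing errors are off by default in the simulator,
so ungapped merging is exact.

## Clustering and frequencies

Dereplication is a hash on the exact sequence with per-sample counts.
Cluster order is deterministic (total count descending, then sequence),
so all downstream ids and reports are reproducible.  `N` is recomputed
after the `min_reads` filter (filter-then-normalise; the alternative
order changes frequencies by < the filter mass and both totals are in
the QC table).  The representation threshold is strict (`> 0.3%`) and
applied per sample.

## Reference library

The amplicon is internal to the coding sequence, so translation frame 0
over the whole variant is the default (configurable).  A gene is a
pseudogene iff a stop codon occurs strictly before the final codon of
the translated span.  The three coeliac epitopes (DQ2.5-glia-α1a
`PFPQPELPY`, -α2 `PQPELPYPQ`, -α1b `PYPQPELPY`) are counted at every
start position, overlaps allowed.  Gene ids are `G{line}_{rank}` in the
deterministic cluster order, for stable joins across report tables.

## Assignment and indel calling

Every reference is scored with a global (Needleman–Wunsch) affine-gap
alignment: match +2, mismatch −3, gap open −10, gap extend −0.5
(biopython `PairwiseAligner`).  These weights make one long indel
(penalty `10 + 0.5·L`, ~73 for the largest observed deletion) far
cheaper than the ~17 paralog SNP differences at 2% divergence (swing
~85), so the true parent wins against every closer-scoring paralog for
pure-deletion alleles — a property verified over 1,000 simulated edited
alleles.  Ties break to the lowest gene id and are flagged.  An
edit-distance prescreen (edlib) is available but off by default: unit
costs charge a long gap per base, so it can rank the true parent of a
large-deletion allele below wrong paralogs and prune it.

Known limitation: an insertion copied from *another family member* can
be genuinely ambiguous.  The epitope repeat region is near-identical
across paralogs, so a family-origin insert of roughly the repeat length
(81 nt) turns an r-repeat allele into a faithful (r+1)-repeat chimera
that aligns best to a different gene.  No global-score assignment can
resolve this; the validation scenarios therefore use vector-origin
insertions (random with respect to the family, identifiable by a ~190
score-point margin), and family-origin classification is tested on the
truth table directly.

Gap runs in the winning alignment become indel calls with 0-based
half-open, left-aligned (5′-most) coordinates, normalised independently
per event without crossing the previous event.  A variant with more
than one proximal event is treated as complex and counted once toward
NHEJ%.  Insertions ≥ 10 bp are classified by exact substring search
(both strands) against the transformation vector(s), then against the
other family genes, else unknown; vector takes precedence.

## Microhomology

All maximal direct-repeat pairs with length in [3, 36] and both copies
starting within `search_radius` = 200 bp of the cut are enumerated; a
pair `(left_start, right_start, L)` predicts an MMEJ deletion of
`right_start − left_start` bp that removes one repeat copy.  Maximality
(the pair cannot be extended on either side) gives each physical repeat
one canonical record and makes the pair interval its own left-aligned
deletion placement, so attribution reduces to exact interval equality
with a left-aligned deletion call (a size tolerance with interval
overlap is available).  Only pairs whose implied deletion can span the
break (`left_start ≤ cut ≤ right_start + L`) are reported by default.
The implementation is checked against an independent brute-force
substring-pair enumeration on random sequences.  Thermodynamic MMEJ
scoring is out of scope.

## Off-target scan

A site is the guide's 12-nt PAM-proximal seed immediately 5′ of NGG.
The scanner reports every position on both strands with at most
`max_mismatches` (default 2) seed mismatches and an exact GG at PAM
positions 2–3 (position 1 free); genome mode is the 0-mismatch special
case.  Ambiguity codes never match (conservative); overlapping sites
are all reported, since the target locus itself is highly repetitive.
The vectorised scan is checked against an independent per-position
oracle on 100 kb of random sequence at 0–2 mismatches.

## Synthetic data generator

The generator emulates what the study's (non-deposited) reads must have
looked like; it is the ground truth for every validation.

* **Family.**  One ancestral backbone (270 nt of random sense codons,
  no internal stops) carries the protospacer+PAM at a fixed codon-
  aligned position (cut at position 146).  The epitope region is a
  tandem repeat of the 81-nt coding of the three concatenated 9-mer
  epitopes, with the per-gene repeat number uniform on
  `epitope_repeat_range` (default 1–3), so paralogs fall into distinct
  length classes (351/432/513 bp) as in the real family.  Paralogs
  diverge by i.i.d. substitutions at `snp_rate` (default 2%); the
  protospacer+PAM is excluded by default (the guides were designed
  against conserved sequence), and substitutions that would create a
  stop codon are resampled — purifying selection, which also makes the
  pseudogene count exact.  Exactly `round(n_genes ×
  pseudogene_fraction)` genes receive an engineered premature stop in
  the 3′ flank.  Per-gene wild-type abundance is uniform (the real
  distribution is unknown; skew can be emulated through the allele
  pool).
* **Editing.**  Each gene contributes `alleles_per_gene` (default 4)
  allele copies — a plant's fixed gene complement.  Per targeted gene,
  `round(nhej_fraction × alleles_per_gene)` copies carry exactly one
  indel overlapping the cut (deterministic count, so a targeted gene is
  never silently missed; one edit per allele, no inversions).  Deletion
  sizes follow a weight table on [1, 126] (default exponential decay,
  scale 15 bp), with sizes predicted by a flanking microhomology pair
  up-weighted by `mmej_bias` (default 5) and such deletions placed at
  the predicting repeat; other deletions are placed uniformly among
  cut-overlapping positions.  Insertions (default 19% of edits) follow
  a weight table on [1, 158] (decay scale 30 bp) and are copied from
  the transformation vector, another family member, or random sequence
  per `insertion_origin_mix`.  The bundled default vector is a
  synthetic 3-kb random stand-in generated from a fixed seed.  Truth
  coordinates are left-aligned.
* **Reads.**  `depth` pairs are drawn uniformly over the allele pool;
  each 280-nt mate covers its end of the amplicon (shorter amplicons
  are read full-length), mate 2 reverse-complemented.  Errors are
  substitution-only at the rate implied by the uniform Phred quality of
  the profile (Q30 default; 0/None = noiseless at Q40), so a noiseless
  unedited simulation round-trips exactly.  What this does *not*
  emulate: PCR amplification bias, chimera formation, indel sequencing
  errors, position-dependent quality decay.  Passing tests show the
  analysis is correct under its stated error model, not that it is
  robust to artefacts outside it.

Alleles whose amplicon exceeds `2 × read_length − min_overlap` (540 bp;
large insertions on the longest genes) produce unmergeable pairs and
are lost — as they would be on a real 2×280 run.  Shorter amplicons
have larger mate overlaps and hence higher expected-error rejection
(a Q30/Q30 disagreement carries Q0), so mutant reads are filtered
slightly more often than wild-type reads; the recovered NHEJ% sits
~0.5–1.3 points below the read-level truth at the standard conditions,
well within the ±2-point recovery target.

## Validation conditions and problem sizes

* **Recovery** (`scenarios.recovery_scenario`): 45 genes, 2% SNPs, 40%
  pseudogenes, 35 genes edited at `nhej_fraction` 0.75, Q30, 50k reads
  per sample (~278 reads/allele, comfortably above the representation
  threshold).  Checked: NHEJ% within ±2 points of read-level truth,
  mutated gene count 35, pseudogene count 18, library size 45.
* **Null** (`null_scenario`): same family, nothing edited, Q30, 2k
  reads/sample.  Checked: NHEJ exactly 0, all 45 variants recovered.
* **Spectrum** (`spectrum_scenario`): every allele of a 45×24 pool gets
  a deletion (unbiased weights, `mmej_bias` 1), noiseless, 50k reads,
  representation threshold lowered to 0.05% because each of the ~1,080
  distinct alleles holds only ~0.1% of reads.  The read-weighted size
  histogram is rescaled to allele equivalents (reads per allele) and
  compared to the weight table by a chi-square test with tail bins
  pooled to expected ≥ 5; read-multinomial noise inflates the statistic
  by a factor ≈ 1 + alleles/depth (~2%), which is negligible at these
  sizes.
* **Oracles**: off-target scan vs per-position rescan (100 kb × 20
  seeds × 0–2 mismatches); microhomology vs brute-force pair
  enumeration (200 × 300 bp); indel left-alignment vs exhaustive
  placement enumeration (100 repeat constructs).

These sizes keep the full suite and the acceptance script to a few
minutes on a single core while leaving the statistical checks
well-powered.

## Numerical and degenerate-input choices

* Inclusive `E ≤ maxEE`; strict `frequency > min_frequency`; strict
  "less than 5 reads" removal (5 is retained).
* `n_genes = 0` is a valid empty family; `depth = 0` gives empty FASTQ;
  an empty sample after filtering is reported, not an error; an empty
  wild-type library is an error (nothing downstream is defined).
* A guide matching no family gene raises, naming the guide; genes
  missing the site in a mixed family are simply not targetable.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in the configs; every operation is bitwise reproducible, and the
  file-based pipeline writes byte-identical reports on rerun.
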