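# Methods

## Scope and data model

The package analyses single-embryo total-RNA libraries (polyA+ and
polyA− transcripts) across an ordered developmental series — by default
the nine pre-implantation stages oocyte, zygote, 2-cell, 4-cell, 8-cell,
morula, early blastocyst, blastocyst, hatched blastocyst. All genomic
intervals are 0-based half-open internally; GTF (1-based inclusive) is
converted at the I/O boundary only, so interval arithmetic never deals
with off-by-one cases and write→read round trips are identities.

Chimeric alignments arrive in a fixed TSV dialect (one row per read
pair: two segments on one chromosome plus an optional linear mate),
standing in for a fusion aligner's output, which is out of scope.
Forward-spliced (linear) junction evidence — in a real run derived from
the linear alignment pass — travels as a separate TSV of per-locus,
per-sample read counts that is joined onto called circles.

## Read cleaning

A read is discarded when more than 50 % of its bases have Phred
quality ≤ 5, or more than 10 % are undetermined; all thresholds are
strict inequalities. Surviving reads are trimmed: adaptor occurrences
(cut at the leftmost match), then one terminal run of ≥ 24 T at the 5′
end or ≥ 24 A at the 3′ end. A read whose remaining sequence is more
than 80 % A/T, or shorter than 30 nt (default; needed to avoid empty
reads), is then discarded. Trimming precedes the AT-content test — the
ordering is otherwise unconstrained and this choice maximizes retained
reads. The report satisfies exact conservation (input = output + the
three discard counters; short-after-trim reads are counted with the
AT-composition discards), and cleaning is idempotent.

## circRNA calling

A chimeric read supports junction (gene, exon *i* → exon *j*, *i* ≤ *j*
genomic) iff its upstream segment starts exactly at exon *i*'s annotated
start and its downstream segment ends exactly at exon *j*'s annotated
end (tolerance 0 nt by default; a `tol` parameter exists for noisy
simulations), both exons belong to the *same* gene, and the segments
appear in reversed genomic order in the read. If the mate exists it must
be linear, on the same chromosome, and inside `[acceptor, donor]`. A
read may support at most one junction; multi-junction matches (possible
at `tol` > 0) are dropped and tallied. Support is counted as *distinct
read pairs* (deduplicated by read id) and a circle is reported per
sample only at ≥ 2 pairs.

The canonical key of a circle is (chrom, min coordinate, max coordinate,
strand); donor/acceptor are interpreted in transcript orientation, so on
the minus strand the genomic-rightmost exon of the circle is the
transcript-upstream acceptor. Position classes: `first_exon` /
`last_exon` when the circle touches the annotated transcript-first/last
exon, else `internal`; evidence of an unannotated upstream exon
(mean read depth > 1 in a 1-kb window upstream of the annotated first
exon) is flagged separately, since it can demote an apparent first-exon
circle.

Forward-spliced reads are counted at both junction loci of a circle and
averaged (rounded half-up); the aggregation rule is a symmetry choice —
the two loci of one circle are interchangeable.

## Junction statistics

circ ratio = back/(back + forward); CLR = back/forward =
ratio/(1 − ratio). Both are undefined with no reads at all; CLR is
flagged infinite when circular reads exist without linear support.
Discounted expression of a hosting gene is RPKM × (1 − circ ratio).

## Absolute quantification

RPKM = count / (length/10³) / (mapped reads/10⁶). Per sample:

1. **ERCC-based total.** OLS of log10 RPKM on log10 attomole over ERCC
   species with amount > 0.001 attomole and RPKM > 0 (≥ 3 required). The
   line is solved for attomole at every gene's RPKM (zero-RPKM genes
   contribute zero), summed, and scaled by 6.02214×10⁵ molecules per
   attomole.
2. **RGC-based total.** Mean over detected RGC species of
   (total gene RPKM / species RPKM) × spiked molecules.
3. **Combined.** Across samples, OLS of log10(RGC-based) on
   log10(ERCC-based); a sample's final total is its fitted value,
   back-transformed. The direction (RGC on ERCC, evaluate at the ERCC
   value) treats the polyA-matched RGC estimate as the accurate scale
   and the ERCC estimate as the stable per-sample covariate — the
   ERCC-side regression pools 90+ species and is much less noisy per
   sample than the 3-species RGC mean, so fitting smooths the RGC noise
   while the systematic ERCC capture bias is absorbed by the intercept.

circRNA RPKM uses the effective junction span (read length − 25) × 2 as
the length term — a junction read must keep a 25-nt anchor on one side
of the back-splice, so it can start up to (read length − 25) nt away in
each direction. circRNA copies = (Σ circle RPKM / Σ gene RPKM) × mRNA
copies.

Spike-in QC retains ERCC species with RPKM ≥ 1 in at least three
samples and reports the pairwise sample Pearson matrix; nothing retained
is a failure report, not an exception. Depth subsampling draws each
sample column from a multivariate hypergeometric distribution, so totals
hit the target exactly and draws are seed-reproducible.

## Differential expression and classification

Size factors are depth / mRNA copies, rescaled to geometric mean 1;
dividing counts by them puts samples on a per-transcript-copy scale,
which matters across the maternal-to-zygotic transition where total mRNA
content swings ~10-fold. Genes enter testing when normalized RPKM ≥ 1 in
at least one sample.

The test is a negative-binomial Wald test on the log2 ratio of
normalized group means. Dispersion is method of moments with two
stabilizing choices: the per-gene estimator uses
(var − mean·E[1/f]) / (mean² − var/n) — the denominator correction
removes the upward bias of the squared sample mean — and the per-gene
values are pooled into a single 10 %-trimmed mean across genes, floored
at 0.01. At 2–3 replicates per stage a per-gene dispersion is far too
noisy for a calibrated test; pooling gives a type-I error close to
nominal (≈ 0.055 at n = 3 in the packaged calibration check).
Benjamini–Hochberg FDR is applied across tested genes; up = FC > 2 at
FDR < 0.05, down = FC < 0.5 at FDR < 0.05.

Classification: *maternal* = mean normalized RPKM peaks in the oocyte
AND some consecutive-stage pair whose earlier stage is at/after the
4-cell stage is called down; *zygotic* = such a pair is called up AND
the oocyte is not the peak; otherwise *undetermined*. "At/after the
4-cell stage" operationalizes the informal "changes sharply after the
4-cell stage"; no formal rule exists, so the first qualifying pair is
(4-cell, 8-cell).

## Genomic features

Per circle: exon count and lengths from the annotated exons it spans;
the upstream flanking intron is the intron immediately 5′ (transcript
orientation) of the acceptor exon, downstream immediately 3′ of the
donor exon; a circle at a terminal exon simply lacks that intron.
Hosting genes with ≥ 2 distinct circle isoforms are hot-spot genes.
Repeat (Alu-like) enrichment counts, per intron, repeat intervals that
*intersect* the intron, compares flanking vs control introns (a seeded
uniform sample of introns from expressed non-hosting genes, matched in
number), and tests with a two-sided Wilcoxon rank-sum.

## Novel-transcript filter

A candidate survives iff overall RPKM > 0.5 and every replicate
RPKM > 0.25; its genomic span is ≥ 10 kb from every known gene's span
(strand-agnostic — strandedness of the rule is unstated, and distance
between spans is the plain reading); and it has ≥ 2 exons with total
exon length > 500 nt. RPKM and length thresholds are strict as stated;
"at least" thresholds are inclusive. Rejections are tallied under the
first failed criterion in the fixed order expression → distance →
structure.

## The synthetic series

The generator is a pure function of its config (identical seed ⇒
byte-identical files). Defaults are the study conditions:

* **Stages and totals.** Nine stages, three embryos each; true total
  mRNA per embryo fixed at 66.4, 29.0, 24.6, 17.0, 15.7, 38.1, 45.9,
  104.5, 150.7 ×10⁶ molecules — the observed single-embryo range.
* **Transcriptome.** 300 multi-exon genes (a scaled-down transcriptome;
  large enough that total-expression noise averages out the way it does
  over a real gene complement), lognormal baseline abundances, and
  archetype profiles: maternal genes (40 %) peak in the oocyte and
  collapse ~8-fold after the 4-cell stage, zygotic genes (40 %) activate
  ~8-fold from the 8-cell stage, the rest are flat.
* **Counts.** 9×10⁶ reads per sample (the real per-stage depth), drawn
  as one multinomial over capture weights
  efficiency × attomole × length-kb × noise, with gamma gene noise of
  shape 1/dispersion (dispersion 0.1, a typical bulk-like value) — i.e.
  gamma-multinomial, negative-binomial-like marginals with exact column
  totals. At this depth the > 0.001-attomole ERCC retention rule keeps
  only species measured well above counting noise, as it does in real
  libraries; at much lower simulated depths Poisson noise on near-cutoff
  species would dominate the regression instead.
* **Capture model.** log-linear with slope 1.0. Endogenous genes and the
  RGC trio share an efficiency 3× that of the ERCCs (the short-polyA
  capture penalty), so the ERCC-based total is biased ~3× high and the
  combined regression is what recovers truth — the scenario the dual
  spike-in design exists for. Lognormal noise: σ = 0.1 dex for ERCC
  species; σ = 0.05 dex for the RGC trio, whose polyA-matched capture is
  the *consistent* element of the design. RGC molecules are exactly
  100:10:1 (10⁶/10⁵/10⁴).
* **Circles.** 20 hosting genes; every second one carries two isoforms
  (hot-spots). Junction boundaries coincide exactly with annotated exon
  boundaries, so the tol = 0 caller can recover them. Per circle and
  sample, total junction reads are Poisson (mean 60) split binomially at
  the true circ ratio (0.10); back-spliced reads become chimeric records
  with mates placed inside the circle span, except a 5 % contaminant
  fraction with mates outside — these exercise the pair-end filter.
  Forward reads are reported at both junction loci.
* **Annotation geometry.** 4–8 exons of 100–300 nt, exponential introns
  (mean 1.2 kb); circle-flanking introns are 4× longer and carry a 4×
  repeat rate (Poisson at 0.6 repeats/kb baseline), mimicking the
  flanking-intron/repeat signature of circularization.
* **Auxiliary fixtures.** A small synthetic FASTQ pair seeded with reads
  violating each cleaning rule, and novel-transcript candidates, one
  quarter passing and the rest failing exactly one criterion each.

What the simulator does **not** emulate: sequence-level reads and errors
(the QC fixture is synthetic sequence with no genome tie-in), fragment
length and positional coverage bias, polyA-tail biochemistry beyond one
per-class efficiency scalar, multi-mapping, isoform structure beyond one
transcript per gene, and correlated biological replicate structure.
Passing tests therefore demonstrate the *algorithms* behave as specified
under the stated noise model, not that the estimates are accurate on
real libraries with alignment artifacts and capture chemistry the model
omits.

## Numerical and design notes

* ERCC regression requires ≥ 3 usable species and a positive slope;
  degenerate combined regressions (all ERCC estimates equal) error.
* Multi-chromosome chimeric records are skipped with a count, not
  errored — trans-chromosomal events are outside exonic-circRNA scope.
* Forward-read averaging rounds half-up to keep counts integral.
* The pipeline runs simulate → clean → circ-call → quantify → deg →
  circ-stats → novel-filter from one YAML config, writes a manifest
  (config hash, seed, sha256 of every output), and its outputs are
  byte-identical under a fixed config; the manifest's timestamps are the
  only non-reproducible bytes.
* Problem sizes in the test suite (30–300 genes, 2×10⁵–9×10⁶ reads,
  500-replicate calibration loops) were chosen so the full suite
  completes in seconds while leaving the statistical criteria
  well-powered.

## Known limitations

* The NB test has no per-gene dispersion shrinkage toward a
  mean-dependent trend and no outlier handling; with strongly
  heterogeneous dispersions the pooled estimate will be miscalibrated
  for the tails.
* The combined copy-number estimator inherits any violation of capture
  proportionality (slope ≠ 1): the RGC ratio estimator is only
  consistent under proportional capture.
* Intronic and exon–intron circles are out of scope; only exonic
  back-splices at annotated boundaries are called.
* With a single replicate per stage the Wald test falls back to the
  dispersion floor and is anti-conservative; classification then relies
  on the very large archetype effect sizes.
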