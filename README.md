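# embryocirc

Downstream analysis of single-embryo total-RNA sequencing (polyA+ *and*
polyA− transcripts) across pre-implantation development: back-splice
circRNA calling with a pair-end linearity check, absolute mRNA/circRNA
copy-number quantification from a dual spike-in design, junction-level
circular/linear statistics, maternal/zygotic gene classification,
circRNA genomic-feature analysis, and novel-transcript filtering — all
exercised end-to-end on a synthetic 9-stage embryo series with known
ground truth.

## The methods at the core

**circRNA calling.** A back-splice joins the 3′ end of a downstream
(donor) exon to the 5′ end of an upstream (acceptor) exon of the same
gene. Evidence is a chimeric read pair whose two segments appear in
reversed genomic order with boundaries landing exactly on annotated
splice sites, and whose mate aligns linearly *inside* the circle span
`[acceptor, donor]` — the pair-end check that removes artifactual
chimeras. A circle is reported in a sample only with ≥ 2 distinct
supporting read pairs there.

**Absolute quantification.** Each library carries two spike-in classes:

* an ERCC-like dilution series of known molar amounts. Per sample,
  ordinary least squares fits `log10 RPKM = a·log10 attomole + b` over
  species with > 0.001 attomole; the line is inverted at every gene's
  RPKM and summed to an ERCC-based total (1 attomole = 6.02214×10⁵
  molecules).
* an RGC trio (RFP:GFP:CRE = 100:10:1 molecules) with long polyA tails
  matching endogenous mRNA capture. Each detected species gives
  `(total RPKM / species RPKM) × spiked molecules`; the mean is the
  RGC-based total.

Because short-tailed ERCCs are captured ~3× less efficiently than
polyA-matched RNA, the two totals disagree systematically; the final
copy number regresses `log10(RGC-based)` on `log10(ERCC-based)` across
all samples and takes each sample's fitted value.

**circRNA copies.** A junction read spans at most
`(read length − 25) × 2` nt — 150 bp for 100-bp reads — which is the
length term in the per-circle RPKM; circRNA copies are
`(Σ circle RPKM / Σ gene RPKM) × mRNA copies`.

**Differential expression and the maternal-to-zygotic transition.**
Counts are normalized by size factors ∝ depth / mRNA copies (geometric
mean 1), so expression is compared per transcript copy. A
negative-binomial Wald test (method-of-moments dispersion pooled across
genes) is run between consecutive stages; up means FC > 2 at FDR < 0.05,
down FC < 0.5 at FDR < 0.05. A gene is *maternal* if it peaks in the
oocyte and has a down call at/after the 4-cell stage, *zygotic* if it
has an up call there and does not peak in the oocyte.

## Worked example

```sh
embryocirc pipeline --config examples/config.yaml --out demo/
```

or from Python:

```python
from embryocirc.pipeline import run_pipeline
run_pipeline({"seed": 7}, outdir="demo")
```

This simulates a 9-stage series (3 embryos per stage, 9×10⁶ reads each),
then runs every stage. `demo/copies.tsv` starts:

```
sample_id  ercc_based_copies  rgc_based_copies  final_copies  circ_copies
oocyte_r1       2.005855e+08      6.764544e+07  6.671662e+07 12213.6
zygote_r1       9.213133e+07      2.758055e+07  3.075850e+07  7157.2
 2cell_r1       6.940763e+07      2.337185e+07  2.320363e+07  5946.0
```

The ERCC-based totals overshoot ~3× (short-polyA capture bias); the
combined estimate recovers the true simulated totals (6.64×10⁷ molecules
per oocyte, 2.9×10⁷ per zygote) to within a few percent, alongside
~10⁴ circRNA copies per embryo. `demo/gene_classes.tsv` recovers the
simulated maternal/zygotic archetypes (120 maternal, 180 zygotic calls
here), and `demo/alu_enrichment.json` shows the elevated repeat density
in circle-flanking introns (2.55 vs 0.55 per kb, rank-sum
p ≈ 1.8×10⁻¹⁵).

Every subcommand (`simulate`, `clean`, `circ-call`, `quantify`, `deg`,
`circ-stats`, `novel-filter`, `pipeline`) is also available standalone;
see `embryocirc --help`.

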