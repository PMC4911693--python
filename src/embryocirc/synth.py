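"""Synthetic single-embryo series with ground truth for every pipeline stage.

The simulator emulates a 9-stage pre-implantation series (oocyte to hatched
blastocyst), one or more libraries per stage, each containing:

* linear gene transcripts following maternal / zygotic / flat archetype
  profiles, scaled so each sample's true total mRNA content matches a
  configured per-stage value (defaults span the ~1.6e7-1.5e8 molecule range
  observed in single embryos);
* an ERCC-like dilution series and an RGC-like trio of spike-ins.  Capture
  follows a log-linear model (expected RPKM proportional to molar amount,
  lognormal noise in dex); endogenous mRNA and the polyA-tailed RGC trio
  share a capture efficiency ``rgc_efficiency_ratio`` times that of the
  short-tailed ERCCs, reproducing the polyA-length capture bias the dual
  spike-in design exists to correct;
* for each simulated circle, back-spliced chimeric read pairs with segment
  boundaries exactly on annotated splice sites (mates inside the circle
  span, except a configurable contaminant fraction placed outside) and
  forward-spliced junction reads at the two junction loci, split binomially
  at the true circ ratio.

Everything is a pure function of the config: identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ioformats import (
    ChimericRead,
    CountTable,
    GeneModel,
    SpikeIn,
    SpikeInPanel,
    write_bed,
    write_chimeric,
    write_count_table,
    write_gtf,
    write_linear_junctions,
    write_spikein_table,
)
from .quantcopy import MOLECULES_PER_ATTOMOLE

__all__ = [
    "STAGES",
    "TRUE_TOTALS",
    "SimulationConfig",
    "AnnotationTruth",
    "TruthTable",
    "SimulatedSeries",
    "simulate_annotation",
    "simulate_embryo_series",
    "emit_truth",
    "read_truth",
    "simulate_all",
]

#: the nine developmental stages, oocyte -> hatched blastocyst
STAGES = (
    "oocyte",
    "zygote",
    "2cell",
    "4cell",
    "8cell",
    "morula",
    "early_blastocyst",
    "blastocyst",
    "hatched_blastocyst",
)

#: default true total mRNA molecules per sample at each stage (x1e6:
#: 66.4, 29.0, 24.6, 17.0, 15.7, 38.1, 45.9, 104.5, 150.7 — the observed
#: single-embryo range during human pre-implantation development)
TRUE_TOTALS = (
    66.4e6, 29.0e6, 24.6e6, 17.0e6, 15.7e6, 38.1e6, 45.9e6, 104.5e6, 150.7e6,
)

# archetype expression profiles over the 9 stages (relative weights);
# maternal peaks in the oocyte and collapses ~8-fold after the 4-cell
# stage, zygotic activates ~8-fold at the 8-cell stage
_MATERNAL_PROFILE = (1.0, 0.95, 0.9, 0.85, 0.11, 0.10, 0.09, 0.09, 0.08)
_ZYGOTIC_PROFILE = (0.10, 0.10, 0.11, 0.12, 0.85, 0.95, 1.0, 1.0, 1.0)
_FLAT_PROFILE = (0.6,) * 9


@dataclass
class SimulationConfig:
    """All knobs of the synthetic embryo series (defaults = study conditions)."""

    seed: int = 0
    n_genes: int = 300
    n_circ_hosting: int = 20
    stages: tuple[str, ...] = STAGES
    replicates_per_stage: int = 3
    true_total_copies: tuple[float, ...] = TRUE_TOTALS
    maternal_frac: float = 0.4
    zygotic_frac: float = 0.4
    nb_dispersion: float = 0.1
    depth: int = 9_000_000
    read_length: int = 100
    # circles
    circ_ratio: float = 0.10
    junction_depth: int = 60
    contaminant_fraction: float = 0.05
    # spike-ins / capture model
    n_ercc: int = 92
    ercc_amount_range: tuple[float, float] = (1e-4, 10.0)  # attomole
    ercc_slope: float = 1.0
    ercc_sigma: float = 0.1  # dex; short-polyA capture is the unstable step
    rgc_sigma: float = 0.05  # dex; polyA-matched capture is more consistent
    rgc_efficiency_ratio: float = 3.0
    rgc_molecules: tuple[float, ...] = (1e6, 1e5, 1e4)  # RFP:GFP:CRE = 100:10:1
    # annotation geometry
    exon_range: tuple[int, int] = (100, 300)
    n_exon_range: tuple[int, int] = (4, 8)
    intron_mean: float = 1200.0
    flanking_multiplier: float = 4.0
    repeat_density_per_kb: float = 0.6
    repeat_length: int = 300
    chrom: str = "chrS"
    # auxiliary fixtures for the QC and novel-transcript stages
    n_novel: int = 32
    n_qc_reads: int = 400

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.stages:
            raise ValueError("stage list must be non-empty")
        if len(self.true_total_copies) != len(self.stages):
            raise ValueError("one true total per stage required")
        if not 0 <= self.circ_ratio < 1:
            raise ValueError("circ_ratio must lie in [0, 1)")
        if self.n_circ_hosting > self.n_genes:
            raise ValueError("n_circ_hosting cannot exceed n_genes")
        if min(self.true_total_copies) <= 0 or self.depth <= 0:
            raise ValueError("totals and depth must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{stage}_r{rep + 1}"
            for stage in self.stages
            for rep in range(self.replicates_per_stage)
        ]

    def stage_of(self, sample_id: str) -> str:
        return sample_id.rsplit("_r", 1)[0]


@dataclass
class AnnotationTruth:
    """Ground truth fixed at annotation time."""

    hosting_genes: list[str]
    # circ_id -> (gene_id, genomic exon indices)
    circles: dict[str, tuple[str, tuple[int, ...]]]
    flanking_introns: list[tuple[str, int, int]]
    intron_truth: pd.DataFrame  # gene_id, intron_index, start, end, is_flanking, n_repeats


@dataclass
class TruthTable:
    """Full ground truth for one simulated series."""

    sample_truth: pd.DataFrame  # sample_id, stage, true_total_copies
    gene_truth: pd.DataFrame  # gene_id, class, is_hosting
    gene_copies: pd.DataFrame  # genes x samples true molecule counts
    junction_truth: pd.DataFrame  # per circle x sample junction ground truth
    intron_truth: pd.DataFrame

    def consistent(self, atol: float = 1e-6) -> bool:
        totals = self.gene_copies.sum(axis=0)
        ref = self.sample_truth.set_index("sample_id")["true_total_copies"]
        return bool(np.allclose(totals[ref.index], ref, rtol=atol))


@dataclass
class SimulatedSeries:
    counts: CountTable
    chimeric: list[ChimericRead]
    linear_junctions: pd.DataFrame
    panel: SpikeInPanel
    genes: list[GeneModel]
    repeats: pd.DataFrame
    truth: TruthTable


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], pd.DataFrame, AnnotationTruth]:
    """Lay out multi-exon genes on one synthetic chromosome.

    Circle-hosting genes (the first ``n_circ_hosting``, alternating strand)
    receive ``flanking_multiplier``-times longer introns around the
    back-spliced exons and a matching elevated repeat rate there.  Every
    second hosting gene carries two circle isoforms (a hot-spot gene).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    genes: list[GeneModel] = []
    repeats_rows: list[tuple[str, int, int, str]] = []
    intron_rows: list[dict] = []
    circles: dict[str, tuple[str, tuple[int, ...]]] = {}
    flanking: list[tuple[str, int, int]] = []
    hosting = [f"g{idx:04d}" for idx in range(cfg.n_circ_hosting)]
    cursor = 10_000
    rep_counter = 0
    for idx in range(cfg.n_genes):
        gene_id = f"g{idx:04d}"
        is_hosting = idx < cfg.n_circ_hosting
        strand = "+" if idx % 2 == 0 else "-"
        n_exons = int(rng.integers(cfg.n_exon_range[0], cfg.n_exon_range[1] + 1))
        if is_hosting:
            n_exons = max(n_exons, 5)
        exon_lens = rng.integers(
            cfg.exon_range[0], cfg.exon_range[1] + 1, size=n_exons
        )
        intron_lens = np.maximum(
            60, rng.exponential(cfg.intron_mean, size=n_exons - 1)
        ).astype(int)
        # circle spans genomic exons 1..2 (and 1..3 for hot-spot isoforms):
        # flanking introns are intron 0 (left of exon 1) and intron 2 or 3
        circle_spans: list[tuple[int, ...]] = []
        if is_hosting:
            circle_spans.append((1, 2))
            if idx % 2 == 0:
                circle_spans.append((1, 3))
            flank_idx = {0} | {span[-1] for span in circle_spans}
            for fi in sorted(flank_idx):
                intron_lens[fi] = int(intron_lens[fi] * cfg.flanking_multiplier)
        else:
            flank_idx = set()
        exons = []
        pos = cursor
        for ei in range(n_exons):
            exons.append((pos, pos + int(exon_lens[ei])))
            pos += int(exon_lens[ei])
            if ei < n_exons - 1:
                pos += int(intron_lens[ei])
        gene = GeneModel(gene_id, cfg.chrom, strand, tuple(exons))
        genes.append(gene)
        cursor = pos + int(rng.integers(5_000, 20_000))
        # repeats per intron: Poisson at the configured density, elevated in
        # flanking introns by the same multiplier
        for ii, (istart, iend) in enumerate(gene.introns()):
            is_flank = ii in flank_idx
            rate = cfg.repeat_density_per_kb * (iend - istart) / 1e3
            if is_flank:
                rate *= cfg.flanking_multiplier
            n_rep = int(rng.poisson(rate))
            for _ in range(n_rep):
                span = min(cfg.repeat_length, iend - istart)
                start = int(rng.integers(istart, max(istart + 1, iend - span)))
                repeats_rows.append(
                    (cfg.chrom, start, start + span, f"AluY_{rep_counter}")
                )
                rep_counter += 1
            intron_rows.append(
                {
                    "gene_id": gene_id,
                    "intron_index": ii,
                    "start": istart,
                    "end": iend,
                    "is_flanking": is_flank,
                    "n_repeats": n_rep,
                }
            )
            if is_flank:
                flanking.append((cfg.chrom, istart, iend))
        for span in circle_spans:
            lo, hi = span[0], span[-1]
            circ_id = (
                f"{cfg.chrom}:{gene.exons[lo][0]}-{gene.exons[hi][1]}:{strand}"
            )
            circles[circ_id] = (gene_id, tuple(range(lo, hi + 1)))
    repeats = pd.DataFrame(
        sorted(repeats_rows), columns=["chrom", "start", "end", "name"]
    )
    truth = AnnotationTruth(
        hosting_genes=hosting,
        circles=circles,
        flanking_introns=flanking,
        intron_truth=pd.DataFrame(intron_rows),
    )
    return genes, repeats, truth


def _gene_classes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    n = cfg.n_genes
    n_mat = int(round(cfg.maternal_frac * n))
    n_zyg = int(round(cfg.zygotic_frac * n))
    labels = (
        ["maternal"] * n_mat
        + ["zygotic"] * n_zyg
        + ["flat"] * (n - n_mat - n_zyg)
    )
    perm = rng.permutation(n)
    return pd.Series(
        [labels[perm[i]] for i in range(n)],
        index=[f"g{idx:04d}" for idx in range(n)],
        name="class",
    )


def _ercc_panel(cfg: SimulationConfig, rng: np.random.Generator) -> SpikeInPanel:
    amounts = np.logspace(
        np.log10(cfg.ercc_amount_range[0]),
        np.log10(cfg.ercc_amount_range[1]),
        cfg.n_ercc,
    )
    lengths = rng.integers(500, 2001, size=cfg.n_ercc)
    species = [
        SpikeIn(f"ERCC-{i:05d}", "ERCC", float(amounts[i]), "attomole",
                int(lengths[i]), 20)
        for i in range(cfg.n_ercc)
    ]
    for name, mol in zip(("RGC-RFP", "RGC-GFP", "RGC-CRE"), cfg.rgc_molecules):
        species.append(SpikeIn(name, "RGC", float(mol), "molecules", 1000, 80))
    return SpikeInPanel(tuple(species))


def simulate_embryo_series(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    ann_truth: AnnotationTruth,
    repeats: pd.DataFrame | None = None,
) -> SimulatedSeries:
    """Draw counts, spike-ins and junction reads for every sample.

    Per-sample gene counts are a depth-exact multinomial over capture
    weights ``efficiency x attomole x length_kb x noise`` with gamma gene
    noise (shape 1/dispersion), so marginal gene counts are
    gamma-multinomial — negative-binomial-like — while column totals equal
    the configured depth exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    panel = _ercc_panel(cfg, rng)
    by_id = {g.gene_id: g for g in genes}
    gene_ids = [g.gene_id for g in genes]
    gene_lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in genes}, dtype=float
    )
    classes = _gene_classes(cfg, rng)
    profiles = {
        "maternal": np.asarray(_MATERNAL_PROFILE),
        "zygotic": np.asarray(_ZYGOTIC_PROFILE),
        "flat": np.asarray(_FLAT_PROFILE),
    }
    # per-gene base abundance (lognormal across genes, fixed over samples)
    base = rng.lognormal(0.0, 0.8, size=cfg.n_genes)

    sample_ids = cfg.sample_ids
    stage_index = {s: i for i, s in enumerate(cfg.stages)}
    gene_copies = pd.DataFrame(index=gene_ids, columns=sample_ids, dtype=float)
    counts = pd.DataFrame(0, index=gene_ids + panel.ids(), columns=sample_ids,
                          dtype=np.int64)
    sample_rows = []
    junction_rows = []
    chimeric: list[ChimericRead] = []
    linear_rows: list[tuple[str, int, str, int]] = []
    unreachable: list[str] = []
    read_counter = 0

    ercc_amt = np.array([s.amount for s in panel.ercc()])
    ercc_len_kb = np.array([s.length for s in panel.ercc()]) / 1e3
    rgc_amt = np.array(
        [mol / MOLECULES_PER_ATTOMOLE for mol in cfg.rgc_molecules]
    )
    rgc_len_kb = np.array([s.length for s in panel.rgc()]) / 1e3

    for sample in sample_ids:
        stage = cfg.stage_of(sample)
        si = stage_index[stage]
        total = float(cfg.true_total_copies[si])
        rel = np.array(
            [profiles[classes[g]][si] * base[i] for i, g in enumerate(gene_ids)]
        )
        copies = rel / rel.sum() * total
        gene_copies[sample] = copies
        sample_rows.append(
            {"sample_id": sample, "stage": stage, "true_total_copies": total}
        )
        # capture weights on the log-linear model; genes and RGC share the
        # higher (polyA-matched) efficiency, ERCC sits a factor below it
        gene_amt = copies / MOLECULES_PER_ATTOMOLE
        gamma_noise = rng.gamma(
            1.0 / cfg.nb_dispersion, cfg.nb_dispersion, size=cfg.n_genes
        )
        w_gene = (
            cfg.rgc_efficiency_ratio
            * gene_amt**cfg.ercc_slope
            * (gene_lengths.values / 1e3)
            * gamma_noise
        )
        w_ercc = (
            ercc_amt**cfg.ercc_slope
            * ercc_len_kb
            * 10 ** rng.normal(0.0, cfg.ercc_sigma, size=cfg.n_ercc)
        )
        w_rgc = (
            cfg.rgc_efficiency_ratio
            * rgc_amt**cfg.ercc_slope
            * rgc_len_kb
            * 10 ** rng.normal(0.0, cfg.rgc_sigma, size=len(rgc_amt))
        )
        w = np.concatenate([w_gene, w_ercc, w_rgc])
        counts[sample] = rng.multinomial(cfg.depth, w / w.sum())

        # junction reads for every circle
        for circ_id, (gene_id, exon_idx) in sorted(ann_truth.circles.items()):
            gene = by_id[gene_id]
            acceptor = gene.exons[exon_idx[0]][0]
            donor = gene.exons[exon_idx[-1]][1]
            n_junction = int(rng.poisson(cfg.junction_depth))
            back = int(rng.binomial(n_junction, cfg.circ_ratio))
            forward = n_junction - back
            n_contam = int(rng.binomial(back, cfg.contaminant_fraction))
            contam_ids = []
            seg_len = min(50, cfg.read_length // 2)
            span = donor - acceptor
            for k in range(back):
                read_id = f"rp{read_counter:08d}"
                read_counter += 1
                is_contam = k < n_contam
                if is_contam:
                    mate = (donor + 2_000, donor + 2_000 + cfg.read_length)
                    contam_ids.append(read_id)
                else:
                    mstart = acceptor + int(
                        rng.integers(0, max(1, span - cfg.read_length))
                    )
                    mate = (mstart, min(donor, mstart + cfg.read_length))
                chimeric.append(
                    ChimericRead(
                        read_id=read_id,
                        sample_id=sample,
                        chrom=gene.chrom,
                        seg1=(donor - seg_len, donor),
                        seg2=(acceptor, acceptor + seg_len),
                        strand=gene.strand,
                        mate_interval=mate,
                        mate_linear=True,
                        mate_chrom=gene.chrom,
                    )
                )
            linear_rows.append((gene.chrom, acceptor, sample, forward))
            linear_rows.append((gene.chrom, donor, sample, forward))
            junction_rows.append(
                {
                    "circ_id": circ_id,
                    "gene_id": gene_id,
                    "acceptor_pos": acceptor,
                    "donor_pos": donor,
                    "sample_id": sample,
                    "true_ratio": cfg.circ_ratio,
                    "back_reads": back,
                    "clean_back_reads": back - n_contam,
                    "forward_reads": forward,
                    "contaminant_reads": ",".join(contam_ids),
                }
            )

    junction_truth = pd.DataFrame(junction_rows)
    if not junction_truth.empty:
        per_circ_max = junction_truth.groupby("circ_id")["clean_back_reads"].max()
        unreachable = per_circ_max.index[per_circ_max < 2].tolist()
        if unreachable:
            warnings.warn(
                "junction depth too low for >=2 back-spliced reads in any "
                f"sample for circles: {unreachable}"
            )
    meta = pd.DataFrame(
        {
            "total_mapped_reads": cfg.depth,
            "read_length": cfg.read_length,
            "stage": [cfg.stage_of(s) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_truth = pd.DataFrame(
        {
            "class": classes,
            "is_hosting": [g in set(ann_truth.hosting_genes) for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = TruthTable(
        sample_truth=pd.DataFrame(sample_rows),
        gene_truth=gene_truth,
        gene_copies=gene_copies,
        junction_truth=junction_truth,
        intron_truth=ann_truth.intron_truth,
    )
    linear_junctions = pd.DataFrame(
        linear_rows, columns=["chrom", "pos", "sample_id", "reads"]
    )
    if repeats is None:
        repeats = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return SimulatedSeries(
        counts=CountTable(counts, meta),
        chimeric=chimeric,
        linear_junctions=linear_junctions,
        panel=panel,
        genes=genes,
        repeats=repeats,
        truth=truth,
    )


def simulate_novel_candidates(cfg: SimulationConfig, genes: list[GeneModel]):
    """Candidate de novo transcripts exercising every filter criterion.

    Candidates are laid out beyond the last annotated gene; one quarter pass
    every criterion, the rest fail exactly one of expression, distance or
    structure (category recorded in ``expected``).
    """
    from .noveltx import NovelTranscript

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    last_end = max(g.span[1] for g in genes)
    candidates: list[NovelTranscript] = []
    expected: list[str] = []
    cursor = last_end + 50_000
    categories = ["pass", "expression", "distance", "structure"]
    for i in range(cfg.n_novel):
        cat = categories[i % 4]
        exon1 = int(rng.integers(280, 400))
        exon2 = int(rng.integers(280, 400))
        gap = int(rng.integers(200, 2_000))
        start = cursor
        exons = ((start, start + exon1), (start + exon1 + gap,
                                          start + exon1 + gap + exon2))
        rpkm, reps = float(rng.uniform(0.6, 3.0)), (
            float(rng.uniform(0.3, 1.5)), float(rng.uniform(0.3, 1.5)),
        )
        if cat == "expression":
            if i % 8 < 4:
                rpkm = float(rng.uniform(0.05, 0.5))
            else:
                reps = (float(rng.uniform(0.01, 0.25)), reps[1])
        elif cat == "distance":
            # overlap the annotated tail of the chromosome: < 10 kb away
            offset = int(rng.integers(1_000, 9_000))
            exons = tuple(
                (s - (cursor - last_end) + offset, e - (cursor - last_end) + offset)
                for s, e in exons
            )
        elif cat == "structure":
            if i % 8 < 4:
                exons = (exons[0],)  # single exon
            else:
                exons = ((start, start + 200), (start + 200 + gap,
                                                start + 200 + gap + 250))
        candidates.append(
            NovelTranscript(
                tx_id=f"novel{i:04d}", chrom=cfg.chrom, strand="+",
                exons=exons, rpkm_overall=rpkm, rpkm_per_replicate=reps,
            )
        )
        expected.append(cat)
        cursor += 30_000
    return candidates, expected


def simulate_qc_reads(cfg: SimulationConfig):
    """A small FASTQ pair exercising every read-cleaning rule.

    Reads are synthetic sequence (no genome tie-in): mostly clean, with
    low-quality, N-rich, polyA/T-tailed, AT-rich and adaptor-bearing reads
    mixed in at fixed proportions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 404]))
    adaptor = "AGATCGGAAGAGC"
    bases = np.array(list("ACGT"))
    r1, r2 = [], []
    L = cfg.read_length
    for i in range(cfg.n_qc_reads):
        kind = i % 10
        for mate, bucket in ((1, r1), (2, r2)):
            seq = "".join(rng.choice(bases, size=L))
            qual = "I" * L  # Q40
            if kind == 0 and mate == 1:  # low quality
                qual = "&" * (L // 2 + 5) + "I" * (L - L // 2 - 5)
            elif kind == 1 and mate == 1:  # undetermined
                seq = "N" * (L // 10 + 2) + seq[L // 10 + 2:]
            elif kind == 2:  # 3' polyA tail
                seq = seq[: L - 30] + "A" * 30
            elif kind == 3 and mate == 2:  # AT-rich
                seq = "".join(rng.choice(np.array(list("AT")), size=L))
            elif kind == 4:  # adaptor read-through
                pos = int(rng.integers(40, 60))
                seq = seq[:pos] + adaptor + seq[pos + len(adaptor):]
            bucket.append((f"qc{i:06d}/{mate}", seq, qual))
    return r1, r2, [adaptor]


def emit_truth(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Write every truth table as TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, index in (
        ("sample_truth", truth.sample_truth, False),
        ("gene_truth", truth.gene_truth, True),
        ("gene_copies", truth.gene_copies.rename_axis("gene_id"), True),
        ("junction_truth", truth.junction_truth, False),
        ("intron_truth", truth.intron_truth, False),
    ):
        path = outdir / f"truth_{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        paths[name] = path
    return paths


def read_truth(outdir: str | Path) -> TruthTable:
    outdir = Path(outdir)
    return TruthTable(
        sample_truth=pd.read_csv(outdir / "truth_sample_truth.tsv", sep="\t"),
        gene_truth=pd.read_csv(
            outdir / "truth_gene_truth.tsv", sep="\t", index_col="gene_id"
        ),
        gene_copies=pd.read_csv(
            outdir / "truth_gene_copies.tsv", sep="\t", index_col="gene_id"
        ),
        junction_truth=pd.read_csv(
            outdir / "truth_junction_truth.tsv", sep="\t",
            keep_default_na=False,
            dtype={"contaminant_reads": str},
        ),
        intron_truth=pd.read_csv(outdir / "truth_intron_truth.tsv", sep="\t"),
    )


def simulate_all(cfg: SimulationConfig, outdir: str | Path | None = None):
    """Annotation + series in one call; optionally write all fixture files."""
    genes, repeats, ann_truth = simulate_annotation(cfg)
    series = simulate_embryo_series(cfg, genes, ann_truth, repeats)
    if outdir is not None:
        from .noveltx import write_novel_table
        from .readqc import write_fastq

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(genes, outdir / "genes.gtf")
        write_bed(repeats, outdir / "repeats.bed")
        write_chimeric(series.chimeric, outdir / "chimeric.tsv")
        write_linear_junctions(
            series.linear_junctions, outdir / "linear_junctions.tsv"
        )
        write_spikein_table(series.panel, outdir / "spikeins.tsv")
        write_count_table(
            series.counts, outdir / "counts.tsv", outdir / "samples.tsv"
        )
        candidates, expected = simulate_novel_candidates(cfg, genes)
        write_novel_table(candidates, outdir / "novel_candidates.tsv")
        pd.DataFrame(
            {"tx_id": [c.tx_id for c in candidates], "expected": expected}
        ).to_csv(outdir / "truth_novel.tsv", sep="\t", index=False)
        r1, r2, adaptors = simulate_qc_reads(cfg)
        write_fastq(r1, outdir / "reads_R1.fastq")
        write_fastq(r2, outdir / "reads_R2.fastq")
        (outdir / "adaptors.txt").write_text("\n".join(adaptors) + "\n")
        emit_truth(series.truth, outdir)
    return series, ann_truth
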