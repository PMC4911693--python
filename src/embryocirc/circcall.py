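"""Exonic circRNA annotation from chimeric read pairs.

A back-splice joins the 3' end of a downstream (donor) exon to the 5' end of
an upstream (acceptor) exon of the same gene.  Evidence is a read pair whose
chimeric read carries two segments in reversed genomic order, with segment
boundaries landing exactly (within ``tol``) on annotated splice sites, and
whose mate — when present — aligns linearly inside the circle span.  A
circRNA is reported in a sample only with at least ``min_reads`` distinct
supporting read pairs there.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioformats import ChimericRead, GeneModel

__all__ = [
    "CircRNARecord",
    "CandidateJunction",
    "AnnotationDiagnostics",
    "annotate_backsplices",
    "filter_support",
    "classify_exon_position",
    "attach_forward_reads",
]


@dataclass
class CircRNARecord:
    """An annotated exonic circRNA with per-sample junction read counts.

    ``acceptor_pos``/``donor_pos`` are the genomic start of the leftmost
    (acceptor, in transcript orientation on the plus strand) exon and the
    genomic end of the rightmost exon: the canonical key of a circle is
    always (chrom, min coordinate, max coordinate, strand).
    ``exon_indices`` are genomic exon ordinals (0-based) within the hosting
    gene and are contiguous.
    """

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    hosting_gene: str
    exon_indices: tuple[int, ...]
    back_reads: dict[str, int] = field(default_factory=dict)
    forward_reads: dict[str, int] = field(default_factory=dict)
    exon_position_class: str = "internal"
    upstream_evidence: bool = False

    def __post_init__(self) -> None:
        if self.acceptor_pos >= self.donor_pos:
            raise ValueError("acceptor_pos must be < donor_pos")
        idx = tuple(self.exon_indices)
        if idx != tuple(range(idx[0], idx[-1] + 1)):
            raise ValueError("exon_indices must be contiguous")
        self.exon_indices = idx

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.acceptor_pos, self.donor_pos, self.strand)

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.acceptor_pos}-{self.donor_pos}:{self.strand}"


@dataclass
class CandidateJunction:
    """A putative back-splice junction with its supporting read ids."""

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    hosting_gene: str
    exon_indices: tuple[int, ...]
    support: dict[str, set[str]] = field(default_factory=dict)  # sample -> read ids

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.acceptor_pos, self.donor_pos, self.strand)


@dataclass
class AnnotationDiagnostics:
    n_reads: int = 0
    n_supporting: int = 0
    n_no_splice_match: int = 0
    n_mate_rejected: int = 0
    n_ambiguous: int = 0
    n_not_backspliced: int = 0


def annotate_backsplices(
    reads: list[ChimericRead],
    genes: list[GeneModel] | set[GeneModel],
    tol: int = 0,
) -> tuple[list[CandidateJunction], AnnotationDiagnostics]:
    """Match chimeric reads to annotated exon pairs of single genes.

    A read supports junction (gene, exon_i -> exon_j, i <= j genomic) iff

    * its downstream segment's end coincides (within ``tol``) with the
      annotated end of exon_j and its upstream segment's start with the
      annotated start of exon_i, both exons of the *same* gene;
    * the two segments appear in back-spliced (reversed genomic) order in
      the read;
    * its mate, when aligned, lies linearly within
      ``[acceptor_pos, donor_pos]`` on the same chromosome.

    A read pair may support at most one junction; reads matching several
    (possible when ``tol > 0``) are dropped and tallied as ambiguous.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    # per chrom: exon start -> [(gene_idx, exon_idx)], exon end -> same
    genes = sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id))
    starts: dict[str, dict[int, list[tuple[int, int]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    ends: dict[str, dict[int, list[tuple[int, int]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for gi, gene in enumerate(genes):
        for ei, (s, e) in enumerate(gene.exons):
            starts[gene.chrom][s].append((gi, ei))
            ends[gene.chrom][e].append((gi, ei))

    diag = AnnotationDiagnostics()
    candidates: dict[tuple, CandidateJunction] = {}
    for read in reads:
        diag.n_reads += 1
        # back-spliced order: first segment genomically downstream of second
        down, up = read.seg1, read.seg2
        if down[0] <= up[0]:
            diag.n_not_backspliced += 1
            continue
        start_hits = _hits(starts.get(read.chrom, {}), up[0], tol)
        end_hits = _hits(ends.get(read.chrom, {}), down[1], tol)
        junctions = set()
        for gi_a, ei_a in start_hits:
            for gi_d, ei_d in end_hits:
                if gi_a != gi_d or ei_a > ei_d:
                    continue
                junctions.add((gi_a, ei_a, ei_d))
        if not junctions:
            diag.n_no_splice_match += 1
            continue
        if len(junctions) > 1:
            diag.n_ambiguous += 1
            continue
        gi, ei_a, ei_d = junctions.pop()
        gene = genes[gi]
        acceptor_pos = gene.exons[ei_a][0]
        donor_pos = gene.exons[ei_d][1]
        if read.mate_interval is not None:
            mate_chrom = read.mate_chrom or read.chrom
            ms, me = read.mate_interval
            if (
                mate_chrom != read.chrom
                or not read.mate_linear
                or ms < acceptor_pos
                or me > donor_pos
            ):
                diag.n_mate_rejected += 1
                continue
        key = (read.chrom, acceptor_pos, donor_pos, gene.strand)
        cand = candidates.get(key)
        if cand is None:
            cand = CandidateJunction(
                chrom=read.chrom,
                strand=gene.strand,
                acceptor_pos=acceptor_pos,
                donor_pos=donor_pos,
                hosting_gene=gene.gene_id,
                exon_indices=tuple(range(ei_a, ei_d + 1)),
            )
            candidates[key] = cand
        cand.support.setdefault(read.sample_id, set()).add(read.read_id)
        diag.n_supporting += 1
    ordered = [candidates[k] for k in sorted(candidates)]
    return ordered, diag


def _hits(boundaries: dict[int, list], pos: int, tol: int) -> list:
    if tol == 0:
        return boundaries.get(pos, [])
    out: list = []
    for p in range(pos - tol, pos + tol + 1):
        out.extend(boundaries.get(p, []))
    return out


def filter_support(
    candidates: list[CandidateJunction], min_reads: int = 2
) -> list[CircRNARecord]:
    """Keep, per sample, junctions with at least ``min_reads`` distinct pairs.

    Back-read counts are distinct read-pair counts, preserved exactly; a
    junction supported in no sample at the threshold is dropped entirely.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    records: list[CircRNARecord] = []
    for cand in candidates:
        back = {
            sample: len(ids)
            for sample, ids in sorted(cand.support.items())
            if len(ids) >= min_reads
        }
        if not back:
            continue
        records.append(
            CircRNARecord(
                chrom=cand.chrom,
                strand=cand.strand,
                acceptor_pos=cand.acceptor_pos,
                donor_pos=cand.donor_pos,
                hosting_gene=cand.hosting_gene,
                exon_indices=cand.exon_indices,
                back_reads=back,
            )
        )
    return records


def classify_exon_position(
    rec: CircRNARecord,
    gene: GeneModel,
    upstream_coverage: np.ndarray | list[float] | None = None,
    *,
    window: int = 1000,
    depth_threshold: float = 1.0,
) -> CircRNARecord:
    """Label a circle by its position within the hosting gene.

    ``first_exon`` if the acceptor exon (in transcript orientation) is the
    gene's annotated first exon, ``last_exon`` if the donor exon is the
    annotated last exon, else ``internal``.  ``upstream_coverage`` is the
    per-base read depth in a ``window``-nt window immediately upstream (in
    transcript orientation) of the annotated first exon; mean depth above
    ``depth_threshold`` sets ``upstream_evidence`` — the signature of an
    unannotated upstream exon that would demote a first-exon call.
    """
    if rec.hosting_gene != gene.gene_id:
        raise ValueError("record not hosted by this gene")
    lo, hi = rec.exon_indices[0], rec.exon_indices[-1]
    if not (0 <= lo <= hi < gene.n_exons):
        raise ValueError("record exon indices not found in gene")
    if gene.exons[lo][0] != rec.acceptor_pos or gene.exons[hi][1] != rec.donor_pos:
        raise ValueError("record boundaries inconsistent with gene model")
    n = gene.n_exons
    if gene.strand == "+":
        includes_first, includes_last = lo == 0, hi == n - 1
    else:
        includes_first, includes_last = hi == n - 1, lo == 0
    if includes_first:
        rec.exon_position_class = "first_exon"
    elif includes_last:
        rec.exon_position_class = "last_exon"
    else:
        rec.exon_position_class = "internal"
    if upstream_coverage is not None:
        cov = np.asarray(upstream_coverage, dtype=float)
        if cov.size:
            rec.upstream_evidence = float(cov.mean()) > depth_threshold
    return rec


def attach_forward_reads(
    records: list[CircRNARecord],
    linear_junctions: pd.DataFrame,
    *,
    aggregate: str = "mean",
) -> list[CircRNARecord]:
    """Join forward-spliced (linear) junction reads onto circRNA records.

    ``linear_junctions`` has columns chrom, pos, sample_id, reads, where pos
    is a splice-site locus.  Each circle has two junction loci (its acceptor
    and donor boundaries); linear reads are counted at both loci and, by
    default, averaged (rounded half up to keep counts integral).
    """
    lookup: dict[tuple[str, int, str], int] = {}
    for row in linear_junctions.itertuples(index=False):
        lookup[(str(row.chrom), int(row.pos), str(row.sample_id))] = int(row.reads)
    for rec in records:
        for sample in rec.back_reads:
            a = lookup.get((rec.chrom, rec.acceptor_pos, sample), 0)
            d = lookup.get((rec.chrom, rec.donor_pos, sample), 0)
            if aggregate == "mean":
                rec.forward_reads[sample] = int(np.floor((a + d) / 2 + 0.5))
            elif aggregate == "sum":
                rec.forward_reads[sample] = a + d
            else:
                raise ValueError(f"unknown aggregate {aggregate!r}")
    return records
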