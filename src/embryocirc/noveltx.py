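"""Three-criterion filter for de novo assembled transcripts.

A candidate survives iff (1) expression: overall RPKM > 0.5 and RPKM > 0.25
in every replicate; (2) distance: at least 10 kb from any known gene
(genomic span to span, strand-agnostic); (3) structure: at least two exons
with total exon length > 500 bp.  Each rejected transcript is tallied under
the first criterion it fails, in the fixed order
expression -> distance -> structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ioformats import GeneModel

__all__ = [
    "NovelTranscript",
    "FilterTally",
    "filter_novel",
    "span_distance",
    "read_novel_table",
    "write_novel_table",
]


@dataclass
class NovelTranscript:
    tx_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    rpkm_overall: float
    rpkm_per_replicate: tuple[float, ...]
    nearest_known_distance: float | None = None

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.tx_id}: exon [{s},{e}) invalid")
            if s < prev_end:
                raise ValueError(f"{self.tx_id}: exons overlap or unsorted")
            prev_end = e
        self.exons = tuple(map(tuple, self.exons))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def total_exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class FilterTally:
    n_input: int = 0
    n_kept: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {"expression": 0, "distance": 0, "structure": 0}
    )

    def as_frame(self) -> pd.DataFrame:
        rows = [("kept", self.n_kept)] + sorted(self.rejected.items())
        return pd.DataFrame(rows, columns=["category", "n"])


def span_distance(
    tx: NovelTranscript, known: list[GeneModel] | set[GeneModel]
) -> float:
    """Distance (nt) from the transcript span to the nearest known gene span.

    Strand-agnostic; 0 if any known gene on the same chromosome overlaps the
    transcript; +inf if the chromosome holds no known gene.
    """
    ts, te = tx.span
    best = float("inf")
    for gene in known:
        if gene.chrom != tx.chrom:
            continue
        gs, ge = gene.span
        if ge <= ts:
            d = ts - ge
        elif gs >= te:
            d = gs - te
        else:
            d = 0
        best = min(best, d)
    return best


NOVEL_COLUMNS = ["tx_id", "chrom", "strand", "exons", "rpkm_overall",
                 "rpkm_per_replicate"]


def write_novel_table(candidates: list[NovelTranscript], path) -> None:
    rows = [
        (
            tx.tx_id, tx.chrom, tx.strand,
            ",".join(f"{s}-{e}" for s, e in tx.exons),
            repr(tx.rpkm_overall),
            ",".join(repr(r) for r in tx.rpkm_per_replicate),
        )
        for tx in candidates
    ]
    pd.DataFrame(rows, columns=NOVEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_novel_table(path) -> list[NovelTranscript]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in part.split("-")) for part in row.exons.split(",")
        )
        out.append(
            NovelTranscript(
                tx_id=row.tx_id, chrom=row.chrom, strand=row.strand,
                exons=exons, rpkm_overall=float(row.rpkm_overall),
                rpkm_per_replicate=tuple(
                    float(x) for x in row.rpkm_per_replicate.split(",")
                ),
            )
        )
    return out


def filter_novel(
    candidates: list[NovelTranscript],
    known: list[GeneModel] | set[GeneModel],
    *,
    min_rpkm: float = 0.5,
    min_rep_rpkm: float = 0.25,
    min_dist: float = 10_000,
    min_exons: int = 2,
    min_len: int = 500,
) -> tuple[list[NovelTranscript], FilterTally]:
    """Apply the three filtering criteria; returns survivors and a tally.

    RPKM and length thresholds are strict (">"); exon count and distance are
    inclusive ("at least").  Precomputed ``nearest_known_distance`` on a
    candidate is trusted; otherwise the span distance is computed here.
    """
    for name, value in (
        ("min_rpkm", min_rpkm), ("min_rep_rpkm", min_rep_rpkm),
        ("min_dist", min_dist), ("min_exons", min_exons), ("min_len", min_len),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    kept: list[NovelTranscript] = []
    tally = FilterTally()
    for tx in candidates:
        tally.n_input += 1
        expr_ok = tx.rpkm_overall > min_rpkm and all(
            r > min_rep_rpkm for r in tx.rpkm_per_replicate
        )
        if not expr_ok:
            tally.rejected["expression"] += 1
            continue
        dist = tx.nearest_known_distance
        if dist is None:
            dist = span_distance(tx, known)
        if not dist >= min_dist:
            tally.rejected["distance"] += 1
            continue
        if not (len(tx.exons) >= min_exons and tx.total_exon_length > min_len):
            tally.rejected["structure"] += 1
            continue
        tally.n_kept += 1
        kept.append(tx)
    return kept, tally
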