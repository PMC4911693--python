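"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``.
GTF (1-based inclusive) is converted at the boundary in both directions, so a
write → read round trip is the identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "ChimericRead",
    "SpikeIn",
    "SpikeInPanel",
    "CountTable",
    "GtfParseError",
    "SchemaError",
    "read_gtf",
    "write_gtf",
    "read_chimeric",
    "write_chimeric",
    "read_linear_junctions",
    "write_linear_junctions",
    "read_spikein_table",
    "write_spikein_table",
    "read_count_table",
    "write_count_table",
    "read_circ_table",
    "write_circ_table",
    "read_bed",
    "write_bed",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks a mandatory column."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of exon intervals on one chromosome.

    ``exons`` are 0-based half-open, sorted by genomic start and
    non-overlapping.  Exon ordinals used elsewhere are genomic (index 0 is the
    leftmost exon); transcript orientation is derived from ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    known: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{start},{end}) has end <= start"
                )
            if start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = end
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def transcript_exon_index(self, genomic_index: int) -> int:
        """Map a genomic exon ordinal to its 1-based transcript ordinal."""
        n = len(self.exons)
        if not 0 <= genomic_index < n:
            raise IndexError(genomic_index)
        return genomic_index + 1 if self.strand == "+" else n - genomic_index


@dataclass(frozen=True)
class ChimericRead:
    """One read pair with two aligned segments — raw back-splice evidence.

    ``seg1`` is the segment that appears first in the read; a back-spliced
    pair has ``seg1`` genomically downstream of ``seg2``.  ``mate_interval``
    is the linear alignment of the other read of the pair, if any.
    """

    read_id: str
    sample_id: str
    chrom: str
    seg1: tuple[int, int]
    seg2: tuple[int, int]
    strand: str
    mate_interval: tuple[int, int] | None = None
    mate_linear: bool = False
    mate_chrom: str | None = None


@dataclass(frozen=True)
class SpikeIn:
    species_id: str
    spike_class: str  # "ERCC" or "RGC"
    amount: float  # attomole (ERCC) or molecules (RGC) per lysis reaction
    amount_unit: str  # "attomole" | "molecules"
    length: int  # nt
    polyA_len: int  # nt

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"{self.species_id}: spike-in amount must be > 0")
        if self.spike_class not in ("ERCC", "RGC"):
            raise ValueError(f"unknown spike-in class {self.spike_class!r}")


@dataclass
class SpikeInPanel:
    """The full spike-in mix: ERCC-like dilution series plus the RGC trio."""

    species: tuple[SpikeIn, ...]

    def __post_init__(self) -> None:
        rgc = self.rgc()
        if rgc and len(rgc) != 3:
            raise ValueError("RGC class must contain exactly three species")
        self.species = tuple(self.species)

    def ercc(self) -> list[SpikeIn]:
        return [s for s in self.species if s.spike_class == "ERCC"]

    def rgc(self) -> list[SpikeIn]:
        return [s for s in self.species if s.spike_class == "RGC"]

    def ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def lengths(self) -> pd.Series:
        return pd.Series(
            {s.species_id: s.length for s in self.species}, dtype=float
        )


@dataclass
class CountTable:
    """Unique-read counts for genes + spike-ins across samples.

    ``counts``: DataFrame, features × samples, non-negative integers.
    ``meta``: DataFrame indexed by sample with columns ``total_mapped_reads``
    and ``read_length``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if (self.meta["total_mapped_reads"] <= 0).any():
            raise ValueError("total_mapped_reads must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon features of a GTF file into :class:`GeneModel` objects.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Exons from multiple transcripts of one gene are unioned (overlapping
    intervals merged) so each gene carries one non-redundant exon chain.
    Genes are returned sorted by (chrom, start, gene_id).
    """
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    info_by_gene: dict[str, tuple[str, str, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end1 < start1:
                raise GtfParseError(
                    f"{path}: line {lineno}: end ({end1}) before start ({start1})"
                )
            attrd = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attrd.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id")
            known = attrd.get("gene_status", "KNOWN").upper() != "NOVEL"
            interval = (start1 - 1, end1)  # 1-based inclusive -> 0-based half-open
            exons_by_gene.setdefault(gene_id, []).append(interval)
            prev = info_by_gene.get(gene_id)
            if prev is not None and (prev[0] != chrom or prev[1] != strand):
                raise GtfParseError(
                    f"{path}: line {lineno}: gene {gene_id} spans multiple "
                    "chromosomes or strands"
                )
            info_by_gene[gene_id] = (chrom, strand, known)

    genes = []
    for gene_id, exons in exons_by_gene.items():
        chrom, strand, known = info_by_gene[gene_id]
        genes.append(
            GeneModel(gene_id, chrom, strand, tuple(_merge_intervals(exons)), known)
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in sorted(set(intervals)):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF exon lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            status = "KNOWN" if gene.known else "NOVEL"
            for start, end in gene.exons:
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.1"; '
                    f'gene_status "{status}";'
                )
                fh.write(
                    f"{gene.chrom}\tembryocirc\texon\t{start + 1}\t{end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Chimeric-alignment dialect (stand-in for a fusion aligner's output)

CHIMERIC_COLUMNS = [
    "read_id",
    "sample_id",
    "chrom",
    "seg1_start",
    "seg1_end",
    "seg2_start",
    "seg2_end",
    "strand",
    "mate_chrom",
    "mate_start",
    "mate_end",
    "mate_linear",
]


def read_chimeric(path: str | Path) -> tuple[list[ChimericRead], int]:
    """Read the chimeric-segment TSV.

    Returns ``(records, n_skipped)`` where records whose two segments lie on
    different chromosomes are skipped (trans-chromosomal events are outside
    exonic-circRNA scope) and counted in ``n_skipped``.
    An empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], 0
    missing = [c for c in CHIMERIC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records: list[ChimericRead] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        seg_chrom = row.chrom
        # both segments share the `chrom` column; a pair of segments on two
        # chromosomes is encoded "chrA|chrB" and skipped (trans-chromosomal
        # events are outside exonic-circRNA scope)
        if "|" in seg_chrom:
            n_skipped += 1
            continue
        if row.mate_chrom in ("", "."):
            mate_interval, mate_chrom = None, None
        else:
            mate_interval = (int(row.mate_start), int(row.mate_end))
            mate_chrom = row.mate_chrom
        records.append(
            ChimericRead(
                row.read_id, row.sample_id, seg_chrom,
                (int(row.seg1_start), int(row.seg1_end)),
                (int(row.seg2_start), int(row.seg2_end)),
                row.strand, mate_interval, row.mate_linear == "1", mate_chrom,
            )
        )
    return records, n_skipped


def write_chimeric(records: Sequence[ChimericRead], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.mate_interval is None:
            mate_chrom, mate_start, mate_end = ".", 0, 0
        else:
            mate_chrom = r.mate_chrom if r.mate_chrom is not None else r.chrom
            mate_start, mate_end = r.mate_interval
        rows.append(
            (
                r.read_id, r.sample_id, r.chrom,
                r.seg1[0], r.seg1[1], r.seg2[0], r.seg2[1],
                r.strand, mate_chrom, mate_start, mate_end,
                1 if r.mate_linear else 0,
            )
        )
    pd.DataFrame(rows, columns=CHIMERIC_COLUMNS).to_csv(path, sep="\t", index=False)


LINEAR_JUNCTION_COLUMNS = ["chrom", "pos", "sample_id", "reads"]


def read_linear_junctions(path: str | Path) -> pd.DataFrame:
    """Forward-spliced (linear) junction read counts per splice-site locus."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in LINEAR_JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def write_linear_junctions(df: pd.DataFrame, path: str | Path) -> None:
    df[LINEAR_JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Spike-in table

SPIKEIN_COLUMNS = ["species_id", "class", "amount", "amount_unit", "length", "polyA_len"]


def read_spikein_table(path: str | Path) -> SpikeInPanel:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPIKEIN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    species = tuple(
        SpikeIn(
            str(row.species_id), str(row["class"]), float(row.amount),
            str(row.amount_unit), int(row.length), int(row.polyA_len),
        )
        for _, row in df.iterrows()
    )
    return SpikeInPanel(species)


def write_spikein_table(panel: SpikeInPanel, path: str | Path) -> None:
    rows = [
        (s.species_id, s.spike_class, repr(s.amount), s.amount_unit, s.length, s.polyA_len)
        for s in panel.species
    ]
    pd.DataFrame(rows, columns=SPIKEIN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count table + sidecar metadata

def read_count_table(path: str | Path, meta_path: str | Path) -> CountTable:
    counts = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    for col in ("total_mapped_reads", "read_length"):
        if col not in meta.columns:
            raise SchemaError(f"{meta_path}: missing mandatory column {col!r}")
    return CountTable(counts, meta)


def write_count_table(table: CountTable, path: str | Path, meta_path: str | Path) -> None:
    table.counts.rename_axis("feature_id").to_csv(path, sep="\t")
    table.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# circRNA table (BED-dialect, one row per circRNA per sample)

CIRC_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "strand",
    "hosting_gene",
    "exon_indices",
    "sample_id",
    "back_reads",
    "forward_reads",
    "exon_position_class",
    "upstream_evidence",
]


def write_circ_table(records: Sequence, path: str | Path) -> None:
    """Serialize annotated circRNA records, one row per circRNA per sample.

    Coordinates stay 0-based half-open (BED convention).  Re-reading
    reproduces the records exactly; zero forward reads are written as 0.
    """
    rows = []
    for rec in records:
        for sample in sorted(rec.back_reads):
            rows.append(
                (
                    rec.chrom, rec.acceptor_pos, rec.donor_pos,
                    f"{rec.hosting_gene}:{rec.exon_indices[0]}-{rec.exon_indices[-1]}",
                    rec.strand, rec.hosting_gene,
                    ",".join(map(str, rec.exon_indices)),
                    sample, rec.back_reads[sample],
                    rec.forward_reads.get(sample, 0),
                    rec.exon_position_class,
                    1 if rec.upstream_evidence else 0,
                )
            )
    pd.DataFrame(rows, columns=CIRC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_circ_table(path: str | Path) -> list:
    from .circcall import CircRNARecord  # circular import guard

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    if df.empty and list(df.columns) != CIRC_COLUMNS:
        raise SchemaError(f"{path}: bad header")
    records: dict[tuple, CircRNARecord] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.start), int(row.end), row.strand)
        if key not in records:
            records[key] = CircRNARecord(
                chrom=row.chrom,
                strand=row.strand,
                acceptor_pos=int(row.start),
                donor_pos=int(row.end),
                hosting_gene=row.hosting_gene,
                exon_indices=tuple(int(x) for x in str(row.exon_indices).split(",")),
                back_reads={},
                forward_reads={},
                exon_position_class=row.exon_position_class,
                upstream_evidence=bool(int(row.upstream_evidence)),
            )
        rec = records[key]
        rec.back_reads[row.sample_id] = int(row.back_reads)
        rec.forward_reads[row.sample_id] = int(row.forward_reads)
    return list(records.values())


# ---------------------------------------------------------------------------
# BED (repeat annotation)

def read_bed(path: str | Path) -> pd.DataFrame:
    """BED6 (or BED3+) repeat annotation → DataFrame[chrom, start, end, name]."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if "name" not in df.columns:
        df["name"] = "."
    df["chrom"] = df["chrom"].astype(str)
    return df[["chrom", "start", "end", "name"]]


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )
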