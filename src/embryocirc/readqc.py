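"""Raw-read cleaning: quality filters, adaptor/poly-run trimming, AT gate.

Rules, applied in order to each read:

1. discard if more than ``lowqual_frac`` of the bases have Phred quality
   <= ``qual_threshold``;
2. discard if more than ``n_frac`` of the bases are undetermined (N);
3. trim a 3' adaptor match (the read is cut at the start of the leftmost
   adaptor occurrence);
4. trim one terminal poly(A) run (3') or poly(T) run (5') of at least
   ``polyrun`` identical bases;
5. discard if the remaining sequence is more than ``at_frac`` A/T, or is
   shorter than ``min_len``.

All fraction thresholds are strict inequalities.  Trimming precedes the
AT-content test, which maximizes the number of retained reads.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Iterator

__all__ = ["QCReport", "FastqRecord", "clean_reads", "clean_read_pairs",
           "read_fastq", "write_fastq"]

FastqRecord = tuple[str, str, str]  # (id, sequence, quality string)


@dataclass
class QCReport:
    """Per-run accounting of the read-cleaning stage.

    Conservation holds by construction:
    ``n_input == n_output + n_discarded_lowqual + n_discarded_undetermined
    + n_discarded_AT``.  The two ``n_trimmed_*`` counters tally reads that
    were trimmed but (possibly) retained, so they overlap with ``n_output``.
    """

    n_input: int = 0
    n_discarded_lowqual: int = 0
    n_discarded_undetermined: int = 0
    n_trimmed_adaptor: int = 0
    n_trimmed_polyAT: int = 0
    n_discarded_AT: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def check_conservation(self) -> bool:
        return self.n_input == (
            self.n_output
            + self.n_discarded_lowqual
            + self.n_discarded_undetermined
            + self.n_discarded_AT
        )


def _phred(qual: str, offset: int) -> list[int]:
    return [ord(c) - offset for c in qual]


def _trim_adaptor(seq: str, qual: str, adaptors: list[str]) -> tuple[str, str, bool]:
    cut = len(seq)
    for adaptor in adaptors:
        if not adaptor:
            continue
        pos = seq.find(adaptor)
        if pos != -1:
            cut = min(cut, pos)
    if cut < len(seq):
        return seq[:cut], qual[:cut], True
    return seq, qual, False


def _trim_polyruns(seq: str, qual: str, polyrun: int) -> tuple[str, str, bool]:
    """Remove one maximal terminal run: >= polyrun T at 5' or A at 3'."""
    trimmed = False
    i = 0
    while i < len(seq) and seq[i] == "T":
        i += 1
    if i >= polyrun:
        seq, qual, trimmed = seq[i:], qual[i:], True
    j = len(seq)
    while j > 0 and seq[j - 1] == "A":
        j -= 1
    if len(seq) - j >= polyrun:
        seq, qual, trimmed = seq[:j], qual[:j], True
    return seq, qual, trimmed


def clean_reads(
    reads: Iterable[FastqRecord],
    adaptors: list[str] | None = None,
    *,
    qual_threshold: int = 5,
    lowqual_frac: float = 0.5,
    n_frac: float = 0.1,
    at_frac: float = 0.8,
    polyrun: int = 24,
    min_len: int = 30,
    phred_offset: int = 33,
) -> tuple[list[FastqRecord], QCReport]:
    """Clean a stream of FASTQ records; returns (kept records, report)."""
    if phred_offset not in (33, 64):
        raise ValueError(f"unknown quality encoding offset {phred_offset}")
    adaptors = adaptors or []
    report = QCReport()
    kept: list[FastqRecord] = []
    for read_id, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"read {read_id}: sequence/quality length mismatch")
        report.n_input += 1
        n = len(seq)
        if n == 0:
            report.n_discarded_AT += 1
            continue
        quals = _phred(qual, phred_offset)
        if sum(q <= qual_threshold for q in quals) > lowqual_frac * n:
            report.n_discarded_lowqual += 1
            continue
        if sum(b == "N" for b in seq.upper()) > n_frac * n:
            report.n_discarded_undetermined += 1
            continue
        seq, qual, adaptor_trimmed = _trim_adaptor(seq, qual, adaptors)
        if adaptor_trimmed:
            report.n_trimmed_adaptor += 1
        seq, qual, poly_trimmed = _trim_polyruns(seq, qual, polyrun)
        if poly_trimmed:
            report.n_trimmed_polyAT += 1
        m = len(seq)
        at = sum(b in "AT" for b in seq.upper())
        if m < min_len or at > at_frac * m:
            report.n_discarded_AT += 1
            continue
        report.n_output += 1
        kept.append((read_id, seq, qual))
    return kept, report


def clean_read_pairs(
    r1: Iterable[FastqRecord],
    r2: Iterable[FastqRecord],
    adaptors: list[str] | None = None,
    **kwargs,
) -> tuple[list[FastqRecord], list[FastqRecord], QCReport, QCReport]:
    """Clean both mates; a pair is kept only if both reads survive."""
    kept1, rep1 = clean_reads(list(r1), adaptors, **kwargs)
    kept2, rep2 = clean_reads(list(r2), adaptors, **kwargs)
    ids1 = {r[0].rstrip("/1 ") for r in kept1}
    ids2 = {r[0].rstrip("/2 ") for r in kept2}
    shared = ids1 & ids2
    out1 = [r for r in kept1 if r[0].rstrip("/1 ") in shared]
    out2 = [r for r in kept2 if r[0].rstrip("/2 ") in shared]
    return out1, out2, rep1, rep2


def read_fastq(path) -> Iterator[FastqRecord]:
    """Stream (id, seq, qual) tuples from an uncompressed FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
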