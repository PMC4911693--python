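import numpy as np
import pytest

from embryocirc.circcall import (
    CircRNARecord,
    annotate_backsplices,
    attach_forward_reads,
    classify_exon_position,
    filter_support,
)
from embryocirc.ioformats import ChimericRead, GeneModel

import pandas as pd


def _backsplice_read(gene, lo, hi, rid="r1", sample="s1", mate="inside",
                     offset=0):
    """A chimeric read joining end of exon `hi` to start of exon `lo`."""
    acceptor = gene.exons[lo][0]
    donor = gene.exons[hi][1]
    if mate == "inside":
        mate_iv = (acceptor + 5, min(donor, acceptor + 80))
    elif mate == "outside":
        mate_iv = (donor + 5000, donor + 5100)
    else:
        mate_iv = None
    return ChimericRead(
        read_id=rid, sample_id=sample, chrom=gene.chrom,
        seg1=(donor - 40 + offset, donor + offset),
        seg2=(acceptor + offset, acceptor + 40 + offset),
        strand=gene.strand,
        mate_interval=mate_iv, mate_linear=mate_iv is not None,
        mate_chrom=gene.chrom if mate_iv is not None else None,
    )


class TestAnnotate:
    def test_exact_junction_supported(self, plus_gene):
        read = _backsplice_read(plus_gene, 1, 2)
        cands, diag = annotate_backsplices([read], [plus_gene])
        assert len(cands) == 1
        cand = cands[0]
        assert cand.acceptor_pos == plus_gene.exons[1][0]
        assert cand.donor_pos == plus_gene.exons[2][1]
        assert cand.support == {"s1": {"r1"}}
        assert diag.n_supporting == 1

    def test_one_nt_offset_rejected_at_zero_tolerance(self, plus_gene):
        read = _backsplice_read(plus_gene, 1, 2, offset=1)
        cands, diag = annotate_backsplices([read], [plus_gene])
        assert cands == [] and diag.n_no_splice_match == 1

    def test_one_nt_offset_recovered_with_tolerance(self, plus_gene):
        read = _backsplice_read(plus_gene, 1, 2, offset=1)
        cands, _ = annotate_backsplices([read], [plus_gene], tol=1)
        assert len(cands) == 1

    def test_segments_in_two_genes_rejected(self, plus_gene):
        other = GeneModel(
            "gother", "chr1", "+",
            tuple((s + 100_000, e + 100_000) for s, e in plus_gene.exons),
        )
        read = ChimericRead(
            "r1", "s1", "chr1",
            seg1=(other.exons[2][1] - 40, other.exons[2][1]),
            seg2=(plus_gene.exons[1][0], plus_gene.exons[1][0] + 40),
            strand="+", mate_interval=None, mate_linear=False,
        )
        cands, diag = annotate_backsplices([read], [plus_gene, other])
        assert cands == [] and diag.n_no_splice_match == 1

    def test_mate_outside_circle_span_rejected(self, plus_gene):
        read = _backsplice_read(plus_gene, 1, 2, mate="outside")
        cands, diag = annotate_backsplices([read], [plus_gene])
        assert cands == [] and diag.n_mate_rejected == 1

    def test_mate_on_other_chromosome_rejected(self, plus_gene):
        read = _backsplice_read(plus_gene, 1, 2)
        read = ChimericRead(
            read.read_id, read.sample_id, read.chrom, read.seg1, read.seg2,
            read.strand, read.mate_interval, True, "chr9",
        )
        cands, diag = annotate_backsplices([read], [plus_gene])
        assert cands == [] and diag.n_mate_rejected == 1

    def test_missing_mate_accepted(self, plus_gene):
        read = _backsplice_read(plus_gene, 1, 2, mate=None)
        cands, _ = annotate_backsplices([read], [plus_gene])
        assert len(cands) == 1

    def test_negative_tolerance_rejected(self, plus_gene):
        with pytest.raises(ValueError):
            annotate_backsplices([], [plus_gene], tol=-1)


class TestFilterSupport:
    def test_per_sample_threshold(self, plus_gene):
        reads = [
            _backsplice_read(plus_gene, 1, 2, rid="a", sample="A"),
            _backsplice_read(plus_gene, 1, 2, rid="b", sample="B"),
            _backsplice_read(plus_gene, 1, 2, rid="c", sample="B"),
            _backsplice_read(plus_gene, 1, 2, rid="d", sample="B"),
        ]
        cands, _ = annotate_backsplices(reads, [plus_gene])
        (rec,) = filter_support(cands, min_reads=2)
        assert rec.back_reads == {"B": 3}

    def test_exactly_two_reads_reported(self, plus_gene):
        reads = [
            _backsplice_read(plus_gene, 1, 2, rid=r, sample="A")
            for r in ("a", "b")
        ]
        cands, _ = annotate_backsplices(reads, [plus_gene])
        (rec,) = filter_support(cands)
        assert rec.back_reads == {"A": 2}

    def test_min_reads_one_reports_everything(self, plus_gene):
        reads = [_backsplice_read(plus_gene, 1, 2, rid="a", sample="A")]
        cands, _ = annotate_backsplices(reads, [plus_gene])
        assert len(filter_support(cands, min_reads=1)) == 1

    def test_min_reads_zero_invalid(self):
        with pytest.raises(ValueError):
            filter_support([], min_reads=0)

    def test_duplicate_read_ids_counted_once(self, plus_gene):
        reads = [
            _backsplice_read(plus_gene, 1, 2, rid="dup", sample="A"),
            _backsplice_read(plus_gene, 1, 2, rid="dup", sample="A"),
        ]
        cands, _ = annotate_backsplices(reads, [plus_gene])
        assert filter_support(cands, min_reads=2) == []


class TestExonPosition:
    def _record(self, gene, lo, hi):
        return CircRNARecord(
            chrom=gene.chrom, strand=gene.strand,
            acceptor_pos=gene.exons[lo][0], donor_pos=gene.exons[hi][1],
            hosting_gene=gene.gene_id,
            exon_indices=tuple(range(lo, hi + 1)), back_reads={"s": 2},
        )

    def test_internal_circle(self, plus_gene):
        rec = classify_exon_position(self._record(plus_gene, 1, 3), plus_gene)
        assert rec.exon_position_class == "internal"

    def test_last_exon_circle(self, plus_gene):
        rec = classify_exon_position(self._record(plus_gene, 2, 4), plus_gene)
        assert rec.exon_position_class == "last_exon"

    def test_first_exon_with_upstream_reads(self, plus_gene):
        rec = classify_exon_position(
            self._record(plus_gene, 0, 2), plus_gene,
            upstream_coverage=np.full(1000, 3.0),
        )
        assert rec.exon_position_class == "first_exon"
        assert rec.upstream_evidence

    def test_minus_strand_first_exon_is_genomic_last(self, minus_gene):
        n = minus_gene.n_exons
        rec = classify_exon_position(
            self._record(minus_gene, 1, n - 1), minus_gene
        )
        assert rec.exon_position_class == "first_exon"

    def test_foreign_record_rejected(self, plus_gene, minus_gene):
        with pytest.raises(ValueError):
            classify_exon_position(self._record(plus_gene, 1, 2), minus_gene)


def test_forward_reads_averaged_over_both_loci(plus_gene):
    rec = CircRNARecord(
        chrom="chr1", strand="+",
        acceptor_pos=plus_gene.exons[1][0], donor_pos=plus_gene.exons[2][1],
        hosting_gene="gplus", exon_indices=(1, 2), back_reads={"s1": 3},
    )
    linear = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [rec.acceptor_pos, rec.donor_pos],
            "sample_id": ["s1", "s1"],
            "reads": [10, 14],
        }
    )
    attach_forward_reads([rec], linear)
    assert rec.forward_reads == {"s1": 12}


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_circles(reads, genes, tol=0, min_reads=2):
    """Test every read against every exon pair of every gene."""
    support = {}
    for read in reads:
        down, up = read.seg1, read.seg2
        if down[0] <= up[0]:
            continue
        matches = set()
        for gene in genes:
            if gene.chrom != read.chrom:
                continue
            for i in range(gene.n_exons):
                for j in range(i, gene.n_exons):
                    if (
                        abs(up[0] - gene.exons[i][0]) <= tol
                        and abs(down[1] - gene.exons[j][1]) <= tol
                    ):
                        matches.add(
                            (read.chrom, gene.exons[i][0], gene.exons[j][1],
                             gene.strand)
                        )
        if len(matches) != 1:
            continue
        key = matches.pop()
        if read.mate_interval is not None:
            mate_chrom = read.mate_chrom or read.chrom
            ms, me = read.mate_interval
            if (
                mate_chrom != read.chrom or not read.mate_linear
                or ms < key[1] or me > key[2]
            ):
                continue
        support.setdefault(key, {}).setdefault(read.sample_id, set()).add(
            read.read_id
        )
    out = set()
    for key, per_sample in support.items():
        for sample, ids in per_sample.items():
            if len(ids) >= min_reads:
                out.add((key, sample, len(ids)))
    return out


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    genes = []
    pos = 1000
    for gi in range(int(rng.integers(2, 6))):
        n_ex = int(rng.integers(3, 7))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(80, 250))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 800))
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(GeneModel(f"g{gi}", "chr1", strand, tuple(exons)))
        pos += int(rng.integers(2000, 8000))
    reads = []
    n_reads = int(rng.integers(50, 400))
    for ri in range(n_reads):
        gene = genes[int(rng.integers(len(genes)))]
        i = int(rng.integers(gene.n_exons))
        j = int(rng.integers(i, gene.n_exons))
        acceptor, donor = gene.exons[i][0], gene.exons[j][1]
        offset = int(rng.choice([0, 0, 0, 1, -1, 3]))
        kind = rng.random()
        if kind < 0.6:
            mate = (acceptor + 2, max(acceptor + 4, donor - 2))
            mate_linear, mate_chrom = True, gene.chrom
        elif kind < 0.8:
            mate = (donor + 3000, donor + 3100)
            mate_linear, mate_chrom = True, gene.chrom
        else:
            mate, mate_linear, mate_chrom = None, False, None
        reads.append(
            ChimericRead(
                read_id=f"r{ri}", sample_id=f"s{int(rng.integers(3))}",
                chrom="chr1",
                seg1=(donor - 35 + offset, donor + offset),
                seg2=(acceptor + offset, acceptor + 35 + offset),
                strand=gene.strand,
                mate_interval=mate, mate_linear=mate_linear,
                mate_chrom=mate_chrom,
            )
        )
    return reads, genes


@pytest.mark.parametrize("seed", range(12))
def test_caller_matches_brute_force_enumeration(seed):
    reads, genes = _random_instance(seed)
    cands, _ = annotate_backsplices(reads, genes)
    records = filter_support(cands, min_reads=2)
    got = {
        (rec.key, sample, n)
        for rec in records
        for sample, n in rec.back_reads.items()
    }
    assert got == brute_force_circles(reads, genes)


def test_strand_symmetry_of_called_circles(plus_gene):
    """Mirroring the locus (flip strand + coordinates) maps circles 1:1."""
    L = 1_000_000
    reads = [
        _backsplice_read(plus_gene, 1, 3, rid=r, sample="A")
        for r in ("a", "b", "c")
    ]
    mirror_gene = GeneModel(
        plus_gene.gene_id, plus_gene.chrom, "-",
        tuple(sorted((L - e, L - s) for s, e in plus_gene.exons)),
    )
    mirror_reads = [
        ChimericRead(
            r.read_id, r.sample_id, r.chrom,
            seg1=(L - r.seg2[1], L - r.seg2[0]),
            seg2=(L - r.seg1[1], L - r.seg1[0]),
            strand="-",
            mate_interval=(L - r.mate_interval[1], L - r.mate_interval[0]),
            mate_linear=True, mate_chrom=r.chrom,
        )
        for r in reads
    ]
    orig = filter_support(annotate_backsplices(reads, [plus_gene])[0])
    mirr = filter_support(annotate_backsplices(mirror_reads, [mirror_gene])[0])
    assert len(orig) == len(mirr) == 1
    assert {(L - orig[0].donor_pos, L - orig[0].acceptor_pos)} == {
        (mirr[0].acceptor_pos, mirr[0].donor_pos)
    }
    assert orig[0].back_reads == mirr[0].back_reads
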