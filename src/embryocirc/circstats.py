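"""Junction-level circular/linear statistics and circRNA genomic features.

The circ ratio at a junction is back/(back+forward) read counts; the
circular-to-linear ratio (CLR) is back/forward, i.e. ratio/(1-ratio).
Feature extraction covers exon counts and lengths, flanking-intron lengths
(the introns immediately adjacent to the back-spliced exons in transcript
orientation), hosting-gene isoform counts, and repeat-element (Alu-like)
enrichment in flanking vs control introns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .circcall import CircRNARecord
from .ioformats import GeneModel

__all__ = [
    "JunctionMetrics",
    "CircFeatureSet",
    "AluEnrichmentResult",
    "junction_metrics",
    "discounted_rpkm",
    "flanking_features",
    "sample_control_introns",
    "alu_enrichment",
]


@dataclass(frozen=True)
class JunctionMetrics:
    """Circular/linear read statistics at one back-splice junction."""

    back: int
    forward: int
    circ_ratio: float | None
    clr: float | None
    clr_infinite: bool = False


def junction_metrics(back: int, forward: int) -> JunctionMetrics:
    """Circ ratio and CLR from back- and forward-spliced read counts.

    Both are undefined (None) with no reads at all; CLR is flagged infinite
    when circular reads exist without any linear support.
    """
    if back < 0 or forward < 0:
        raise ValueError("read counts must be non-negative")
    total = back + forward
    if total == 0:
        return JunctionMetrics(back, forward, None, None)
    ratio = back / total
    if forward == 0:
        return JunctionMetrics(back, forward, ratio, None, clr_infinite=True)
    return JunctionMetrics(back, forward, ratio, back / forward)


def discounted_rpkm(rpkm: float, circ_ratio: float) -> float:
    """Linear-only expression of a hosting gene: RPKM x (1 - circ ratio)."""
    if not 0 <= circ_ratio <= 1:
        raise ValueError("circ_ratio must lie in [0, 1]")
    return rpkm * (1 - circ_ratio)


@dataclass
class CircFeatureSet:
    """Genomic features of a circRNA set.

    ``per_circ``: one row per circle — n_exons, total exon length, flanking
    intron lengths (NaN where the circle touches a terminal exon and the
    intron does not exist).  ``per_gene``: circRNA isoform counts with the
    hot-spot flag (>= 2 isoforms).
    """

    per_circ: pd.DataFrame
    per_gene: pd.DataFrame

    @property
    def hotspot_genes(self) -> list[str]:
        return self.per_gene.index[self.per_gene["hotspot"]].tolist()


def flanking_features(
    circs: list[CircRNARecord], genes: list[GeneModel] | set[GeneModel]
) -> CircFeatureSet:
    """Per-circle exon/intron features and per-gene isoform counts.

    The upstream flanking intron is the intron immediately 5' (transcript
    orientation) of the acceptor exon; downstream immediately 3' of the
    donor exon.  On the minus strand these swap genomic sides.
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for rec in circs:
        gene = by_id.get(rec.hosting_gene)
        if gene is None:
            raise ValueError(f"hosting gene {rec.hosting_gene} not in annotation")
        lo, hi = rec.exon_indices[0], rec.exon_indices[-1]
        introns = gene.introns()
        # genomic-left intron precedes exon `lo`; genomic-right follows `hi`
        left = introns[lo - 1] if lo >= 1 else None
        right = introns[hi] if hi < len(introns) else None
        if gene.strand == "+":
            upstream, downstream = left, right
        else:
            upstream, downstream = right, left
        exon_lens = [e - s for s, e in (gene.exons[i] for i in rec.exon_indices)]
        rows.append(
            {
                "circ_id": rec.circ_id,
                "hosting_gene": rec.hosting_gene,
                "n_exons": len(rec.exon_indices),
                "total_exon_length": int(sum(exon_lens)),
                "exon_lengths": ",".join(map(str, exon_lens)),
                "upstream_intron_length": (
                    upstream[1] - upstream[0] if upstream else math.nan
                ),
                "downstream_intron_length": (
                    downstream[1] - downstream[0] if downstream else math.nan
                ),
                "upstream_intron_start": upstream[0] if upstream else -1,
                "upstream_intron_end": upstream[1] if upstream else -1,
                "downstream_intron_start": downstream[0] if downstream else -1,
                "downstream_intron_end": downstream[1] if downstream else -1,
                "chrom": rec.chrom,
                "exon_position_class": rec.exon_position_class,
            }
        )
    per_circ = pd.DataFrame(rows)
    if per_circ.empty:
        per_gene = pd.DataFrame(columns=["n_isoforms", "hotspot"])
    else:
        iso = per_circ.groupby("hosting_gene")["circ_id"].nunique()
        per_gene = pd.DataFrame({"n_isoforms": iso, "hotspot": iso >= 2})
    return CircFeatureSet(per_circ, per_gene)


def sample_control_introns(
    genes: list[GeneModel],
    hosting_genes: set[str],
    n: int,
    seed: int,
    *,
    expressed_genes: set[str] | None = None,
) -> list[tuple[str, int, int]]:
    """Seeded uniform sample of ``n`` introns from expressed non-hosting genes.

    ``expressed_genes`` (e.g. the RPKM >= 1 set) restricts the pool; None
    means every non-hosting gene is eligible.
    """
    pool: list[tuple[str, int, int]] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.gene_id in hosting_genes:
            continue
        if expressed_genes is not None and gene.gene_id not in expressed_genes:
            continue
        for s, e in gene.introns():
            pool.append((gene.chrom, s, e))
    if not pool:
        raise ValueError("no control introns available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [pool[i] for i in sorted(idx)]


@dataclass
class AluEnrichmentResult:
    flanking_counts: np.ndarray
    control_counts: np.ndarray
    flanking_density_per_kb: float
    control_density_per_kb: float
    p_value: float


def alu_enrichment(
    flanking_introns: list[tuple[str, int, int]],
    control_introns: list[tuple[str, int, int]],
    repeats: pd.DataFrame,
    seed: int = 0,
) -> AluEnrichmentResult:
    """Repeat-element load in flanking vs control introns.

    A repeat counts toward an intron when their intervals intersect.
    Densities are total repeats per kb of intron; the p-value is a two-sided
    Wilcoxon rank-sum test on per-intron counts.  If the control set is
    larger than the flanking set it is subsampled (seeded) to match.
    """
    if not control_introns:
        raise ValueError("control intron set is empty")
    if len(control_introns) > len(flanking_introns):
        rng = np.random.default_rng(seed)
        idx = rng.choice(
            len(control_introns), size=len(flanking_introns), replace=False
        )
        control_introns = [control_introns[i] for i in sorted(idx)]
    trees: dict[str, IntervalTree] = {}
    for row in repeats.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end)
        )

    def count(introns: list[tuple[str, int, int]]) -> np.ndarray:
        out = np.zeros(len(introns), dtype=int)
        for i, (chrom, s, e) in enumerate(introns):
            tree = trees.get(str(chrom))
            if tree is not None:
                out[i] = len(tree.overlap(s, e))
        return out

    fl = count(flanking_introns)
    ct = count(control_introns)
    fl_len = sum(e - s for _, s, e in flanking_introns) / 1e3
    ct_len = sum(e - s for _, s, e in control_introns) / 1e3
    stat = stats.ranksums(fl, ct)
    return AluEnrichmentResult(
        flanking_counts=fl,
        control_counts=ct,
        flanking_density_per_kb=float(fl.sum() / fl_len) if fl_len else math.nan,
        control_density_per_kb=float(ct.sum() / ct_len) if ct_len else math.nan,
        p_value=float(stat.pvalue),
    )
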