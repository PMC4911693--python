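"""RPKM and dual spike-in absolute quantification of mRNA and circRNA copies.

The absolute quantification combines two spike-in classes with different
capture behaviour:

* an ERCC-like dilution series of known molar amounts (attomole per lysis
  reaction) anchors a per-sample log-log regression of RPKM on amount, which
  is inverted over all genes and summed to an ERCC-based total;
* an RGC-like trio of polyA-tailed species of known molecule counts gives a
  direct ratio estimate (total RPKM / species RPKM x spiked molecules,
  averaged over detected species);
* a final cross-sample regression of the RGC-based on the ERCC-based totals
  (both log10) yields the combined per-sample copy number as the fitted
  value at the sample's ERCC-based estimate.

circRNA copy numbers are derived from the circular-junction RPKM mass
relative to the total gene RPKM mass, scaled by the mRNA copy number.  The
junction "length" of a circle is the effective span a back-splice junction
read can occupy: (read length - anchor) x 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ioformats import CountTable, SpikeInPanel

__all__ = [
    "CopyEstimate",
    "ErccQCResult",
    "MOLECULES_PER_ATTOMOLE",
    "compute_rpkm",
    "ercc_total_copies",
    "rgc_total_copies",
    "combine_copy_estimates",
    "effective_circ_length",
    "circ_rpkm",
    "circ_copy_number",
    "subsample_counts",
    "ercc_qc",
    "estimate_sample_copies",
]

#: molecules per attomole (Avogadro constant x 1e-18)
MOLECULES_PER_ATTOMOLE = 6.02214e5


@dataclass
class CopyEstimate:
    """Per-sample absolute copy numbers and the ERCC regression behind them."""

    sample_id: str
    ercc_based_copies: float
    rgc_based_copies: float
    final_copies: float = float("nan")
    circ_copies: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")


@dataclass
class ErccQCResult:
    """Spike-in reproducibility check: retained species and Pearson matrix."""

    retained: list[str]
    pearson: pd.DataFrame | None
    ok: bool
    message: str = ""

    @property
    def mean_offdiag(self) -> float:
        if self.pearson is None or len(self.pearson) < 2:
            return float("nan")
        m = self.pearson.values
        n = m.shape[0]
        return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def compute_rpkm(counts: CountTable, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads.

    ``RPKM = count / (length/1e3) / (total_mapped_reads/1e6)`` per sample;
    zero counts give zero RPKM.
    """
    lengths = lengths.reindex(counts.counts.index)
    missing = lengths.index[lengths.isna()].tolist()
    if missing:
        raise ValueError(f"features missing length: {missing[:10]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"features with non-positive length: {bad[:10]}")
    mapped_millions = counts.meta.loc[counts.samples, "total_mapped_reads"] / 1e6
    if (mapped_millions <= 0).any():
        raise ValueError("total_mapped_reads must be positive")
    len_kb = lengths / 1e3
    return counts.counts.div(len_kb, axis=0).div(mapped_millions, axis=1)


def ercc_total_copies(
    ercc_rpkm: pd.Series,
    panel: SpikeInPanel,
    gene_rpkm: pd.Series,
    *,
    min_attomole: float = 0.001,
    min_points: int = 3,
) -> tuple[tuple[float, float], float]:
    """ERCC-anchored total mRNA copy number for one sample.

    Ordinary least squares of log10 RPKM on log10 attomole over ERCC species
    with amount strictly above ``min_attomole`` and positive RPKM; the fitted
    line is solved for attomole at every gene's RPKM (zero-RPKM genes
    contribute zero), summed, and converted to molecules.

    Returns ``((slope, intercept), molecules)``.
    """
    amounts = pd.Series(
        {s.species_id: s.amount for s in panel.ercc()}, dtype=float
    )
    common = amounts.index.intersection(ercc_rpkm.index)
    amounts = amounts.loc[common]
    rpkm = ercc_rpkm.loc[common]
    usable = (amounts > min_attomole) & (rpkm > 0)
    if int(usable.sum()) < min_points:
        raise ValueError(
            f"ERCC regression needs >= {min_points} species above "
            f"{min_attomole} attomole with positive RPKM; got {int(usable.sum())}"
        )
    x = np.log10(amounts[usable].values)
    y = np.log10(rpkm[usable].values)
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope <= 0:
        raise ValueError("ERCC regression slope non-positive; capture model invalid")
    pos = gene_rpkm[gene_rpkm > 0]
    # invert log10(RPKM) = slope*log10(attomole) + intercept per gene
    attomoles = 10 ** ((np.log10(pos.values) - intercept) / slope)
    molecules = float(attomoles.sum() * MOLECULES_PER_ATTOMOLE)
    return (slope, intercept), molecules


def rgc_total_copies(
    rgc_rpkm: pd.Series,
    spiked_molecules: pd.Series,
    total_refseq_rpkm: float,
) -> float:
    """RGC-anchored total: mean over detected species of
    (total RPKM / species RPKM) x spiked molecules."""
    common = spiked_molecules.index.intersection(rgc_rpkm.index)
    rpkm = rgc_rpkm.loc[common]
    detected = rpkm[rpkm > 0]
    if detected.empty:
        raise ValueError("no RGC species with positive RPKM")
    estimates = total_refseq_rpkm / detected * spiked_molecules.loc[detected.index]
    return float(estimates.mean())


def combine_copy_estimates(
    ercc_based: pd.Series, rgc_based: pd.Series, *, min_samples: int = 3
) -> pd.Series:
    """Combined per-sample totals from the two spike-in classes.

    Regresses log10(RGC-based) on log10(ERCC-based) over all samples with
    both estimates positive; a sample's final copy number is the fitted
    value at its ERCC-based estimate, back-transformed.
    """
    paired = pd.DataFrame({"ercc": ercc_based, "rgc": rgc_based}).dropna()
    paired = paired[(paired > 0).all(axis=1)]
    if len(paired) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples with both estimates positive; "
            f"got {len(paired)}"
        )
    x = np.log10(paired["ercc"].values)
    y = np.log10(paired["rgc"].values)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regression: all ERCC-based estimates equal")
    fit = stats.linregress(x, y)
    final = 10 ** (fit.slope * np.log10(ercc_based.astype(float)) + fit.intercept)
    return pd.Series(final, index=ercc_based.index, name="final_copies")


def effective_circ_length(read_length: int, anchor: int = 25) -> int:
    """Effective junction span of a back-splice read: (read_length - anchor) x 2.

    A junction read must keep ``anchor`` nt on one side of the back-splice,
    so it can start up to ``read_length - anchor`` nt away in each direction;
    with 100-bp reads the effective length is 150 bp.
    """
    if read_length <= anchor:
        raise ValueError(
            f"read_length ({read_length}) must exceed anchor ({anchor})"
        )
    return (read_length - anchor) * 2


def circ_rpkm(
    junction_reads: pd.Series | float,
    read_length: int,
    total_mapped_reads: float,
    anchor: int = 25,
):
    """Per-circle RPKM with the effective junction span as the length term."""
    eff_len = effective_circ_length(read_length, anchor)
    return junction_reads / (eff_len / 1e3) / (total_mapped_reads / 1e6)


def circ_copy_number(
    circ_rpkm_sum: float, refseq_rpkm_sum: float, mrna_copies: float
) -> float:
    """circRNA copies = (sum of circle RPKM / sum of gene RPKM) x mRNA copies."""
    if refseq_rpkm_sum <= 0:
        raise ValueError("refseq_rpkm_sum must be positive")
    return circ_rpkm_sum / refseq_rpkm_sum * mrna_copies


def subsample_counts(counts: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample column to ``depth`` reads without replacement.

    Each column is drawn from a multivariate hypergeometric distribution on
    its feature counts, so column totals equal ``depth`` exactly and the
    draw is reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    new = {}
    for sample in counts.samples:
        col = counts.counts[sample].to_numpy()
        total = int(col.sum())
        if depth > total:
            raise ValueError(
                f"sample {sample}: depth {depth} exceeds total {total}"
            )
        new[sample] = rng.multivariate_hypergeometric(col.astype(np.int64), depth)
    sub = pd.DataFrame(new, index=counts.counts.index)[counts.samples]
    meta = counts.meta.copy()
    meta.loc[counts.samples, "total_mapped_reads"] = depth
    return CountTable(sub, meta)


def ercc_qc(
    ercc_rpkm: pd.DataFrame, *, min_rpkm: float = 1.0, min_samples: int = 3
) -> ErccQCResult:
    """Technical-error check on the ERCC panel.

    A species is retained iff its RPKM is at least ``min_rpkm`` in at least
    ``min_samples`` samples ("more than two"); the pairwise sample Pearson
    correlation is computed on retained species.  No retained species yields
    a failure report, not an exception.
    """
    if ercc_rpkm.shape[1] < 2:
        raise ValueError("ercc_qc needs at least two samples")
    keep = (ercc_rpkm >= min_rpkm).sum(axis=1) >= min_samples
    retained = ercc_rpkm.index[keep].tolist()
    if not retained:
        return ErccQCResult([], None, ok=False, message="no ERCC species retained")
    sub = ercc_rpkm.loc[retained]
    return ErccQCResult(retained, sub.corr(method="pearson"), ok=True)


def estimate_sample_copies(
    counts: CountTable,
    panel: SpikeInPanel,
    gene_lengths: pd.Series,
    *,
    min_attomole: float = 0.001,
) -> tuple[list[CopyEstimate], pd.DataFrame]:
    """Run the full dual spike-in estimator over every sample.

    Returns the per-sample :class:`CopyEstimate` list (with ``final_copies``
    from the combined regression) and the gene RPKM table (spike-ins
    excluded) for downstream use.
    """
    spike_ids = panel.ids()
    lengths = pd.concat([gene_lengths, panel.lengths()])
    lengths = lengths[~lengths.index.duplicated()]
    rpkm = compute_rpkm(counts, lengths.reindex(counts.counts.index))
    gene_mask = ~rpkm.index.isin(spike_ids)
    gene_rpkm = rpkm.loc[gene_mask]
    ercc_ids = [s.species_id for s in panel.ercc()]
    rgc_molecules = pd.Series(
        {
            s.species_id: (
                s.amount
                if s.amount_unit == "molecules"
                else s.amount * MOLECULES_PER_ATTOMOLE
            )
            for s in panel.rgc()
        },
        dtype=float,
    )
    estimates: list[CopyEstimate] = []
    for sample in counts.samples:
        (slope, intercept), ercc_copies = ercc_total_copies(
            rpkm.loc[rpkm.index.isin(ercc_ids), sample],
            panel,
            gene_rpkm[sample],
            min_attomole=min_attomole,
        )
        total_rpkm = float(gene_rpkm[sample].sum())
        rgc_copies = rgc_total_copies(
            rpkm.loc[rpkm.index.isin(rgc_molecules.index), sample],
            rgc_molecules,
            total_rpkm,
        )
        estimates.append(
            CopyEstimate(sample, ercc_copies, rgc_copies, slope=slope,
                         intercept=intercept)
        )
    ercc_series = pd.Series(
        {e.sample_id: e.ercc_based_copies for e in estimates}
    ).loc[counts.samples]
    rgc_series = pd.Series(
        {e.sample_id: e.rgc_based_copies for e in estimates}
    ).loc[counts.samples]
    final = combine_copy_estimates(ercc_series, rgc_series)
    for est in estimates:
        est.final_copies = float(final[est.sample_id])
    return estimates, gene_rpkm
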