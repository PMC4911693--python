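"""mRNA-content-aware normalization, pairwise DE, and maternal/zygotic calls.

Normalization uses size factors proportional to sequencing depth divided by
the absolute mRNA content of the sample, so expression is compared per
transcript copy rather than per sequenced read — essential across the
maternal-to-zygotic transition where total mRNA content changes several
fold.  Differential expression is a negative-binomial Wald test with
method-of-moments dispersion pooled across genes; a gene is called up with
fold change > 2 at FDR < 0.05 and down with fold change < 0.5 at FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ioformats import CountTable

__all__ = [
    "size_factors",
    "pairwise_de",
    "de_series",
    "classify_maternal_zygotic",
]

_LN2_SQ = np.log(2) ** 2


def size_factors(counts: CountTable, mrna_copies: pd.Series) -> pd.Series:
    """Per-sample size factors: depth / mRNA copies, geometric mean 1.

    Dividing a sample's counts by its factor yields expression on a common
    per-copy scale across samples.
    """
    copies = mrna_copies.reindex(counts.samples)
    if copies.isna().any() or (copies <= 0).any():
        raise ValueError("every sample needs a positive mRNA copy estimate")
    depth = counts.meta.loc[counts.samples, "total_mapped_reads"].astype(float)
    raw = depth / copies
    factors = raw / np.exp(np.log(raw).mean())
    factors.name = "size_factor"
    return factors


def _pooled_dispersion(
    qa: np.ndarray, qb: np.ndarray, inv_fa: float, inv_fb: float, floor: float
) -> np.ndarray:
    """Method-of-moments NB dispersion, pooled across genes.

    The per-gene estimator is (var - mu * mean(1/f)) / (mu^2 - var/n); the
    denominator subtracts var/n because the squared sample mean
    overestimates mu^2 by the variance of the mean.  Per-gene estimates are
    far too noisy at 2-3 replicates, so a single trimmed-mean dispersion
    over all genes is used, floored at ``floor``.  Returns one value per
    gene (currently constant).
    """
    ests = []
    for q, inv_f in ((qa, inv_fa), (qb, inv_fb)):
        n = q.shape[1]
        if n < 2:
            continue
        mu = q.mean(axis=1)
        var = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = mu**2 - var / n
            a = (var - mu * inv_f) / denom
        ests.append(np.where((mu > 0) & (denom > 0), a, np.nan))
    if not ests:
        return np.full(qa.shape[0], floor)
    per_gene = np.nanmean(np.vstack(ests), axis=0)
    per_gene = np.clip(per_gene, 0.0, None)
    valid = per_gene[np.isfinite(per_gene)]
    if valid.size == 0:
        common = floor
    else:
        common = float(stats.trim_mean(valid, 0.1))
    alpha = max(floor, common)
    return np.full(qa.shape[0], alpha)


def pairwise_de(
    counts_A: pd.DataFrame,
    counts_B: pd.DataFrame,
    factors: pd.Series,
    *,
    keep_genes: pd.Index | None = None,
    dispersion_floor: float = 0.01,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test between two stages (replicate columns per stage).

    ``factors`` must cover every column of both count frames.  ``keep_genes``
    is the expression gate (e.g. genes with normalized RPKM >= 1 in at least
    one sample); None keeps all genes.  Returns a DataFrame indexed by gene
    with columns base_mean_A/B, log2_fold_change, p_value, fdr, direction.
    An empty gate yields an empty frame.
    """
    genes = counts_A.index
    if not genes.equals(counts_B.index):
        raise ValueError("count frames must share the gene index")
    if keep_genes is not None:
        genes = genes.intersection(keep_genes)
        counts_A = counts_A.loc[genes]
        counts_B = counts_B.loc[genes]
    if genes.empty:
        import warnings

        warnings.warn("no genes pass the expression gate; empty DE result")
        return pd.DataFrame(
            columns=[
                "base_mean_A", "base_mean_B", "log2_fold_change",
                "p_value", "fdr", "direction",
            ]
        )
    fa = factors.reindex(counts_A.columns).astype(float)
    fb = factors.reindex(counts_B.columns).astype(float)
    if fa.isna().any() or fb.isna().any():
        raise ValueError("size factors missing for some samples")
    qa = counts_A.to_numpy(dtype=float) / fa.to_numpy()
    qb = counts_B.to_numpy(dtype=float) / fb.to_numpy()
    na, nb = qa.shape[1], qb.shape[1]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    inv_fa = float(np.mean(1.0 / fa.to_numpy()))
    inv_fb = float(np.mean(1.0 / fb.to_numpy()))
    alpha = _pooled_dispersion(qa, qb, inv_fa, inv_fb, dispersion_floor)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_b) - np.log2(mu_a)
        var_log_a = (inv_fa / mu_a + alpha) / (na * _LN2_SQ)
        var_log_b = (inv_fb / mu_b + alpha) / (nb * _LN2_SQ)
        se = np.sqrt(var_log_a + var_log_b)
        z = lfc / se
    testable = np.isfinite(z)
    p = np.full(genes.size, np.nan)
    p[testable] = 2 * stats.norm.sf(np.abs(z[testable]))
    fdr = np.full(genes.size, np.nan)
    if testable.any():
        fdr[testable] = multipletests(p[testable], method="fdr_bh")[1]
    fc = np.where(np.isfinite(lfc), 2.0**lfc, np.nan)
    direction = np.full(genes.size, "ns", dtype=object)
    sig = np.isfinite(fdr) & (fdr < alpha_fdr)
    direction[sig & (fc > fc_up)] = "up"
    direction[sig & (fc < fc_down)] = "down"
    return pd.DataFrame(
        {
            "base_mean_A": mu_a,
            "base_mean_B": mu_b,
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        },
        index=genes,
    )


def de_series(
    counts: CountTable,
    stage_of: pd.Series,
    stages: list[str],
    factors: pd.Series,
    *,
    keep_genes: pd.Index | None = None,
    **de_kwargs,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run pairwise DE between every pair of consecutive stages."""
    results = {}
    for a, b in zip(stages[:-1], stages[1:]):
        cols_a = stage_of.index[stage_of == a]
        cols_b = stage_of.index[stage_of == b]
        results[(a, b)] = pairwise_de(
            counts.counts[list(cols_a)],
            counts.counts[list(cols_b)],
            factors,
            keep_genes=keep_genes,
            **de_kwargs,
        )
    return results


def classify_maternal_zygotic(
    de_results: dict[tuple[str, str], pd.DataFrame],
    stage_rpkm: pd.DataFrame,
    stages: list[str],
    four_cell_stage: str = "4cell",
) -> pd.Series:
    """Maternal / zygotic / undetermined call per gene.

    maternal: expression peaks in the oocyte (first stage) AND a significant
    down call exists in some consecutive-stage pair at or after the 4-cell
    stage.  zygotic: a significant up call exists in such a pair AND the
    oocyte is not the peak stage.  Everything else: undetermined.
    """
    if four_cell_stage not in stages:
        raise ValueError(
            f"4-cell stage label {four_cell_stage!r} not in stage list"
        )
    missing = [s for s in stages if s not in stage_rpkm.columns]
    if missing:
        raise ValueError(f"stage RPKM missing stages: {missing}")
    oocyte = stages[0]
    mzt_idx = stages.index(four_cell_stage)
    late_pairs = [
        pair for pair in de_results if stages.index(pair[0]) >= mzt_idx
    ]
    genes = stage_rpkm.index
    peak = stage_rpkm[stages].idxmax(axis=1)
    down_late = pd.Series(False, index=genes)
    up_late = pd.Series(False, index=genes)
    for pair in late_pairs:
        res = de_results[pair]
        down_late |= (
            pd.Series(res["direction"] == "down", index=res.index)
            .reindex(genes, fill_value=False)
        )
        up_late |= (
            pd.Series(res["direction"] == "up", index=res.index)
            .reindex(genes, fill_value=False)
        )
    cls = pd.Series("undetermined", index=genes, name="class")
    cls[(peak == oocyte) & down_late] = "maternal"
    cls[(peak != oocyte) & up_late] = "zygotic"
    return cls
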