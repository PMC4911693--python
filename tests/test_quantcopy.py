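import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryocirc.ioformats import CountTable, SpikeIn, SpikeInPanel
from embryocirc.quantcopy import (
    MOLECULES_PER_ATTOMOLE,
    circ_copy_number,
    circ_rpkm,
    combine_copy_estimates,
    compute_rpkm,
    effective_circ_length,
    ercc_qc,
    ercc_total_copies,
    rgc_total_copies,
    subsample_counts,
)


def ols_oracle(x, y):
    """Closed-form simple least squares: slope and intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb


class TestRpkm:
    def test_formula(self, small_counts):
        lengths = pd.Series({"gA": 1000.0, "gB": 500.0, "gC": 2000.0})
        rpkm = compute_rpkm(small_counts, lengths)
        # count 10, 1 kb, 1e6 mapped -> 10
        assert rpkm.loc["gA", "s1"] == pytest.approx(10.0)
        assert rpkm.loc["gB", "s1"] == 0.0
        assert rpkm.loc["gC", "s2"] == pytest.approx(50 / 2 / 2)

    def test_zero_length_errors(self, small_counts):
        lengths = pd.Series({"gA": 1000.0, "gB": 0.0, "gC": 2000.0})
        with pytest.raises(ValueError, match="gB"):
            compute_rpkm(small_counts, lengths)

    def test_missing_length_errors(self, small_counts):
        with pytest.raises(ValueError, match="gC"):
            compute_rpkm(small_counts, pd.Series({"gA": 1.0, "gB": 1.0}))

    def test_ratio_quantities_invariant_to_depth_doubling(self, small_counts):
        lengths = pd.Series({"gA": 1000.0, "gB": 500.0, "gC": 2000.0})
        rpkm1 = compute_rpkm(small_counts, lengths)
        doubled = CountTable(
            small_counts.counts * 2,
            small_counts.meta.assign(
                total_mapped_reads=small_counts.meta.total_mapped_reads * 2
            ),
        )
        rpkm2 = compute_rpkm(doubled, lengths)
        pd.testing.assert_frame_equal(rpkm1, rpkm2)


class TestErccTotal:
    def test_exact_line_recovers_avogadro_conversion(self, exact_panel):
        # RPKM = 10 x attomole exactly; genes summing to RPKM 10 -> 1 attomole
        ercc_rpkm = pd.Series(
            {s.species_id: 10 * s.amount for s in exact_panel.ercc()}
        )
        gene_rpkm = pd.Series({"gA": 6.0, "gB": 4.0})
        (slope, intercept), molecules = ercc_total_copies(
            ercc_rpkm, exact_panel, gene_rpkm
        )
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(1.0)
        assert molecules == pytest.approx(602_214.0)

    def test_all_species_below_retention_cutoff_errors(self):
        panel = SpikeInPanel(
            tuple(
                SpikeIn(f"E{i}", "ERCC", 0.0005, "attomole", 1000, 20)
                for i in range(5)
            )
        )
        rpkm = pd.Series({f"E{i}": 1.0 for i in range(5)})
        with pytest.raises(ValueError, match=">= 3"):
            ercc_total_copies(rpkm, panel, pd.Series({"g": 1.0}))

    def test_noisy_fit_matches_closed_form_oracle(self, exact_panel, rng):
        amounts = np.array([s.amount for s in exact_panel.ercc()])
        log_rpkm = 0.9 * np.log10(amounts) + 0.5 + rng.normal(0, 0.1, len(amounts))
        ercc_rpkm = pd.Series(
            10**log_rpkm, index=[s.species_id for s in exact_panel.ercc()]
        )
        (slope, intercept), _ = ercc_total_copies(
            ercc_rpkm, exact_panel, pd.Series({"g": 5.0})
        )
        o_slope, o_intercept = ols_oracle(np.log10(amounts), log_rpkm)
        assert slope == pytest.approx(o_slope, abs=1e-9)
        assert intercept == pytest.approx(o_intercept, abs=1e-9)

    def test_zero_rpkm_genes_contribute_zero(self, exact_panel):
        ercc_rpkm = pd.Series(
            {s.species_id: 10 * s.amount for s in exact_panel.ercc()}
        )
        with_zero = ercc_total_copies(
            ercc_rpkm, exact_panel, pd.Series({"gA": 10.0, "gB": 0.0})
        )[1]
        without = ercc_total_copies(
            ercc_rpkm, exact_panel, pd.Series({"gA": 10.0})
        )[1]
        assert with_zero == pytest.approx(without)


class TestRgcTotal:
    def test_self_consistent_species_agree(self):
        rpkm = pd.Series({"RFP": 100.0, "GFP": 10.0, "CRE": 1.0})
        molecules = pd.Series({"RFP": 1e6, "GFP": 1e5, "CRE": 1e4})
        assert rgc_total_copies(rpkm, molecules, 10_000.0) == pytest.approx(1e8)

    def test_single_detected_species(self):
        rpkm = pd.Series({"RFP": 100.0, "GFP": 0.0, "CRE": 0.0})
        molecules = pd.Series({"RFP": 1e6, "GFP": 1e5, "CRE": 1e4})
        assert rgc_total_copies(rpkm, molecules, 10_000.0) == pytest.approx(1e8)

    def test_mean_over_disagreeing_species(self):
        rpkm = pd.Series({"RFP": 100.0, "GFP": 5.0})
        molecules = pd.Series({"RFP": 1e6, "GFP": 1e5})
        # RFP -> 1e8, GFP -> 2e8
        assert rgc_total_copies(rpkm, molecules, 10_000.0) == pytest.approx(1.5e8)

    def test_no_detected_species_errors(self):
        with pytest.raises(ValueError):
            rgc_total_copies(
                pd.Series({"RFP": 0.0}), pd.Series({"RFP": 1e6}), 10.0
            )


class TestCombine:
    def test_identity_when_estimates_agree(self):
        vals = pd.Series([1e7, 3e7, 9e7], index=list("abc"))
        final = combine_copy_estimates(vals, vals)
        assert np.allclose(final, vals)

    def test_exact_proportionality_recovered(self):
        ercc = pd.Series([1e7, 3e7, 9e7, 2e7], index=list("abcd"))
        final = combine_copy_estimates(ercc, 3 * ercc)
        assert np.allclose(final, 3 * ercc)

    def test_noisy_pairs_match_closed_form_oracle(self, rng):
        ercc = pd.Series(10 ** rng.uniform(7, 8.2, 9), index=range(9))
        rgc = ercc / 3 * 10 ** rng.normal(0, 0.05, 9)
        final = combine_copy_estimates(ercc, rgc)
        slope, intercept = ols_oracle(np.log10(ercc), np.log10(rgc))
        expected = 10 ** (slope * np.log10(ercc) + intercept)
        assert np.allclose(final, expected, rtol=1e-9)

    def test_too_few_samples_errors(self):
        two = pd.Series([1e7, 2e7], index=list("ab"))
        with pytest.raises(ValueError):
            combine_copy_estimates(two, two)


class TestEffectiveLength:
    def test_hundred_bp_reads_give_150(self):
        assert effective_circ_length(100) == 150

    def test_fifty_bp_reads_give_50(self):
        assert effective_circ_length(50) == 50

    def test_read_length_at_anchor_errors(self):
        with pytest.raises(ValueError):
            effective_circ_length(25)


class TestCircCopies:
    def test_copy_formula(self):
        assert circ_copy_number(100.0, 10_000.0, 1e7) == pytest.approx(1e5)

    def test_zero_circ_mass_gives_zero(self):
        assert circ_copy_number(0.0, 10_000.0, 1e7) == 0.0

    def test_per_circ_rpkm_uses_effective_length(self):
        # 3 junction reads, 100 bp reads (effective 150 bp), 1e6 mapped
        assert circ_rpkm(3, 100, 1e6) == pytest.approx(20.0)

    def test_linear_in_mrna_copies(self):
        a = circ_copy_number(50.0, 1000.0, 1e6)
        b = circ_copy_number(50.0, 1000.0, 2e6)
        assert b == pytest.approx(2 * a)

    def test_zero_refseq_mass_errors(self):
        with pytest.raises(ValueError):
            circ_copy_number(1.0, 0.0, 1e6)


class TestSubsample:
    def test_exact_total_after_subsampling(self, small_counts):
        sub = subsample_counts(small_counts, 50, seed=3)
        assert (sub.counts.sum(axis=0) == 50).all()

    def test_same_seed_identical(self, small_counts):
        a = subsample_counts(small_counts, 50, seed=3)
        b = subsample_counts(small_counts, 50, seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_depth_above_total_errors(self, small_counts):
        with pytest.raises(ValueError):
            subsample_counts(small_counts, 10**9, seed=0)

    def test_matches_hypergeometric_moments(self):
        # mean of per-feature subsampled counts over 200 draws within 3 sigma
        col = np.array([40, 25, 15, 10, 10])
        counts = pd.DataFrame({"s": col}, index=[f"g{i}" for i in range(5)])
        meta = pd.DataFrame(
            {"total_mapped_reads": [100], "read_length": [100]}, index=["s"]
        )
        table = CountTable(counts, meta)
        depth, n_draws = 30, 200
        draws = np.stack(
            [
                subsample_counts(table, depth, seed=s).counts["s"].to_numpy()
                for s in range(n_draws)
            ]
        )
        total = col.sum()
        expected = depth * col / total
        var = (
            depth * (col / total) * (1 - col / total)
            * (total - depth) / (total - 1)
        )
        se = np.sqrt(var / n_draws)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9).all()


class TestErccQc:
    def _rpkm(self):
        return pd.DataFrame(
            {
                "s1": [5.0, 2.0, 0.2],
                "s2": [5.0, 0.5, 0.2],
                "s3": [5.0, 2.0, 0.2],
                "s4": [5.0, 0.1, 0.1],
            },
            index=["keep", "two_samples", "never"],
        )

    def test_species_in_exactly_two_samples_excluded(self):
        result = ercc_qc(self._rpkm())
        assert result.retained == ["keep"]

    def test_species_in_three_samples_retained(self):
        rpkm = self._rpkm()
        rpkm.loc["two_samples", "s4"] = 1.0  # boundary: >= 1 in exactly 3
        assert "two_samples" in ercc_qc(rpkm).retained

    def test_identical_samples_have_unit_correlation(self):
        rpkm = pd.DataFrame(
            {"s1": [1.0, 5.0, 9.0], "s2": [1.0, 5.0, 9.0], "s3": [2.0, 4.0, 8.0]},
            index=list("abc"),
        )
        result = ercc_qc(rpkm)
        assert result.pearson.loc["s1", "s2"] == pytest.approx(1.0)

    def test_nothing_retained_is_report_not_exception(self):
        rpkm = pd.DataFrame(
            {"s1": [0.1], "s2": [0.2], "s3": [0.1]}, index=["x"]
        )
        result = ercc_qc(rpkm)
        assert not result.ok and result.retained == []
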