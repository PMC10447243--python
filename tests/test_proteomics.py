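"""LFQ processing: replicate averaging, two-tier imputation, PCA QC,
differential statistics, ranking and correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuromito import proteomics as P


def _matrix(values, groups, biosamples=None, scale="log2"):
    vals = pd.DataFrame(values)
    vals.index = [f"P{i}" for i in range(len(vals))]
    design = pd.DataFrame(
        {
            "group": groups,
            "biosample": biosamples if biosamples else list(vals.columns),
        },
        index=list(vals.columns),
    )
    return P.LfqMatrix(vals, design, scale=scale)


class TestAverageTechnicalReplicates:
    def test_mean_single_and_all_missing(self):
        m = _matrix(
            {"a_r1": [10.0, 10.0, np.nan], "a_r2": [12.0, np.nan, np.nan]},
            groups=["control", "control"],
            biosamples=["a", "a"],
        )
        out = P.average_technical_replicates(m)
        assert list(out.intensities.columns) == ["a"]
        assert out.intensities.loc["P0", "a"] == 11.0
        assert out.intensities.loc["P1", "a"] == 10.0
        assert np.isnan(out.intensities.loc["P2", "a"])

    def test_replicates_spanning_groups_rejected(self):
        m = _matrix(
            {"a_r1": [10.0], "a_r2": [12.0]},
            groups=["control", "case"],
            biosamples=["a", "a"],
        )
        with pytest.raises(ValueError, match="span groups"):
            P.average_technical_replicates(m)


class TestImpute:
    def test_no_missing_is_identity(self, small_matrix):
        out, tier = P.impute(small_matrix, seed=0)
        pd.testing.assert_frame_equal(out.intensities, small_matrix.intensities)
        assert (tier == P.TIER_NONE).all().all()

    def test_tier1_statistics_match_shift_and_width(self):
        # 3000 proteins absent from the control group -> 3000*6 tier-1 cells;
        # a separate fully-observed block supplies the global mean and s.d.
        rng = np.random.default_rng(21)
        n_censored, n_obs = 3000, 3000
        cols = [f"c{i}" for i in range(6)] + [f"e{i}" for i in range(6)]
        observed_block = rng.normal(25.0, 2.0, size=(n_obs, 12))
        censored_block = np.full((n_censored, 12), np.nan)
        censored_block[:, 6:] = rng.normal(25.0, 2.0, size=(n_censored, 6))
        vals = pd.DataFrame(
            np.vstack([observed_block, censored_block]), columns=cols
        )
        vals.index = [f"P{i:05d}" for i in range(len(vals))]
        design = pd.DataFrame(
            {"group": ["control"] * 6 + ["case"] * 6, "biosample": cols},
            index=cols,
        )
        m = P.LfqMatrix(vals, design, scale="log2")
        out, tier = P.impute(m, seed=3)
        flat = m.intensities.values[m.intensities.notna().values]
        mu, sd = flat.mean(), flat.std(ddof=1)
        imputed = out.intensities.values[(tier == P.TIER_SHIFTED).values]
        assert len(imputed) >= 10_000
        assert imputed.mean() == pytest.approx(mu - 2 * sd, rel=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.02)

    def test_low_detection_group_fully_overwritten(self):
        # P0 detected in 2/6 control but 5/5 case samples: the whole control
        # block (observed values included) is tier-1 replaced, case untouched
        rng = np.random.default_rng(7)
        cols = [f"c{i}" for i in range(6)] + [f"e{i}" for i in range(5)]
        vals = pd.DataFrame(rng.normal(25, 2, size=(40, 11)), columns=cols)
        vals.index = [f"P{i}" for i in range(40)]
        vals.loc["P0", ["c0", "c1", "c2", "c3"]] = np.nan
        design = pd.DataFrame(
            {"group": ["control"] * 6 + ["case"] * 5, "biosample": cols},
            index=cols,
        )
        m = P.LfqMatrix(vals, design, scale="log2")
        out, tier = P.impute(m, seed=1)
        ctrl = [f"c{i}" for i in range(6)]
        case = [f"e{i}" for i in range(5)]
        assert (tier.loc["P0", ctrl] == P.TIER_SHIFTED).all()
        assert (tier.loc["P0", case] == P.TIER_NONE).all()
        assert not np.allclose(
            out.intensities.loc["P0", ["c4", "c5"]],
            vals.loc["P0", ["c4", "c5"]],
        )
        np.testing.assert_array_equal(
            out.intensities.loc["P0", case].values, vals.loc["P0", case].values
        )

    def test_observed_cells_bit_identical_and_no_missing_left(self, imputed_cohort):
        averaged, imputed, tier = imputed_cohort
        log2 = averaged.log2()
        keep = (tier == P.TIER_NONE).values
        np.testing.assert_array_equal(
            imputed.intensities.values[keep], log2.intensities.values[keep]
        )
        assert not imputed.intensities.isna().any().any()
        # tier counts partition the formerly-missing plus overwritten cells
        was_missing = log2.intensities.isna().values
        assert ((tier != P.TIER_NONE).values | ~was_missing).all()

    def test_chained_tier_used_for_sporadic_missing(self, imputed_cohort):
        _, _, tier = imputed_cohort
        counts = tier.stack().value_counts()
        assert counts.get(P.TIER_CHAINED, 0) > 0
        assert counts.get(P.TIER_SHIFTED, 0) > 0

    def test_degenerate_dataset_rejected(self):
        m = _matrix(
            {"a": [25.0, 25.0], "b": [25.0, np.nan], "c": [25.0, 25.0],
             "d": [25.0, 25.0]},
            groups=["control", "control", "case", "case"],
        )
        with pytest.raises(ValueError, match="zero variance"):
            P.impute(m, seed=0)


class TestPcaQc:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(3)
        base = rng.normal(25, 0.01, size=(100, 8))
        base[0, :4] += 1.0  # one protein separates the groups
        m = _matrix(
            {f"s{i}": base[:, i] for i in range(8)},
            groups=["control"] * 4 + ["case"] * 4,
        )
        coords, evr, flags = P.pca_qc(m)
        assert evr[0] > 0.9
        pc1 = coords["PC1"].values
        assert (pc1[:4] > 0).all() != (pc1[4:] > 0).all()  # groups separated

    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(25, 0.5, size=(200, 9))
        vals[:, 0] += 10 * 0.5  # 10x the within-group spread
        m = _matrix(
            {f"s{i}": vals[:, i] for i in range(9)},
            groups=["control"] * 5 + ["case"] * 4,
        )
        _, _, flags = P.pca_qc(m)
        assert flags["s0"]
        assert flags.sum() == 1

    def test_coordinates_centered(self, imputed_cohort):
        _, imputed, _ = imputed_cohort
        coords, _, _ = P.pca_qc(imputed)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-8)

    def test_too_few_samples_rejected(self):
        m = _matrix({"a": [1.0, 2.0], "b": [1.0, 2.0]}, groups=["control", "case"])
        with pytest.raises(ValueError, match="3 samples"):
            P.pca_qc(m)


class TestDifferentialAbundance:
    def test_identical_group_means(self):
        m = _matrix(
            {"c0": [1.0], "c1": [2.0], "c2": [3.0],
             "e0": [1.0], "e1": [2.0], "e2": [3.0]},
            groups=["control"] * 3 + ["case"] * 3,
        )
        d = P.differential_abundance(m)
        assert d.loc["P0", "log2fc"] == pytest.approx(0.0)
        assert d.loc["P0", "p_raw"] == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # control (1,2,3), case (4,5,6): pooled sd = 1, so
        # t = (5-2) / sqrt(2/3) = 3*sqrt(3/2), df = 4
        m = _matrix(
            {"c0": [1.0], "c1": [2.0], "c2": [3.0],
             "e0": [4.0], "e1": [5.0], "e2": [6.0]},
            groups=["control"] * 3 + ["case"] * 3,
        )
        d = P.differential_abundance(m)
        t_expected = 3.0 * np.sqrt(1.5)
        assert d.loc["P0", "log2fc"] == pytest.approx(3.0)
        assert d.loc["P0", "t_stat"] == pytest.approx(t_expected, rel=1e-12)
        assert d.loc["P0", "p_raw"] == pytest.approx(
            2 * stats.t.sf(t_expected, df=4), rel=1e-12
        )
        assert d.loc["P0", "p_raw"] == pytest.approx(0.0214, abs=5e-4)

    def test_bonferroni_saturates_at_one(self, small_matrix):
        d = P.differential_abundance(small_matrix)
        m_tests = len(d)
        assert (d["p_bonf"] == np.minimum(1.0, d["p_raw"] * m_tests)).all()
        assert d["p_bonf"].max() <= 1.0

    def test_t_squared_equals_anova_f(self, small_matrix):
        d = P.differential_abundance(small_matrix)
        anova = P.complex_level_anova(
            small_matrix, {"one": ["P000"], "two": ["P001"]}
        )
        assert anova.loc["one", "F"] == pytest.approx(
            d.loc["P000", "t_stat"] ** 2, rel=1e-9
        )

    def test_small_group_rejected(self):
        m = _matrix(
            {"c0": [1.0], "c1": [2.0], "e0": [3.0]},
            groups=["control", "control", "case"],
        )
        with pytest.raises(ValueError, match="2 samples"):
            P.differential_abundance(m)


class TestComplexLevelAnova:
    def test_textbook_two_group_f(self):
        # per-sample means (10,10,10) vs (12,12,12) with tiny jitter: F huge
        m = _matrix(
            {"c0": [10.0], "c1": [10.1], "c2": [9.9],
             "e0": [12.0], "e1": [12.1], "e2": [11.9]},
            groups=["control"] * 3 + ["case"] * 3,
        )
        out = P.complex_level_anova(m, {"cx": ["P0"]})
        F_ref, p_ref = stats.f_oneway([10.0, 10.1, 9.9], [12.0, 12.1, 11.9])
        assert out.loc["cx", "F"] == pytest.approx(F_ref)
        assert out.loc["cx", "p"] == pytest.approx(p_ref)

    def test_empty_complex_skipped_with_warning(self, small_matrix):
        with pytest.warns(UserWarning, match="no measured proteins"):
            out = P.complex_level_anova(
                small_matrix, {"good": ["P000"], "ghost": ["nope"]}
            )
        assert list(out.index) == ["good"]

    def test_single_group_rejected(self):
        m = _matrix(
            {"c0": [1.0], "c1": [2.0]}, groups=["control", "control"]
        )
        with pytest.raises(ValueError, match="two groups"):
            P.complex_level_anova(m, {"cx": ["P0"]})


class TestRankByLog2fc:
    def test_ascending_ranks(self):
        d = pd.DataFrame({"log2fc": [1.0, -2.0, 0.0]}, index=["a", "b", "c"])
        out = P.rank_by_log2fc(d)
        assert list(out.index) == ["b", "c", "a"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_ties_broken_lexicographically(self):
        d = pd.DataFrame({"log2fc": [0.0, 0.0, 0.0]}, index=["z", "a", "m"])
        out = P.rank_by_log2fc(d)
        assert list(out.index) == ["a", "m", "z"]

    def test_planted_depletion_ranks_low(self, lfq_cohort, imputed_cohort):
        design, _, annot, _ = lfq_cohort
        _, imputed, _ = imputed_cohort
        diff = P.differential_abundance(imputed)
        ranked = P.rank_by_log2fc(diff, annot, ["TCA"])
        tca_ranks = ranked.loc[ranked["in_TCA"], "rank"]
        assert tca_ranks.median() <= len(ranked) / 4  # bottom quartile


class TestCorrelateExternal:
    def test_perfect_correlations(self, small_matrix):
        d = P.differential_abundance(small_matrix)
        out = P.correlate_external(d, d["log2fc"])
        assert out["r"] == pytest.approx(1.0)
        out = P.correlate_external(d, -d["log2fc"])
        assert out["r"] == pytest.approx(-1.0)
        assert out["n"] == len(d)

    def test_null_correlation_small(self, small_matrix):
        d = P.differential_abundance(small_matrix)
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            ext = pd.Series(rng.normal(size=len(d)), index=d.index)
            if abs(P.correlate_external(d, ext)["r"]) >= 0.3:
                hits += 1
        assert hits <= 2

    def test_insufficient_overlap_rejected(self, small_matrix):
        d = P.differential_abundance(small_matrix)
        with pytest.raises(ValueError, match="overlap"):
            P.correlate_external(d, {"P000": 1.0, "P001": 2.0})
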