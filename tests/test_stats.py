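"""Density conversion, synthetic counts, ANOVA and Holm-Sidak adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ihtwin.errors import ValidationError
from ihtwin.stats import (
    CountFrameRecord,
    anova_pairwise,
    cells_from_frame,
    condition_pairs,
    density_from_counts,
    holm_sidak,
    one_way_anova,
    records_to_frame,
    region_pairs_within_condition,
    run_validation_pipeline,
    synth_counts,
    two_way_anova,
)


def record(count, n_sections=1, **kw):
    return CountFrameRecord("a1", "IH", "CA1", count, n_sections=n_sections, **kw)


class TestDensity:
    def test_zero_count(self):
        assert density_from_counts(record(0)) == 0.0

    def test_single_frame_volume(self):
        # 0.28 mm * 0.28 mm * 0.035 mm = 0.002744 mm^3
        assert density_from_counts(record(10)) == pytest.approx(10 / 0.002744)
        assert density_from_counts(record(10)) == pytest.approx(3644.3, abs=0.1)

    def test_linearity_in_count(self):
        assert density_from_counts(record(20)) == pytest.approx(
            2 * density_from_counts(record(10)))

    def test_sections_scale_volume(self):
        assert density_from_counts(record(10, n_sections=4)) == pytest.approx(
            density_from_counts(record(10)) / 4)

    def test_invalid_record(self):
        with pytest.raises(ValidationError):
            record(-1)
        with pytest.raises(ValidationError):
            CountFrameRecord("a", "IH", "CA2", 1)


class TestSynthCounts:
    def test_deterministic_given_seed(self):
        a = records_to_frame(synth_counts(seed=5))
        b = records_to_frame(synth_counts(seed=5))
        assert a.equals(b)

    def test_group_sizes_and_structure(self):
        df = records_to_frame(synth_counts(seed=0))
        assert df.groupby("group").animal_id.nunique().to_dict() == {"CTRL": 7, "IH": 8}
        assert set(df.region) == {"CA1", "CA3", "DG"}

    def test_poisson_limit_mean(self):
        # dispersion -> inf: sample mean within 2% of baseline * multiplier
        recs = synth_counts(baseline_by_region={"CA1": 50.0, "CA3": 50.0, "DG": 50.0},
                            ih_effect_multiplier=1.3, n_ih=10000, n_ctrl=2,
                            dispersion=float("inf"), seed=1)
        ih = [r.count for r in recs if r.group == "IH"]
        assert np.mean(ih) == pytest.approx(65.0, rel=0.02)

    def test_null_multiplier_groups_indistinguishable(self):
        recs = synth_counts(ih_effect_multiplier=1.0, n_ih=10000, n_ctrl=10000, seed=2)
        df = records_to_frame(recs)
        a = df.loc[df.group == "IH", "count"]
        b = df.loc[df.group == "CTRL", "count"]
        p = sps.ttest_ind(a, b).pvalue
        assert p > 0.001

    def test_overdispersion_exceeds_poisson(self):
        recs = synth_counts(baseline_by_region={"CA1": 20.0, "CA3": 20.0, "DG": 20.0},
                            n_ih=5000, n_ctrl=2, dispersion=2.0, seed=3,
                            ih_effect_multiplier=1.0)
        ih = np.array([r.count for r in recs if r.group == "IH"], dtype=float)
        # NB variance = mu + mu^2/r = 20 + 200
        assert ih.var() > 3 * ih.mean()

    def test_invalid_sizes(self):
        with pytest.raises(ValidationError):
            synth_counts(n_ih=1)


class TestHolmSidak:
    def test_single_comparison_identity(self):
        assert holm_sidak(np.array([0.04]))[0] == pytest.approx(0.04, abs=1e-15)

    def test_step_down_closed_form(self):
        adj = holm_sidak(np.array([0.01, 0.03, 0.04]))
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 3, abs=1e-12)
        assert adj[1] == pytest.approx(1 - (1 - 0.03) ** 2, abs=1e-12)
        # monotonicity enforcement carries the second value onto the third
        assert adj[2] == pytest.approx(adj[1], abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(8)
        ours = holm_sidak(p)
        theirs = multipletests(p, method="holm-sidak")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_adjustment_invariants(self, pvals):
        p = np.array(pvals)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            holm_sidak(np.array([0.5, 1.5]))


class TestOneWayAnova:
    def test_identical_constant_groups(self):
        f, p, *_ = one_way_anova({"a": np.ones(5), "b": np.ones(4)})
        assert f == 0.0 and p == 1.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 1.0, size=8) for i, k in enumerate("abcd")}
        f, p, *_ = one_way_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_group_f_is_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 7)
        f, _, *_ = one_way_anova({"a": a, "b": b})
        t = sps.ttest_ind(a, b).statistic
        assert f == pytest.approx(t ** 2, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova({"a": np.ones(1), "b": np.ones(4)})


class TestAnovaPairwise:
    def test_comparison_table_invariants(self):
        df = records_to_frame(synth_counts(seed=7))
        res = anova_pairwise(cells_from_frame(df), alpha=0.05)
        tab = res.comparisons
        assert (tab.p_adjusted >= tab.p_raw - 1e-12).all()
        order = tab.p_raw.argsort(kind="stable")
        assert (np.diff(tab.p_adjusted.to_numpy()[order]) >= -1e-12).all()

    def test_condition_family_has_three_pairs(self):
        assert len(condition_pairs()) == 3
        assert len(region_pairs_within_condition()) == 6

    def test_pooled_variant_uses_omnibus_df(self):
        df = records_to_frame(synth_counts(seed=8))
        cells = cells_from_frame(df)
        res = anova_pairwise(cells, pairs=condition_pairs(), variance="pooled")
        n_total = sum(len(v) for v in cells.values())
        assert res.df_within == n_total - len(cells)

    def test_strong_effect_detected(self):
        # a 3x condition effect at generous n must flag every region pair
        recs = synth_counts(ih_effect_multiplier=3.0, n_ih=30, n_ctrl=30, seed=9)
        res = anova_pairwise(cells_from_frame(records_to_frame(recs)),
                             pairs=condition_pairs())
        assert res.comparisons.significant.all()

    def test_unknown_pair_rejected(self):
        df = records_to_frame(synth_counts(seed=10))
        with pytest.raises(ValidationError):
            anova_pairwise(cells_from_frame(df), pairs=[("IH:CA1", "nope")])


class TestPipeline:
    def test_full_pipeline_shape(self):
        out = run_validation_pipeline(synth_counts(seed=11))
        assert set(out) >= {"densities", "anova_f", "anova_p",
                            "condition_comparisons", "regional_comparisons",
                            "ih_ctrl_density_ratio"}
        assert len(out["condition_comparisons"]) == 3
        assert out["ih_ctrl_density_ratio"] > 0

    def test_two_way_anova_terms(self):
        df = records_to_frame(synth_counts(seed=12))
        tab = two_way_anova(df)
        assert "C(group)" in tab.index and "C(region)" in tab.index
        assert "C(group):C(region)" in tab.index
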