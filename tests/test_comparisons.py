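"""Cross-condition statistics and control-experiment analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from percosc import (
    ExperimentConfig,
    chi_square_2x2,
    default_observer,
    posthoc_pairwise,
    rearrange_luminance_to_bins,
    simulate_soa_control,
    analyze_soa_control,
    tukey_hsd_table,
    two_way_anova_amplitude,
    watson_williams,
)
from percosc.comparisons import soa_binned_subject
from percosc.design import CONTROL2_LEVEL_BY_BIN, LUMINANCE_LEVELS


def balanced_table(rng, n_subj=6, shift_a=0.0, shift_b=0.0, sd=1.0):
    rows = []
    for cond_i, cond in enumerate(["5Hz", "IAF"]):
        for pos_i, pos in enumerate("12345"):
            for s in range(n_subj):
                rows.append(
                    {
                        "subject": f"S{s}",
                        "condition": cond,
                        "position": pos,
                        "peak_to_trough": rng.normal(
                            0.2 + cond_i * shift_a + pos_i * shift_b, sd
                        ),
                    }
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_cells_have_zero_effect_sums_of_squares(self):
        table = balanced_table(np.random.default_rng(0), sd=0.0)
        table["peak_to_trough"] = 0.3
        aov = two_way_anova_amplitude(table)
        for effect in ("condition", "position", "condition:position"):
            assert aov.loc[effect, "sum_sq"] == pytest.approx(0.0, abs=1e-20)

    def test_sum_of_squares_identity_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            table = balanced_table(rng)
            aov = two_way_anova_amplitude(table)
            y = table["peak_to_trough"]
            ss_total = float(((y - y.mean()) ** 2).sum())
            assert aov["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-8)

    def test_detects_a_large_main_effect(self):
        hits = 0
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = balanced_table(rng, shift_a=10.0, sd=1.0)
            aov = two_way_anova_amplitude(table)
            hits += aov.loc["condition", "PR(>F)"] < 1e-3
        assert hits >= 19

    def test_rejects_unbalanced_design(self):
        table = balanced_table(np.random.default_rng(3))
        with pytest.raises(ValueError):
            two_way_anova_amplitude(table.iloc[:-1])


class TestPosthoc:
    def test_identical_groups_give_zero_t(self):
        table = pd.DataFrame(
            {"condition": ["a"] * 4 + ["b"] * 4, "peak_to_trough": [0.2] * 8}
        )
        table.loc[::2, "peak_to_trough"] = 0.4
        out = posthoc_pairwise(table, [("a", "b")])
        assert out.loc[0, "t"] == pytest.approx(0.0)

    def test_one_row_per_requested_pair(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "condition": np.repeat(list("abc"), 10),
                "peak_to_trough": rng.normal(size=30),
            }
        )
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        out = posthoc_pairwise(table, pairs)
        assert len(out) == len(pairs)

    def test_large_separation_survives_fdr(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {
                "condition": np.repeat(["a", "b"], 20),
                "peak_to_trough": np.concatenate(
                    [rng.normal(0, 1, 20), rng.normal(5, 1, 20)]
                ),
            }
        )
        out = posthoc_pairwise(table, [("a", "b")])
        assert out.loc[0, "p_fdr"] < 0.01

    def test_tukey_covers_all_level_pairs(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            {
                "position": np.repeat(list("12345"), 6),
                "peak_to_trough": rng.normal(size=30),
            }
        )
        out = tukey_hsd_table(table)
        assert len(out) == 10


class TestWatsonWilliams:
    def test_identical_concentrated_samples_not_rejected(self):
        rng = np.random.default_rng(7)
        g = rng.vonmises(1.0, 30.0, 20)
        F, p = watson_williams(g, g.copy())
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_opposite_means_strongly_rejected(self):
        rng = np.random.default_rng(8)
        a = rng.vonmises(0.0, 25.0, 20)
        b = rng.vonmises(np.pi, 25.0, 20)
        _, p = watson_williams(a, b)
        assert p < 1e-3

    def test_agrees_with_label_permutation_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.vonmises(0.6, 8.0, 15)
        b = rng.vonmises(1.1, 8.0, 15)
        F_obs, p_param = watson_williams(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            F, _ = watson_williams(perm[:15], perm[15:])
            count += F >= F_obs
        p_perm = count / n_perm
        assert abs(p_param - p_perm) < 0.02 + 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)

    def test_deficient_groups_rejected(self):
        with pytest.raises(ValueError):
            watson_williams([0.1, 0.2], [0.3, 0.4, 0.5])


class TestChiSquare:
    def test_independent_table(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_computed(self):
        # all expected counts are 2.5, so chi2 = 4 * (2.5)^2 / 2.5 = 10
        chi2, p = chi_square_2x2([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(1.565e-3, rel=1e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 5]])


@pytest.fixture(scope="module")
def cfg():
    return ExperimentConfig()


class TestSoaControl:
    def test_counts_conserved_through_phase_rearrangement(self, cfg):
        obs = default_observer(cfg)
        ds = simulate_soa_control(cfg, obs, 1, 10, rng=0)[0]
        binned = soa_binned_subject(ds, "1")
        assert binned.n_bins == 8  # +-50 ms endpoints merged into one point
        total = sum(1 for t in ds.targets if t.position_id == "1")
        assert int(np.sum(binned.n_targets)) == total

    def test_flat_soa_performance_is_never_significant(self, cfg):
        obs = default_observer(cfg)
        ds = simulate_soa_control(cfg, obs, 4, 25, rng=1, soa_modulation=0.0)
        out = analyze_soa_control(ds, cfg.position_ids, 2000, rng=2)
        assert not out["significant_fdr"].any()

    def test_injected_soa_cosine_is_recovered(self, cfg):
        obs = default_observer(cfg)
        theta = np.pi / 3
        ds = simulate_soa_control(
            cfg, obs, 4, 60, rng=3, soa_modulation=0.5, soa_preferred_phase=theta
        )
        out = analyze_soa_control(ds, ["1"], 1000, rng=4)
        from percosc import circular_distance

        assert circular_distance(out.loc[0, "phase_rad"], theta) < np.pi / 8
        assert out.loc[0, "p_raw"] < 0.01


class TestLuminanceControl:
    def level_frame(self, rates, n=200):
        return pd.DataFrame(
            {
                "level": list(LUMINANCE_LEVELS),
                "n_targets": n,
                "n_hits": [int(round(r * n)) for r in rates],
                "hit_rate": list(rates),
            }
        )

    def test_mapping_order_matches_the_emulated_cycle(self):
        rates = [0.40, 0.45, 0.55, 0.60]  # levels 64, 128, 192, 255
        res = rearrange_luminance_to_bins(self.level_frame(rates), 200, rng=0)
        by_level = dict(zip(LUMINANCE_LEVELS, rates))
        np.testing.assert_allclose(
            res.binned.hit_rate, [by_level[l] for l in CONTROL2_LEVEL_BY_BIN]
        )

    @settings(derandomize=True, max_examples=40)
    @given(rates=st.lists(st.floats(0.05, 0.95), min_size=4, max_size=4))
    def test_fitted_phase_restricted_to_zero_or_pi(self, rates):
        res = rearrange_luminance_to_bins(self.level_frame(rates), 50, rng=1)
        phi = res.fit.preferred_phase
        assert min(abs(phi), abs(abs(phi) - np.pi)) < 1e-6

    def test_constant_performance_has_zero_amplitude(self):
        res = rearrange_luminance_to_bins(self.level_frame([0.5] * 4), 100, rng=2)
        assert res.fit.half_amplitude == pytest.approx(0.0, abs=1e-12)

    def test_missing_level_rejected(self):
        frame = self.level_frame([0.4, 0.5, 0.6, 0.7]).iloc[:3]
        with pytest.raises(ValueError):
            rearrange_luminance_to_bins(frame, 100, rng=3)

    def test_surrogate_phases_share_the_symmetry(self):
        """Surrogates built at level granularity keep the mirrored cycle, so
        a luminance-driven curve is compared against symmetric nulls."""
        res = rearrange_luminance_to_bins(
            self.level_frame([0.35, 0.45, 0.55, 0.65]), 2000, rng=4
        )
        assert res.mc.p_raw < 0.05
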