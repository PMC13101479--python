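"""Detection ladder, leakage, generation accounting, and stability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from loxkit.biosensor_stats import (apply_p_floor, detection_ladder,
                                    fisher_combine, generation_table,
                                    generations, leakage_summary,
                                    ppb_to_nanomolar, stability_track,
                                    welch_t_two_sided)


class TestUnitConversion:
    def test_arsenic_mcl_equivalence(self):
        # 10 ppb As at 74.92 g/mol is ~133 nM
        assert ppb_to_nanomolar(10.0) == pytest.approx(10e-6 / 74.92 * 1e9)
        assert ppb_to_nanomolar(10.0) == pytest.approx(133.48, abs=0.01)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_two_sided([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_vanishing_p(self):
        _, _, p = welch_t_two_sided([1.0, 1.001, 0.999],
                                    [100.0, 100.001, 99.999])
        assert p < 1e-8

    def test_textbook_formula(self):
        a = np.array([0.10, 0.12, 0.11])
        b = np.array([0.20, 0.22, 0.21])
        t, df, p = welch_t_two_sided(a, b)
        # independent hand computation of the Welch statistic and df
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(p_hand)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            welch_t_two_sided([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=8),
           st.lists(st.floats(-10, 10), min_size=3, max_size=8),
           st.floats(0.5, 3.0), st.floats(-5, 5))
    def test_symmetry_and_affine_invariance(self, a, b, scale, shift):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        _, _, p1 = welch_t_two_sided(a, b)
        _, _, p2 = welch_t_two_sided(b, a)
        assert p1 == pytest.approx(p2)
        a2 = [scale * x + shift for x in a]
        b2 = [scale * x + shift for x in b]
        _, _, p3 = welch_t_two_sided(a2, b2)
        assert p1 == pytest.approx(p3, rel=1e-6)


class TestFisher:
    def test_all_ones(self):
        chi2, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0.0 and df == 6 and p == 1.0

    def test_three_halves(self):
        chi2, df, p = fisher_combine([0.5, 0.5, 0.5])
        assert chi2 == pytest.approx(4.159, abs=1e-3)
        assert df == 6
        assert p == pytest.approx(0.6547, abs=1e-3)

    def test_single_p_identity(self):
        for p_in in (0.01, 0.3, 0.9):
            _, df, p_out = fisher_combine([p_in])
            assert df == 2 and p_out == pytest.approx(p_in)

    def test_zero_rejected_with_floor_guidance(self):
        with pytest.raises(ValueError, match="floor"):
            fisher_combine([0.0, 0.5])
        with pytest.warns(UserWarning, match="floored"):
            floored = apply_p_floor([0.0, 0.5])
        assert fisher_combine(floored)[2] < 1e-100

    def test_matches_scipy_reference(self, rng):
        ps = rng.uniform(0.01, 1.0, 6)
        chi2, _, p = fisher_combine(ps)
        ref = stats.combine_pvalues(ps, method="fisher")
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_uniform_inputs_give_uniform_combined(self, rng):
        # KS check on 5000 seeded draws of Fisher-combined uniform p-values
        ps = rng.uniform(size=(5000, 3))
        chi2 = -2 * np.log(ps).sum(axis=1)
        combined = stats.chi2.sf(chi2, 6)
        assert stats.kstest(combined, "uniform").pvalue > 0.01


class TestDetectionLadder:
    def _readouts(self, effect_at=None, seed=0, concs=(0.0, 15e-9, 30e-9, 60e-9)):
        rng = np.random.default_rng(seed)
        rows = []
        for e in range(3):
            for c in concs:
                mu = 0.002
                if effect_at is not None and c >= effect_at:
                    mu = 0.02
                for _ in range(3):
                    rows.append({"experiment": f"E{e+1}", "concentration": c,
                                 "value": rng.normal(mu, 2e-4)})
        return pd.DataFrame(rows)

    def test_strong_effect_detected_at_onset(self):
        res = detection_ladder(self._readouts(effect_at=30e-9, seed=1))
        assert res.lowest_detected == pytest.approx(30e-9)
        assert res.steps.shape[0] == 3

    def test_missing_replicates_reported(self):
        df = self._readouts(seed=2)
        df = df.drop(df[(df.experiment == "E2")
                        & (df.concentration == 30e-9)].index[:2])
        with pytest.raises(ValueError, match="E2"):
            detection_ladder(df)

    def test_experiment_subsetting(self):
        df = self._readouts(effect_at=15e-9, seed=3)
        full = detection_ladder(df)
        subset = detection_ladder(df, experiments=["E1", "E2"])
        assert {c.experiment for c in subset.comparisons} == {"E1", "E2"}
        assert subset.steps["df"].iloc[0] == 4  # 2 experiments combined
        assert full.steps["df"].iloc[0] == 6

    def test_holm_adjustment_is_more_conservative(self):
        df = self._readouts(effect_at=60e-9, seed=4)
        plain = detection_ladder(df)
        holm = detection_ladder(df, holm=True)
        assert np.all(holm.steps["combined_p_holm"].to_numpy()
                      >= plain.steps["combined_p"].to_numpy() - 1e-15)


class TestLeakage:
    def test_no_change_gives_zero(self):
        assert leakage_summary([0.002] * 3, [0.002] * 3) == 0.0

    def test_median_of_added_fractions(self):
        base = [0.001, 0.001, 0.001]
        end = [0.0015, 0.0021, 0.0030]
        assert leakage_summary(end, base) == pytest.approx(0.0011)

    def test_matches_exponential_leak_prediction(self, rng):
        # leak rate k over duration T from f0: added ~ f0 (e^{kT} - 1)
        f0, k_leak, T, n = 0.001, 0.05, 17.0, 150_000
        expected = f0 * (np.exp(k_leak * T) - 1)
        ends, bases = [], []
        for _ in range(9):
            f_end = f0 * np.exp(k_leak * T)
            bases.append(rng.binomial(n, f0) / n)
            ends.append(rng.binomial(n, f_end) / n)
        est = leakage_summary(ends, bases)
        assert est == pytest.approx(expected, rel=0.25)


class TestGenerations:
    def test_regrowth_to_same_density(self):
        assert generations(1e9, 1e9, 1e4) == pytest.approx(np.log2(1e4))
        assert generations(1e9, 1e9, 1e4) == pytest.approx(13.2877, abs=1e-4)

    def test_four_cycles_cumulative(self):
        table = generation_table([1e9] * 5, 1e4)
        assert table["cumulative_generations"].iloc[-1] == pytest.approx(
            4 * np.log2(1e4))
        assert round(table["cumulative_generations"].iloc[-1]) == 53

    def test_no_dilution_no_growth(self):
        assert generations(5e8, 5e8, 1.0) == 0.0

    def test_invalid_inputs(self):
        for bad in [(0, 1e9, 1e4), (1e9, -1, 1e4), (1e9, 1e9, 0)]:
            with pytest.raises(ValueError):
                generations(*bad)


class TestStabilityTrack:
    def test_constant_fractions_no_decline(self):
        track = stability_track({"pre_induction": 0.01, "post_exposure": 0.4,
                                 "passage_1": 0.4, "passage_2": 0.4})
        assert np.allclose(track.relative_change[1:], 0.0)

    def test_sixty_percent_decline(self):
        track = stability_track({"post_exposure": 0.40, "passage_4": 0.16})
        assert track.relative_change[-1] == pytest.approx(-0.60)

    def test_reference_required_and_nonzero(self):
        with pytest.raises(ValueError, match="reference"):
            stability_track({"passage_1": 0.2})
        with pytest.raises(ValueError, match="undefined"):
            stability_track({"post_exposure": 0.0, "passage_1": 0.1})

    def test_selection_decline_matches_competition_recursion(self, rng):
        # oracle: deterministic two-type competition f' = f(1-s)/(1-s f)
        s_coef, f = 0.02, 0.4
        n_gens = 53
        truth = [f]
        for _ in range(n_gens):
            f = f * (1 - s_coef) / (1 - s_coef * f)
            truth.append(f)
        # stochastic counterpart: binomial sampling with fitness weighting
        N = 500_000
        f_sim = 0.4
        for _ in range(n_gens):
            mean_next = f_sim * (1 - s_coef) / (1 - s_coef * f_sim)
            f_sim = rng.binomial(N, mean_next) / N
        track = stability_track({"post_exposure": 0.4, "passage_4": f_sim})
        expected_decline = (truth[-1] - truth[0]) / truth[0]
        assert track.relative_change[-1] == pytest.approx(expected_decline,
                                                          abs=0.02)
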