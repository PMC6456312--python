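"""Genome scan: LOD arithmetic, invariances, thresholds, peak calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from qgmap import scan
from qgmap.scan import LodCurve

HAND_LOD = 3.0 * np.log10(7.0)  # 6 strains, RSS 28 -> 4


class TestLodScan:
    def test_hand_least_squares_instance(self, two_founder_panel):
        haps, pheno = two_founder_panel
        curve = scan.lod_scan(haps, pheno)
        assert curve.lod[1] == pytest.approx(HAND_LOD, abs=1e-10)
        assert curve.lod[2] == pytest.approx(HAND_LOD, abs=1e-10)

    def test_collinear_position_scores_zero(self, two_founder_panel):
        haps, pheno = two_founder_panel
        curve = scan.lod_scan(haps, pheno)
        assert curve.lod[0] == pytest.approx(0.0, abs=1e-10)

    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100.0),
    )
    @settings(
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_affine_invariance(self, two_founder_panel, shift, scale):
        haps, pheno = two_founder_panel
        base = scan.lod_scan(haps, pheno).lod
        moved = scan.lod_scan(haps, pheno * scale + shift).lod
        assert np.allclose(base, moved, atol=1e-8)

    def test_matches_brute_force_ols(self, random_soft_panel):
        import statsmodels.api as sm

        haps, pheno, cov = random_soft_panel
        curve = scan.lod_scan(haps, pheno, cov)
        n = haps.n_rils
        x0 = pd.get_dummies(cov["subpop"], drop_first=True, dtype=float).to_numpy()
        y = pheno.reindex(haps.rils).to_numpy()
        null_fit = sm.OLS(y, sm.add_constant(x0)).fit()
        for j in range(haps.n_positions):
            x_full = np.hstack([sm.add_constant(x0), haps.probs[:, j, :-1]])
            full_fit = sm.OLS(y, x_full).fit()
            lod = 0.5 * n * np.log10(null_fit.ssr / full_fit.ssr)
            assert curve.lod[j] == pytest.approx(lod, abs=1e-8)

    def test_misaligned_strains_error(self, two_founder_panel):
        haps, pheno = two_founder_panel
        with pytest.raises(ValueError, match="lack phenotypes"):
            scan.lod_scan(haps, pheno.rename(lambda s: s + "_x"))

    def test_too_few_strains_error(self, two_founder_panel):
        # an 8-founder model needs more than 6 strains
        from qgmap.simulate import simulate_founder_mosaics

        h8 = simulate_founder_mosaics(6, 8, np.arange(0, 5, 1.0), 2, 1.0, seed=0)
        y = pd.Series(np.arange(6.0), index=h8.rils)
        with pytest.raises(ValueError, match="parameters"):
            scan.lod_scan(h8, y)


class TestFounderEffects:
    def test_hand_group_means(self, two_founder_panel):
        haps, pheno = two_founder_panel
        effects, mean = scan.founder_effects_at(haps, pheno, position=5.0)
        assert mean == pytest.approx(13.0)
        assert effects == pytest.approx([-2.0, 2.0], abs=1e-10)

    def test_constant_phenotype_zero_effects(self, two_founder_panel):
        haps, pheno = two_founder_panel
        effects, _ = scan.founder_effects_at(
            haps, pd.Series(3.0, index=haps.rils), position=5.0
        )
        assert np.allclose(effects, 0.0, atol=1e-10)

    def test_negation_negates_effects(self, random_soft_panel):
        haps, pheno, cov = random_soft_panel
        e1, _ = scan.founder_effects_at(haps, pheno, cov, position=5.0)
        e2, _ = scan.founder_effects_at(haps, -pheno, cov, position=5.0)
        assert np.allclose(e1, -e2, atol=1e-10)

    def test_effects_sum_to_zero_under_balance(self, two_founder_panel):
        haps, pheno = two_founder_panel
        effects, _ = scan.founder_effects_at(haps, pheno, position=5.0)
        assert effects.sum() == pytest.approx(0.0, abs=1e-10)


class TestVarianceExplained:
    def test_hand_arithmetic(self, two_founder_panel):
        haps, pheno = two_founder_panel
        ve = scan.variance_explained_at(haps, pheno, position=5.0)
        assert ve == pytest.approx(100.0 * (1 - 4.0 / 28.0), abs=1e-10)

    def test_perfect_fit_is_100(self, two_founder_panel):
        haps, _ = two_founder_panel
        y = pd.Series([1.0, 1, 1, 4, 4, 4], index=haps.rils)
        assert scan.variance_explained_at(haps, y, position=5.0) == pytest.approx(
            100.0
        )

    def test_constant_phenotype_warns_zero(self, two_founder_panel):
        haps, _ = two_founder_panel
        y = pd.Series(2.0, index=haps.rils)
        with pytest.warns(UserWarning):
            ve = scan.variance_explained_at(haps, y, position=5.0)
        assert ve == 0.0


class TestPermutationThreshold:
    def _panel(self):
        from qgmap.simulate import simulate_founder_mosaics

        h = simulate_founder_mosaics(60, 4, np.arange(0, 30, 1.0), 4, 0.9, seed=5)
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=60), index=h.rils)
        return h, y

    def test_deterministic_under_seed(self):
        h, y = self._panel()
        t1 = scan.permutation_threshold(h, y, n_perm=50, seed=3)
        t2 = scan.permutation_threshold(h, y, n_perm=50, seed=3)
        assert t1 == t2
        assert t1 != scan.permutation_threshold(h, y, n_perm=50, seed=4)

    def test_alpha_one_is_minimum_of_maxima(self):
        h, y = self._panel()
        t, maxes = scan.permutation_threshold(
            h, y, n_perm=40, alpha=1.0, seed=1, return_max_lods=True
        )
        assert t == pytest.approx(maxes.min())

    def test_covariate_path_matches_fast_path_when_trivial(self):
        # A single-level covariate contributes no columns beyond the
        # intercept, so the exact per-permutation path must agree with the
        # vectorized no-covariate path on the same seed.
        h, y = self._panel()
        cov = pd.DataFrame({"batch": ["b1"] * 60}, index=h.rils)
        t_fast = scan.permutation_threshold(h, y, None, n_perm=30, seed=9)
        t_slow = scan.permutation_threshold(h, y, cov, n_perm=30, seed=9)
        assert t_fast == pytest.approx(t_slow, abs=1e-9)

    def test_invalid_parameters(self):
        h, y = self._panel()
        with pytest.raises(ValueError):
            scan.permutation_threshold(h, y, n_perm=0)
        with pytest.raises(ValueError):
            scan.permutation_threshold(h, y, n_perm=10, alpha=0.0)


class TestCallPeaks:
    def _curve(self, lod, pos=None, chrom=None):
        lod = np.asarray(lod, dtype=float)
        pos = np.asarray(pos if pos is not None else np.arange(len(lod)), float)
        chrom = np.asarray(chrom if chrom is not None else ["1"] * len(lod))
        return LodCurve(chrom, pos, lod)

    def test_drop_two_rule_hand_case(self):
        curve = self._curve([0, 2, 4, 6, 4, 0], pos=[1, 3, 5, 7, 9, 11])
        peaks = scan.call_peaks(curve, threshold=3.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.peak_position == 7 and (p.ci_low, p.ci_high) == (5.0, 9.0)

    def test_subthreshold_curve_empty(self):
        curve = self._curve([0.1, 0.5, 0.2])
        assert scan.call_peaks(curve, threshold=3.0) == []

    def test_separation_suppresses_shoulder(self):
        curve = self._curve([0, 5, 4.5, 4.8, 0, 0], pos=[0, 2, 4, 6, 8, 10])
        peaks = scan.call_peaks(curve, threshold=3.0, min_peak_separation=10)
        assert len(peaks) == 1 and peaks[0].peak_position == 2

    def test_distinct_chromosomes_not_suppressed(self):
        curve = self._curve(
            [5, 0, 0, 6, 0, 0], pos=[0, 5, 10, 0, 5, 10], chrom=["1"] * 3 + ["2"] * 3
        )
        peaks = scan.call_peaks(curve, threshold=3.0)
        assert {p.chrom for p in peaks} == {"1", "2"}

    def test_interval_clipped_at_chromosome_end(self):
        curve = self._curve([6, 5, 0], pos=[0, 1, 2])
        p = scan.call_peaks(curve, threshold=3.0)[0]
        assert (p.ci_low, p.ci_high) == (0.0, 1.0)

    def test_empty_curve_error(self):
        with pytest.raises(ValueError):
            scan.call_peaks(self._curve([]), threshold=1.0)


def test_scan_summary_annotates_peaks(two_founder_panel):
    haps, pheno = two_founder_panel
    out = scan.scan_summary(haps, pheno, n_perm=30, alpha=0.5, seed=0)
    assert set(out) == {"curve", "threshold", "peaks", "total_var_explained"}
    if out["peaks"]:
        p = out["peaks"][0]
        assert p.founder_effects is not None and p.var_explained is not None
        assert out["total_var_explained"] == pytest.approx(
            sum(q.var_explained for q in out["peaks"])
        )
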