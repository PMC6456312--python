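"""Generators: determinism, probability structure, ground-truth wiring."""

import numpy as np
import pandas as pd
import pytest

from qgmap import assay, simulate
from qgmap.containers import SimTruth


class TestFounderMosaics:
    def test_rows_are_distributions(self):
        h = simulate.simulate_founder_mosaics(
            30, 8, np.arange(0, 50, 1.0), 8, 0.9, seed=1
        )
        assert np.allclose(h.probs.sum(axis=2), 1.0, atol=1e-9)
        assert h.probs.min() >= 0 and h.probs.max() <= 1

    def test_full_certainty_gives_unit_vectors(self):
        h = simulate.simulate_founder_mosaics(
            20, 5, np.arange(0, 20, 1.0), 4, 1.0, seed=2
        )
        assert np.all(h.probs.max(axis=2) == 1.0)
        assert np.all(h.probs.sum(axis=2) == 1.0)

    def test_same_seed_identical(self):
        kw = dict(
            n_rils=25,
            n_founders=8,
            positions=np.arange(0, 40, 0.5),
            expected_segments=6,
            assignment_certainty=0.92,
        )
        a = simulate.simulate_founder_mosaics(seed=11, **kw)
        b = simulate.simulate_founder_mosaics(seed=11, **kw)
        assert np.array_equal(a.probs, b.probs)
        c = simulate.simulate_founder_mosaics(seed=12, **kw)
        assert not np.array_equal(a.probs, c.probs)

    def test_expected_block_count(self):
        # E[founder switches per RIL] = expected_segments - 1; the oracle
        # counts argmax changes and is compared with the analytic mean of
        # the transition chain (sum of per-gap switch probabilities).
        h = simulate.simulate_founder_mosaics(
            1000, 8, np.arange(0, 100.0 + 1e-9, 1.0), 8, 1.0, seed=3
        )
        states = h.probs.argmax(axis=2)
        switches = (np.diff(states, axis=1) != 0).sum(axis=1)
        gaps = np.diff(h.positions)
        expected = np.minimum(7.0 / 100.0 * gaps, 1.0).sum()
        assert expected == pytest.approx(7.0, abs=1e-9)
        se = switches.std(ddof=1) / np.sqrt(len(switches))
        assert abs(switches.mean() - 7.0) < 4 * se + 0.05

    @pytest.mark.parametrize(
        "kw",
        [
            {"positions": np.array([0.0, 1.0, 0.5])},
            {"assignment_certainty": 0.05},
            {"assignment_certainty": 1.2},
            {"n_founders": 1},
        ],
    )
    def test_invalid_inputs(self, kw):
        args = dict(
            n_rils=5,
            n_founders=8,
            positions=np.arange(0, 10, 1.0),
            expected_segments=3,
            assignment_certainty=0.9,
            seed=0,
        )
        args.update(kw)
        with pytest.raises(ValueError):
            simulate.simulate_founder_mosaics(**args)


class TestRilPhenotypes:
    def _panel(self, certainty=1.0, n=40, seed=5):
        return simulate.simulate_founder_mosaics(
            n, 8, np.arange(0, 20, 1.0), 3, certainty, seed=seed
        )

    def test_noise_free_identity(self):
        h = self._panel()
        rng = np.random.default_rng(0)
        truth = SimTruth(
            qtl_positions=[10.0],
            founder_effects=[list(rng.normal(0, 1, 8))],
            target_h2=1.0,
        )
        ph = simulate.simulate_ril_phenotypes(h, truth, n_reps=1, seed=1)
        g = h.probs[:, 10, :] @ np.array(truth.founder_effects[0])
        assert np.allclose(ph["value"].to_numpy(), g)

    def test_single_qtl_hard_assignment_offset(self):
        h = self._panel()
        truth = SimTruth(
            qtl_positions=[10.0],
            founder_effects=[[5.0, 0, 0, 0, 0, 0, 0, 0]],
            target_h2=1.0,
        )
        ph = simulate.simulate_ril_phenotypes(h, truth, n_reps=1, seed=1)
        carrier = h.probs[:, 10, 0] == 1.0
        vals = ph.set_index("strain")["value"].reindex(h.rils).to_numpy()
        assert np.allclose(vals[carrier], 5.0)
        assert np.allclose(vals[~carrier], 0.0)

    def test_target_h2_sets_noise_analytically(self):
        h = self._panel(n=200)
        rng = np.random.default_rng(1)
        truth = SimTruth(
            qtl_positions=[5.0],
            founder_effects=[list(rng.normal(0, 2, 8))],
            target_h2=0.6,
        )
        simulate.simulate_ril_phenotypes(h, truth, n_reps=2, seed=2)
        g = h.probs[:, 5, :] @ np.array(truth.founder_effects[0])
        v_g = np.var(g)
        assert truth.env_sd**2 == pytest.approx(v_g * 0.4 / 0.6, rel=1e-12)

    def test_off_grid_qtl_rejected(self):
        h = self._panel()
        truth = SimTruth(
            qtl_positions=[10.37], founder_effects=[[1.0] * 8], target_h2=0.5
        )
        with pytest.raises(KeyError):
            simulate.simulate_ril_phenotypes(h, truth, n_reps=1, seed=0)

    def test_null_truth_gives_iid_noise(self):
        h = self._panel(n=100)
        truth = SimTruth(target_h2=0.0)
        ph = simulate.simulate_ril_phenotypes(h, truth, n_reps=2, seed=3)
        assert truth.env_sd == 1.0
        assert ph["value"].std() == pytest.approx(1.0, rel=0.2)

    def test_covariate_shifts_additive(self):
        h = self._panel(n=10)
        truth = SimTruth(target_h2=0.0)
        ph = simulate.simulate_ril_phenotypes(
            h, truth, n_reps=1, covariate_shifts={"pA1": 0.0, "pA2": 100.0}, seed=4
        )
        means = ph.groupby("subpop")["value"].mean()
        assert means["pA2"] - means["pA1"] == pytest.approx(100.0, abs=2.0)


class TestLinePanel:
    def test_same_seed_identical(self):
        a = simulate.simulate_line_panel(n_lines=50, n_snps=100, seed=9)
        b = simulate.simulate_line_panel(n_lines=50, n_snps=100, seed=9)
        assert np.array_equal(a[0].counts, b[0].counts)
        for pa, pb in zip(a[1], b[1]):
            assert pa.equals(pb)

    def test_homozygous_and_maf_floor(self):
        geno, _, _ = simulate.simulate_line_panel(n_lines=80, n_snps=300, seed=10)
        assert set(np.unique(geno.counts)) <= {0.0, 2.0}
        assert geno.maf().min() >= 0.05

    def test_shared_signal_perfect_correlation(self):
        sp = [
            {"shift": 0.0, "scale": 1.0, "noise_sd": 0.0},
            {"shift": 42.0, "scale": 1.0, "noise_sd": 0.0},
        ]
        _, phenos, _ = simulate.simulate_line_panel(
            n_lines=60, n_snps=200, n_causal=10, n_studies=2, study_params=sp, seed=11
        )
        r = np.corrcoef(phenos[0], phenos[1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert (phenos[1] - phenos[0]).mean() == pytest.approx(42.0, abs=1e-9)

    def test_no_causal_snps_no_correlation(self):
        rs = []
        for s in range(10):
            _, phenos, _ = simulate.simulate_line_panel(
                n_lines=400, n_snps=50, n_causal=0, n_studies=2, seed=100 + s
            )
            rs.append(np.corrcoef(phenos[0], phenos[1])[0, 1])
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(400 * 10)

    def test_maf_floor_below_005_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_line_panel(n_lines=20, n_snps=10, maf_min=0.01, seed=0)


class TestPlate:
    def test_zero_noise_round_trip(self):
        conc = np.array([0.0, 0.4, 1.0, 2.5, 3.3])
        plate, table = simulate.simulate_plate(conc, noise_sd=0.0, seed=0)
        rec = assay.triglyceride_concentration(plate)
        assert np.allclose(rec, conc, atol=1e-10)
        per_sample = assay.plate_table_concentrations(table)
        assert np.allclose(per_sample["concentration"].to_numpy(), conc, atol=1e-10)

    def test_zero_concentration_zero_numerator(self):
        plate, _ = simulate.simulate_plate(np.array([0.0]), noise_sd=0.0, seed=0)
        assert plate.fa_sample[0] == pytest.approx(
            plate.ia_sample[0] * plate.correction_factor
        )
        assert assay.triglyceride_concentration(plate)[0] == pytest.approx(0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_plate(np.array([-0.1]))

    def test_noise_matches_delta_method(self):
        # First-order propagation through the formula: per-sample variance
        # (C_std/D)^2 * (sigma_FA^2 + F^2 * 2 sigma^2), the IA term doubled
        # because IA is a difference of two scans.
        sigma = 0.01
        plate, _ = simulate.simulate_plate(
            np.full(1000, 1.0), noise_sd=sigma, seed=42
        )
        rec = assay.triglyceride_concentration(plate)
        d = 0.9 - 0.05 * 0.8
        pred_sd = 2.5 / d * sigma * np.sqrt(1.0 + 0.8**2 * 2.0)
        assert rec.mean() == pytest.approx(1.0, abs=0.05)
        assert rec.std() == pytest.approx(pred_sd, rel=0.15)
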