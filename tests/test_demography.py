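"""Neutrality statistics, mismatch model, expansion fitting and dating."""

import itertools
import math

import numpy as np
import pytest

from haplogeo.demography import (
    DATING_PRESETS,
    DatingInput,
    SuddenExpansionModel,
    classify_modality,
    date_expansion,
    expected_mismatch,
    fit_sudden_expansion,
    fu_fs_statistic,
    mismatch_histogram,
    raggedness,
    tajima_d,
    tajima_d_statistic,
)

from conftest import haplotypes_from_sequences


class TestTajimaDStatistic:
    def test_matches_independent_formula(self):
        """Independent re-derivation of every constant, 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 60))
            S = int(rng.integers(1, 40))
            pi = float(rng.uniform(0.1, 15.0))

            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
            assert tajima_d_statistic(S, pi, n) == pytest.approx(expected, abs=1e-12)

    def test_zero_when_pi_equals_watterson(self):
        n = 10
        a1 = sum(1 / i for i in range(1, n))
        S = 8
        assert tajima_d_statistic(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_sign_conventions(self):
        # excess rare variants (pi < S/a1) -> negative D
        assert tajima_d_statistic(10, 1.0, 20) < 0
        assert tajima_d_statistic(10, 6.0, 20) > 0

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            tajima_d_statistic(5, 1.0, 3)

    def test_no_segregating_sites_nan(self):
        assert np.isnan(tajima_d_statistic(0, 0.0, 10))


class TestFuFsStatistic:
    def test_ewens_expectation_sign(self):
        """More haplotypes than neutrality predicts -> negative F_S."""
        n, pi = 30, 2.0
        # expected K under Ewens for theta=2: sum theta/(theta+i)
        k_exp = sum(pi / (pi + i) for i in range(n))
        assert fu_fs_statistic(pi, int(np.ceil(k_exp)) + 6, n) < 0
        assert fu_fs_statistic(pi, max(2, int(k_exp) - 4), n) > 0

    def test_matches_direct_ewens_sum(self):
        """Oracle: exact Ewens sampling probabilities via Stirling numbers."""
        n, theta = 8, 1.5
        # unsigned Stirling numbers of the first kind, recurrence
        s = np.zeros((n + 1, n + 1))
        s[0, 0] = 1
        for m in range(1, n + 1):
            for k in range(1, m + 1):
                s[m, k] = s[m - 1, k - 1] + (m - 1) * s[m - 1, k]
        rising = np.prod([theta + i for i in range(n)])
        probs = np.array([s[n, k] * theta**k / rising for k in range(n + 1)])
        for k_obs in range(2, n + 1):
            sp = probs[k_obs:].sum()
            expected = math.log(sp / (1 - sp))
            assert fu_fs_statistic(theta, k_obs, n) == pytest.approx(expected, abs=1e-10)

    def test_undefined_for_zero_pi(self):
        assert np.isnan(fu_fs_statistic(0.0, 3, 10))


class TestMismatchHistogram:
    def test_hand_counted(self):
        # 2 copies of AAAA, 1 of AAAT, 1 of AATT
        h, d = haplotypes_from_sequences(["AAAA", "AAAA", "AAAT", "AATT"])
        hist = mismatch_histogram(h, d)
        # pairs: (AAAA,AAAA)=0; 2x(AAAA,AAAT)=1; 2x(AAAA,AATT)=2; (AAAT,AATT)=1
        assert hist.tolist() == [1, 3, 2]
        assert hist.sum() == 6  # C(4,2)

    def test_total_is_all_pairs(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("AT"), 15)) for _ in range(9)]
        h, d = haplotypes_from_sequences(seqs)
        hist = mismatch_histogram(h, d)
        assert hist.sum() == 9 * 8 // 2

    def test_needs_two_individuals(self):
        h, d = haplotypes_from_sequences(["AAAA", "AAAA"])
        single = haplotypes_from_sequences(["AAAA"])
        with pytest.raises(ValueError):
            mismatch_histogram(*single)


class TestExpectedMismatch:
    def test_tau_zero_is_stationary(self):
        theta = 3.0
        e = expected_mismatch(0.0, theta, 50.0, 30)
        j = np.arange(29)
        stationary = theta**j / (1 + theta) ** (j + 1)
        np.testing.assert_allclose(e[:29], stationary, rtol=1e-10)

    def test_sums_to_one(self):
        for tau, t0, t1 in [(0.5, 0.1, 10), (3, 1, 100), (8, 0.01, 50)]:
            e = expected_mismatch(tau, t0, t1, 40)
            assert e.sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_thetas_collapse_to_stationary(self):
        e1 = expected_mismatch(5.0, 2.0, 2.0, 25)
        e2 = expected_mismatch(0.0, 2.0, 2.0, 25)
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_large_theta1_peak_near_tau(self):
        """theta0 -> 0, theta1 large: the curve peaks near tau."""
        e = expected_mismatch(6.0, 0.01, 1000.0, 30)
        assert abs(int(np.argmax(e)) - 6) <= 1

    def test_nonnegative(self):
        e = expected_mismatch(2.5, 0.5, 30.0, 40)
        assert (e >= 0).all()


class TestRaggedness:
    def test_hand_computed(self):
        # hist [2, 2] -> x = [0.5, 0.5]; with leading zero class:
        # (0.5-0)^2 + (0.5-0.5)^2 = 0.25
        assert raggedness(np.array([2, 2])) == pytest.approx(0.25)

    def test_smooth_lower_than_ragged(self):
        smooth = np.array([1, 4, 8, 10, 8, 4, 1], dtype=float)
        ragged = np.array([8, 1, 9, 0, 10, 1, 7], dtype=float)
        assert raggedness(smooth) < raggedness(ragged)


class TestFitSuddenExpansion:
    def test_recovers_exact_expansion_curve(self):
        """Noise-free expected curve: parameters recovered closely."""
        tau, t0, t1 = 4.0, 0.1, 60.0
        e = expected_mismatch(tau, t0, t1, 30)
        hist = np.round(e * 1e6).astype(int)
        fit = fit_sudden_expansion(hist, n=50)
        assert fit.tau == pytest.approx(tau, rel=0.1)
        assert fit.ssd < 1e-5

    def test_stationary_curve_gives_small_tau(self):
        """Exact stationary curve: smallest-tau tie-break avoids the ridge."""
        e = expected_mismatch(0.0, 2.0, 2.0, 25)
        hist = np.round(e * 1e6).astype(int)
        fit = fit_sudden_expansion(hist, n=40)
        assert fit.tau < 0.5
        assert fit.theta0 == pytest.approx(2.0, rel=0.05)

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError):
            fit_sudden_expansion(np.zeros(5), n=10)

    def test_model_wrapper(self):
        h, d = haplotypes_from_sequences(
            ["AAAAA", "AAAAT", "AAATT", "AATTT", "AAAAA", "AAAAT"]
        )
        model = SuddenExpansionModel.from_haplotypes(h, d)
        fit = model.fit()
        assert fit.n == 6
        assert fit.p_ssd is None  # gof off by default
        assert np.array_equal(fit.histogram, mismatch_histogram(h, d))


class TestGofBootstrap:
    def test_bootstrap_fields_and_reproducibility(self):
        h, d = haplotypes_from_sequences(
            ["AAAAAA", "AAAAAT", "AAAATT", "AAATTT", "AAAAAA",
             "AAAAAT", "AAAATT", "TAAAAA"]
        )
        model = SuddenExpansionModel.from_haplotypes(h, d)
        f1 = model.fit(gof=True, n_boot=120, seed=5)
        f2 = model.fit(gof=True, n_boot=120, seed=5)
        assert 0 < f1.p_ssd <= 1
        assert 0 < f1.p_rag <= 1
        assert f1.tau_ci[0] <= f1.tau_ci[1]
        assert (f1.p_ssd, f1.p_rag, f1.tau_ci) == (f2.p_ssd, f2.p_rag, f2.tau_ci)


class TestNeutralityPipeline:
    def test_tajima_d_observed_matches_statistic(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "AAAAAAATTT",
                "AAAAAAAAAA", "AAAAAAAAAT"]
        h, d = haplotypes_from_sequences(seqs)
        res = tajima_d(h, d, n_sims=0)
        # oracle: S and pi by hand over the 6 sequences
        S = 3
        pairs = list(itertools.combinations(seqs, 2))
        pi = np.mean([sum(a != b for a, b in zip(x, y)) for x, y in pairs])
        assert res.S == S
        assert res.pi == pytest.approx(pi, abs=1e-12)
        assert res.statistic == pytest.approx(tajima_d_statistic(S, pi, 6), abs=1e-12)

    def test_p_value_reasonable_for_neutralish_data(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "AAAAAAATTT",
                "AAAAAAAAAA", "AAAAAAAAAT"]
        h, d = haplotypes_from_sequences(seqs)
        res = tajima_d(h, d, n_sims=300, seed=0)
        assert 0.05 < res.p_value < 0.95


class TestDating:
    def test_published_worked_examples(self):
        """Three preset (mu, k, g) combinations with their printed dates."""
        cases = [
            ("C_tibetana", 0.625, 9_600),
            ("M_thunbergii", 0.438, 3_700),
            ("S_superba", 0.082, 6_100),
        ]
        for preset, tau, T in cases:
            date = date_expansion(tau, DATING_PRESETS[preset], rounding="paper")
            assert date.T == T

    def test_unrounded_formula(self):
        d = DatingInput(mu=1e-9, k=1000, g=10)
        date = date_expansion(2.0, d)
        assert date.T == pytest.approx(2.0 / (2 * 1e-9 * 1000 * 10))

    def test_ci_transforms(self):
        d = DatingInput(mu=1e-9, k=1000, g=10)
        date = date_expansion(2.0, d, tau_ci=(1.0, 3.0))
        assert date.ci[0] == pytest.approx(0.5 * date.T)
        assert date.ci[1] == pytest.approx(1.5 * date.T)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            DatingInput(0, 1000, 10)
        with pytest.raises(ValueError):
            date_expansion(-1, DatingInput(1e-9, 1000, 10))
        with pytest.raises(ValueError):
            date_expansion(1, DatingInput(1e-9, 1000, 10), rounding="ceil")


class TestModality:
    def test_unimodal(self):
        assert classify_modality(np.array([2, 6, 10, 6, 2, 1])) == "unimodal"

    def test_bimodal(self):
        hist = np.array([10, 6, 1, 0, 0, 1, 6, 10, 6, 1], dtype=float)
        assert classify_modality(hist) in ("bimodal", "multimodal")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_modality(np.zeros(4))
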