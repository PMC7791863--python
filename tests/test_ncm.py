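"""Neutral community model: prediction, fitting, intervals, partitioning."""

import numpy as np
import pytest
from scipy import special

from gutneutral.ncm import (
    NcmInput,
    build_ncm_input,
    fit_ncm,
    fit_ncm_per_group,
    predict_freq,
    wilson_interval,
)
from gutneutral.neutral_sim import (
    SimConfig,
    make_study_fixture,
    sample_source,
    simulate_beta_multinomial,
)
from gutneutral.otu_io import OtuTable


def _noiseless_input(m0=0.03, n_otus=300, N=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    p = np.sort(10 ** rng.uniform(-5, -0.5, size=n_otus))
    d = 1.0 / N
    f = predict_freq(p, N, m0, d)
    return NcmInput(p=p, f=f, n_samples=29, N=N, d=d,
                    otu_ids=[f"O{i}" for i in range(n_otus)])


class TestBuildNcmInput:
    def test_ubiquitous_otu_has_frequency_one(self, random_table):
        inp = build_ncm_input(random_table)
        j = inp.otu_ids.index("OTU_0")  # fixture guarantees OTU_0 in all samples
        assert inp.f[j] == 1.0

    def test_mean_depth_and_default_detection_limit(self):
        t = OtuTable(
            ["S1", "S2", "S3"],
            ["a", "b"],
            np.array([[50, 50], [100, 100], [150, 150]]),
        )
        inp = build_ncm_input(t)
        assert inp.N == 200.0
        assert inp.d == pytest.approx(0.005)

    def test_p_and_f_match_double_loop_tally(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 20, size=(10, 50))
        counts[:, 0] += 1
        t = OtuTable([f"S{i}" for i in range(10)], [f"O{j}" for j in range(50)], counts)
        inp = build_ncm_input(t)
        # brute-force double loop
        p_exp, f_exp, ids = [], [], []
        for j in range(50):
            ps, det = [], 0
            for i in range(10):
                ps.append(counts[i, j] / counts[i].sum())
                det += counts[i, j] >= 1
            if np.mean(ps) > 0:
                p_exp.append(np.mean(ps))
                f_exp.append(det / 10)
                ids.append(f"O{j}")
        assert inp.otu_ids == ids
        assert np.allclose(inp.p, p_exp, atol=1e-14)
        assert np.allclose(inp.f, f_exp, atol=1e-14)

    def test_fewer_than_two_samples_rejected(self):
        t = OtuTable(["S1"], ["a"], np.array([[5]]))
        with pytest.raises(ValueError, match="2 samples"):
            build_ncm_input(t)


class TestPredictFreq:
    def test_detection_limit_to_zero_gives_certain_detection(self):
        assert predict_freq(0.1, 1000, 0.1, 1e-300) == pytest.approx(1.0)

    def test_symmetric_beta_median_half(self):
        # p = 0.5 makes the two shape parameters equal; CDF at 0.5 is 0.5
        assert predict_freq(0.5, 1000, 0.1, 0.5) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(123)
        N, m, d = 1000, 0.05, 0.001
        p = 0.01
        draws = rng.beta(N * m * p, N * m * (1 - p), size=10**6)
        assert predict_freq(p, N, m, d) == pytest.approx(
            float((draws > d).mean()), abs=1e-3
        )

    def test_non_decreasing_in_p_on_grid(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 100)
        vals = predict_freq(grid, 1000, 0.05, 0.001)
        assert np.all(np.diff(vals) >= -1e-12)

    @pytest.mark.parametrize("p,m,d", [(0.0, 0.1, 0.1), (1.5, 0.1, 0.1), (0.5, 0.0, 0.1), (0.5, 0.1, 0.0)])
    def test_domain_errors(self, p, m, d):
        with pytest.raises(ValueError):
            predict_freq(p, 1000, m, d)


class TestWilsonInterval:
    def test_lower_bound_zero_at_zero_proportion(self):
        lo, hi = wilson_interval(0.0, 29)
        assert lo == 0.0 and hi > 0

    def test_matches_high_precision_closed_form(self):
        # 50-digit evaluation of the Wilson closed form, frozen
        # p=0.5, n=10, z=1.959963984540054...
        lo, hi = wilson_interval(0.5, 10)
        assert lo == pytest.approx(0.236593090512564, abs=1e-12)
        assert hi == pytest.approx(0.763406909487436, abs=1e-12)

    def test_coverage_at_small_n(self):
        rng = np.random.default_rng(99)
        cover = 0
        for _ in range(2000):
            k = rng.binomial(29, 0.3)
            lo, hi = wilson_interval(k / 29, 29)
            cover += lo <= 0.3 <= hi
        assert cover / 2000 >= 0.93

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            wilson_interval(0.5, 0)


class TestFitNcm:
    def test_self_consistency_on_noiseless_frequencies(self):
        inp = _noiseless_input(m0=0.03)
        fit = fit_ncm(inp)
        assert fit.m == pytest.approx(0.03, abs=1e-4)
        assert fit.r_squared >= 0.999
        assert fit.Nm == pytest.approx(fit.N * fit.m)

    def test_simulated_recovery_and_grid_search_agreement(self):
        m0 = 0.05
        src = sample_source(300, "logseries", seed=21)
        cfg = SimConfig(n_samples=30, community_size_N=1000,
                        reads_per_sample=1000, m=m0, seed=22)
        table = simulate_beta_multinomial(src, cfg)
        inp = build_ncm_input(table)
        fit = fit_ncm(inp)
        assert abs(fit.m - m0) / m0 <= 0.20
        # independent dense grid oracle
        grid = np.arange(0.001, 0.2001, 0.001)
        p = np.minimum(inp.p, 1 - 1e-12)
        sses = [
            float(np.sum((inp.f - (1 - special.betainc(inp.N * g * p,
                                                       inp.N * g * (1 - p),
                                                       inp.d))) ** 2))
            for g in grid
        ]
        best = grid[int(np.argmin(sses))]
        assert abs(fit.m - best) <= 0.001 + 1e-9

    def test_permuted_frequencies_destroy_fit(self):
        inp = _noiseless_input(m0=0.03, seed=5)
        rng = np.random.default_rng(6)
        f_perm = rng.permutation(inp.f)
        inp_perm = NcmInput(p=inp.p, f=f_perm, n_samples=inp.n_samples,
                            N=inp.N, d=inp.d, otu_ids=inp.otu_ids)
        assert fit_ncm(inp_perm).r_squared < 0.2

    def test_degenerate_frequencies_rejected(self):
        inp = _noiseless_input()
        bad = NcmInput(p=inp.p, f=np.full_like(inp.f, 0.5),
                       n_samples=29, N=inp.N, d=inp.d, otu_ids=inp.otu_ids)
        with pytest.raises(ValueError, match="degenerate"):
            fit_ncm(bad)

    def test_band_and_partition_consistency(self):
        src = sample_source(200, "logseries", seed=31)
        cfg = SimConfig(n_samples=20, community_size_N=1000, m=0.05, seed=32)
        fit = fit_ncm(build_ncm_input(simulate_beta_multinomial(src, cfg)))
        assert np.all(fit.band_lower <= fit.predicted_f + 1e-12)
        assert np.all(fit.predicted_f <= fit.band_upper + 1e-12)
        assert abs(sum(fit.partition_fractions.values()) - 1.0) < 1e-12
        for fi, lo, hi, lab in zip(fit.f, fit.band_lower, fit.band_upper, fit.partition):
            expected = "above" if fi > hi else ("below" if fi < lo else "neutral")
            assert lab == expected

    def test_invariant_to_row_and_column_order(self):
        src = sample_source(100, "logseries", seed=41)
        cfg = SimConfig(n_samples=15, community_size_N=1000, m=0.05, seed=42)
        t = simulate_beta_multinomial(src, cfg)
        rng = np.random.default_rng(43)
        ci = rng.permutation(t.n_otus)
        ri = rng.permutation(t.n_samples)
        t2 = OtuTable(
            [t.sample_ids[i] for i in ri],
            [t.otu_ids[j] for j in ci],
            t.counts[np.ix_(ri, ci)],
        )
        f1 = fit_ncm(build_ncm_input(t))
        f2 = fit_ncm(build_ncm_input(t2))
        assert f1.m == pytest.approx(f2.m, rel=1e-6)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-6)

    def test_model_beats_permuted_data_consistently(self):
        wins = 0
        for rep in range(100):
            inp = _noiseless_input(m0=0.04, n_otus=100, seed=rep)
            rng = np.random.default_rng(rep + 10_000)
            noisy_f = np.clip(
                rng.binomial(29, inp.f) / 29, 0, 1
            )  # sampling noise only
            inp_n = NcmInput(p=inp.p, f=noisy_f, n_samples=29, N=inp.N,
                             d=inp.d, otu_ids=inp.otu_ids)
            inp_p = NcmInput(p=inp.p, f=rng.permutation(noisy_f), n_samples=29,
                             N=inp.N, d=inp.d, otu_ids=inp.otu_ids)
            wins += fit_ncm(inp_n).r_squared > fit_ncm(inp_p).r_squared
        assert wins >= 95

    def test_per_group_fit_on_study_fixture(self):
        t = make_study_fixture(seed=3)
        fits = fit_ncm_per_group(t)
        assert set(fits) == {"Control", "N_lim", "P_lim"}
        for fit in fits.values():
            assert 0 < fit.m <= 1
            assert fit.m_ci[0] <= fit.m <= fit.m_ci[1]
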