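"""Unit and oracle tests for the four uniqueness estimators."""

import math
from fractions import Fraction

import numpy as np
import pytest

from uniqrisk import (
    EquivalenceClassTable,
    FrequencySpectrum,
    SamplingContext,
    build_equivalence_classes,
    estimate_all,
    estimate_mu_argus,
    estimate_pitman,
    estimate_snb,
    estimate_zayatz,
    lambda3,
    spectrum,
)
from uniqrisk.estimators import (
    mu_argus_posterior_pmf,
    pitman_expected_singleton_fraction,
    pitman_loglik,
)
from uniqrisk.exceptions import InputError, ParameterError
from uniqrisk.frequency import MicrodataTable
from uniqrisk.synthetic import crp_class_sizes, generate_crp_population, generate_snb_population


def crp_fixture_spectrum(n=400, alpha=0.3, theta=15.0, seed=5):
    return FrequencySpectrum.from_class_sizes(crp_class_sizes(n, alpha, theta, seed))


class TestSamplingContext:
    def test_pi_derived(self):
        assert SamplingContext(50, 200).pi == 0.25

    @pytest.mark.parametrize("n, N", [(0, 5), (6, 5), (-1, 5)])
    def test_invalid(self, n, N):
        with pytest.raises(ParameterError):
            SamplingContext(n, N)

    def test_spectrum_total_must_match_n(self):
        spec = FrequencySpectrum({1: 3}, 3, 3)
        with pytest.raises(InputError):
            estimate_zayatz(spec, SamplingContext(4, 10))


class TestZayatz:
    def test_exact_rational_oracle(self):
        """Direct summation of every hypergeometric term in exact arithmetic."""
        spec = FrequencySpectrum({1: 3, 2: 2, 3: 1}, 10, 6)
        n, N = 10, 20
        res = estimate_zayatz(spec, SamplingContext(n, N))

        def p(j):
            return Fraction(j * math.comb(N - j, n - 1), math.comb(N, n))

        num = p(1) * Fraction(3, 6)
        den = num + p(2) * Fraction(2, 6) + p(3) * Fraction(1, 6)
        expected = Fraction(3) * (num / den) / Fraction(n)
        assert res.lambda3_hat == pytest.approx(float(expected), abs=1e-14)
        assert res.converged

    def test_full_sample_is_exact(self):
        pop = generate_crp_population(300, 0.2, 10.0, seed=2)
        spec = spectrum(pop)
        res = estimate_zayatz(spec, SamplingContext(pop.total, pop.total))
        assert res.lambda3_hat == pytest.approx(lambda3(pop), abs=1e-12)

    def test_no_sample_uniques_gives_zero(self):
        spec = FrequencySpectrum({2: 4}, 8, 4)
        assert estimate_zayatz(spec, SamplingContext(8, 40)).lambda3_hat == 0.0

    def test_deterministic(self):
        spec = crp_fixture_spectrum()
        ctx = SamplingContext(spec.total, 4 * spec.total)
        a = estimate_zayatz(spec, ctx)
        b = estimate_zayatz(spec, ctx)
        assert a.lambda3_hat == b.lambda3_hat


class TestMuArgus:
    def test_posterior_rederivation_oracle(self):
        """Re-derive P(F=1|f=1) by brute-force evaluation of the shifted
        negative binomial posterior series and check normalization."""
        pi = 0.1
        series = [mu_argus_posterior_pmf(F, 1, pi) for F in range(1, 4000)]
        assert sum(series) == pytest.approx(1.0, abs=1e-12)  # proper posterior
        assert series[0] == pytest.approx(pi, abs=1e-15)

        spec = FrequencySpectrum({1: 5, 2: 3}, 11, 8)
        res = estimate_mu_argus(spec, SamplingContext(11, 110))
        expected = 5 * series[0] / (pi * 110)
        assert res.lambda3_hat == pytest.approx(expected, abs=1e-12)

    def test_full_sample_limit(self):
        spec = FrequencySpectrum({1: 4, 3: 2}, 10, 6)
        res = estimate_mu_argus(spec, SamplingContext(10, 10))
        assert res.lambda3_hat == pytest.approx(4 / 10)

    def test_no_sample_uniques_gives_zero(self):
        spec = FrequencySpectrum({2: 4}, 8, 4)
        assert estimate_mu_argus(spec, SamplingContext(8, 80)).lambda3_hat == 0.0


class TestPitman:
    def test_ewens_singleton_closed_form(self):
        # E[M1(N)] = theta*N/(theta+N-1) at alpha = 0
        for theta, N in [(5.0, 100), (20.0, 2000)]:
            assert pitman_expected_singleton_fraction(0.0, theta, N) * N == pytest.approx(
                theta * N / (theta + N - 1)
            )

    @pytest.mark.parametrize("alpha", [0.0, 0.25])
    def test_predictive_singletons_match_crp_oracle(self, alpha):
        """The predictive singleton expectation agrees with a seeded CRP
        Monte Carlo oracle, in the Ewens case and the general case."""
        theta, N, draws = 20.0, 400, 2000
        m1 = np.array(
            [
                sum(1 for s in crp_class_sizes(N, alpha, theta, seed) if s == 1)
                for seed in range(draws)
            ],
            dtype=float,
        )
        se = m1.std() / math.sqrt(draws)
        expected = N * pitman_expected_singleton_fraction(alpha, theta, N)
        assert abs(m1.mean() - expected) <= 3 * se

    def test_degenerate_single_class(self):
        spec = FrequencySpectrum({50: 1}, 50, 1)
        res = estimate_pitman(spec, SamplingContext(50, 500))
        assert res.converged
        assert res.lambda3_hat <= 1 / 500

    def test_all_singletons_hits_alpha_boundary(self):
        spec = FrequencySpectrum({1: 40}, 40, 40)
        res = estimate_pitman(spec, SamplingContext(40, 4000))
        assert res.converged
        assert res.diagnostics["boundary_alpha"]
        assert res.params["alpha"] == pytest.approx(1.0, abs=1e-5)
        assert res.lambda3_hat == pytest.approx(1.0, abs=1e-3)

    def test_local_optimality_on_grid(self):
        """No grid neighbour (step 0.01) of the fitted (alpha, theta) has a
        higher log-likelihood."""
        spec = crp_fixture_spectrum()
        res = estimate_pitman(spec, SamplingContext(spec.total, 10 * spec.total))
        a, t = res.params["alpha"], res.params["theta"]
        best = pitman_loglik(a, t, spec)
        for da in (-0.01, 0.0, 0.01):
            for dt in (-0.01, 0.0, 0.01):
                aa, tt = a + da, t + dt
                if not (0.0 <= aa < 1.0 and tt > -aa):
                    continue
                assert pitman_loglik(aa, tt, spec) <= best + 1e-7

    def test_full_sample_close_to_truth_on_crp_fixture(self):
        pop = generate_crp_population(2000, 0.3, 30.0, seed=8)
        res = estimate_pitman(spectrum(pop), SamplingContext(pop.total, pop.total))
        assert res.converged
        assert res.lambda3_hat == pytest.approx(lambda3(pop), abs=0.05)


class TestSnb:
    def test_full_sample_close_to_truth(self):
        pop = generate_snb_population(800, 1.0, 0.4, seed=7)
        N = pop.total
        res = estimate_snb(spectrum(pop), SamplingContext(N, N))
        assert res.converged
        assert res.lambda3_hat == pytest.approx(lambda3(pop), abs=0.02)

    def test_all_singleton_stress_case_never_silent(self):
        """With an all-singleton spectrum at tiny pi the fit may fail; a
        failure must carry converged=False and no estimate."""
        spec = FrequencySpectrum({1: 30}, 30, 30)
        res = estimate_snb(spec, SamplingContext(30, 3000))
        if not res.converged:
            assert res.lambda3_hat is None
        else:
            assert 0.0 <= res.lambda3_hat <= 1.0

    def test_estimate_in_unit_interval_when_converged(self):
        for seed in range(5):
            pop = generate_snb_population(200, 1.5, 0.5, seed=seed)
            res = estimate_snb(spectrum(pop), SamplingContext(pop.total, 2 * pop.total))
            if res.converged:
                assert 0.0 <= res.lambda3_hat <= 1.0


class TestSufficiencyAndAggregation:
    def test_estimates_depend_only_on_spectrum(self):
        """Permuting records / relabelling classes leaves every estimate
        bit-identical (the spectrum is sufficient)."""
        recs = [("a",)] * 3 + [("b",)] * 2 + [("c",), ("d",)]
        t1 = MicrodataTable(("q",), recs)
        t2 = MicrodataTable(("q",), [("x" + r[0],) for r in reversed(recs)])
        s1 = spectrum(build_equivalence_classes(t1))
        s2 = spectrum(build_equivalence_classes(t2))
        assert s1 == s2
        ctx = SamplingContext(7, 70)
        for r1, r2 in zip(estimate_all(s1, ctx), estimate_all(s2, ctx)):
            assert r1.estimator_name == r2.estimator_name
            assert r1.lambda3_hat == r2.lambda3_hat
            assert r1.converged == r2.converged

    def test_estimate_all_returns_four_in_stable_order(self):
        spec = crp_fixture_spectrum(n=100)
        ctx = SamplingContext(100, 1000)
        res = estimate_all(spec, ctx)
        assert [r.estimator_name for r in res] == ["pitman", "snb", "zayatz", "mu_argus"]

    def test_estimate_all_isolates_failures(self, monkeypatch):
        import uniqrisk.estimators as est

        def boom(spec, ctx):
            raise RuntimeError("fit exploded")

        monkeypatch.setitem(est._ESTIMATORS, "snb", boom)
        spec = crp_fixture_spectrum(n=100)
        res = est.estimate_all(spec, SamplingContext(100, 1000))
        by_name = {r.estimator_name: r for r in res}
        assert by_name["snb"].converged is False and by_name["snb"].lambda3_hat is None
        assert by_name["zayatz"].converged and by_name["pitman"].converged
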