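"""RBP log-odds scoring, score distributions, beta prior and switch probability."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from intronscore import rbp
from intronscore.rbp import (BetaPrior, RbpPwm, RbpScorer, m_value,
                             matching_score, omega, p_switch,
                             p_switch_conditional, phi, score_distribution,
                             solve_beta_prior)


def _random_pwm(rng, k=None):
    k = k or int(rng.integers(3, 8))
    counts = rng.integers(0, 60, size=(k, 4)).astype(float)
    return RbpPwm("r", counts, float(counts.sum(axis=1).max()) + 1.0)


class TestLogOdds:
    def test_uniform_counts_give_zero(self):
        pwm = RbpPwm("u", np.full((3, 4), 7.0), 28)
        np.testing.assert_allclose(pwm.log_odds(), 0.0, atol=1e-12)

    def test_hand_arithmetic_k1(self, toy_pwm):
        s = toy_pwm.log_odds()[0]
        assert s[0] == pytest.approx(1.0, abs=1e-9)
        # (0 + 2) / (4 + 8) / 0.25 = 2/3
        assert s[1] == pytest.approx(np.log2(2 / 3), abs=1e-9)

    def test_doubling_counts_changes_only_pseudocount(self):
        counts = np.array([[8.0, 2.0, 1.0, 1.0]])
        a = RbpPwm("a", counts, 12.0)
        b = RbpPwm("b", 2 * counts, 24.0)
        ca, cb = np.sqrt(12.0), np.sqrt(24.0)
        exp_a = np.log2(((counts + ca) / (12 + 4 * ca)) / 0.25)
        exp_b = np.log2(((2 * counts + cb) / (24 + 4 * cb)) / 0.25)
        np.testing.assert_allclose(a.log_odds(), exp_a, atol=1e-12)
        np.testing.assert_allclose(b.log_odds(), exp_b, atol=1e-12)


class TestMatchingScore:
    def test_toy_sequence(self, toy_pwm):
        assert matching_score("A", toy_pwm.log_odds()) == pytest.approx(1.0)

    def test_consensus_maximal(self):
        rng = np.random.default_rng(3)
        pwm = _random_pwm(rng, k=5)
        lom = pwm.log_odds()
        smax = matching_score(pwm.consensus(), lom)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=5))
            assert matching_score(seq, lom) <= smax + 1e-12

    def test_length_mismatch_raises(self, toy_pwm):
        with pytest.raises(ValueError):
            matching_score("AC", toy_pwm.log_odds())

    def test_ambiguous_base_raises(self, toy_pwm):
        with pytest.raises(ValueError):
            matching_score("N", toy_pwm.log_odds())


class TestScoreDistribution:
    def test_uniform_matrix_zero_moments(self):
        pwm = RbpPwm("u", np.full((4, 4), 3.0), 12)
        for bg in ("B", "NB"):
            d = score_distribution(pwm, bg)
            assert d.mean == pytest.approx(0.0, abs=1e-12)
            assert d.variance == pytest.approx(0.0, abs=1e-12)

    def test_toy_hand_arithmetic(self, toy_pwm):
        d = score_distribution(toy_pwm, "B")
        # f = (0.5, 1/6, 1/6, 1/6); s = (1, log2(2/3) x3)
        s_c = np.log2(2 / 3)
        exp_mean = 0.5 * 1.0 + 3 * (1 / 6) * s_c
        exp_var = (0.5 - 0.25) + 3 * ((1 / 6) * s_c**2 - ((1 / 6) * s_c) ** 2)
        assert d.mean == pytest.approx(exp_mean, abs=1e-9)
        assert d.variance == pytest.approx(exp_var, abs=1e-9)
        assert d.mean == pytest.approx(0.2075, abs=5e-5)
        assert d.variance == pytest.approx(0.3926, abs=5e-5)

    def test_binding_mean_matches_sampling(self):
        # rows drawn multinomially so row sums equal n_sites and the
        # pseudo-counted frequencies are a proper distribution per position
        rng = np.random.default_rng(7)
        counts = rng.multinomial(96, rng.dirichlet(np.ones(4)), size=4).astype(float)
        pwm = RbpPwm("m", counts, 96.0)
        d = score_distribution(pwm, "B")
        f = pwm.binding_frequencies()
        lom = pwm.log_odds()
        n = 100_000
        draws = np.zeros(n)
        for i in range(pwm.k):
            idx = rng.choice(4, size=n, p=f[i])
            draws += lom[i, idx]
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - d.mean) < 3 * se


class TestPhiOmega:
    def test_phi_conventions(self):
        d = rbp.ScoreDistribution("B", 1.0, 4.0)
        assert phi(1.0, d) == pytest.approx(0.5)
        assert phi(1e6, d) == pytest.approx(1.0)
        deg = rbp.ScoreDistribution("B", 1.0, 0.0)
        assert phi(0.5, deg) == 0.0 and phi(1.5, deg) == 1.0 and phi(1.0, deg) == 0.5

    def test_phi_matches_erf_evaluation(self):
        from math import erf, sqrt

        d = rbp.ScoreDistribution("NB", -0.3, 2.5)
        for s in (-3.0, 0.0, 1.7):
            expected = 0.5 * (1 + erf((s - d.mean) / sqrt(2 * d.variance)))
            assert phi(s, d) == pytest.approx(expected, abs=1e-12)

    def test_omega_one_at_shared_mean(self):
        d = rbp.ScoreDistribution("B", 0.5, 1.0)
        dn = rbp.ScoreDistribution("NB", 0.5, 1.0)
        assert omega(0.5, d, dn) == pytest.approx(1.0)

    def test_omega_strictly_increasing(self):
        rng = np.random.default_rng(11)
        pwm = _random_pwm(rng)
        db, dnb = score_distribution(pwm, "B"), score_distribution(pwm, "NB")
        grid = np.linspace(-8, 8, 41)
        vals = [omega(s, db, dnb) for s in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_omega_matches_naive_ratio(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pwm = _random_pwm(rng)
            db, dnb = score_distribution(pwm, "B"), score_distribution(pwm, "NB")
            s = float(rng.normal(scale=2))
            num, den = phi(s, db), 1.0 - phi(s, dnb)
            if num >= 1e-12 and den >= 1e-12:
                assert omega(s, db, dnb) == pytest.approx(num / den, rel=1e-9)


class TestMValue:
    def test_zero_when_alleles_equal(self):
        d = rbp.ScoreDistribution("B", 1.0, 2.0)
        dn = rbp.ScoreDistribution("NB", 0.0, 2.0)
        assert m_value(0.7, 0.7, d, dn) == 0.0

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            pwm = _random_pwm(rng)
            db, dnb = score_distribution(pwm, "B"), score_distribution(pwm, "NB")
            sa, sr = rng.normal(scale=3, size=2)
            assert m_value(sa, sr, db, dnb) == -m_value(sr, sa, db, dnb)

    def test_sign_follows_score_order(self):
        rng = np.random.default_rng(19)
        pwm = _random_pwm(rng)
        db, dnb = score_distribution(pwm, "B"), score_distribution(pwm, "NB")
        assert m_value(2.0, 1.0, db, dnb) > 0
        assert m_value(-2.0, 1.0, db, dnb) < 0


class TestBetaPrior:
    def _independent_cdf(self, x, a, b):
        """Numerical integration of the beta density (no betainc)."""
        logc = gammaln(a + b) - gammaln(a) - gammaln(b)

        def pdf(t):
            return np.exp(logc + (a - 1) * np.log(t) + (b - 1) * np.log1p(-t))

        val, _ = integrate.quad(pdf, 0.0, x, epsabs=1e-12, limit=200)
        return val

    @pytest.mark.parametrize("ic", range(1, 21))
    def test_constraints_hold_for_ic_grid(self, ic):
        prior = solve_beta_prior(ic)
        mode = 2.0 ** -ic
        assert prior.alpha > 1 and prior.beta > 1
        assert (prior.alpha - 1) / (prior.alpha + prior.beta - 2) == \
            pytest.approx(mode, abs=1e-6)
        assert self._independent_cdf(mode / 10, prior.alpha, prior.beta) == \
            pytest.approx(0.005, abs=1e-6)

    def test_ic_zero_is_error(self):
        with pytest.raises(ValueError):
            solve_beta_prior(0.0)

    def test_root_unique_on_decreasing_branch(self):
        # the tail CDF is monotone decreasing past its maximum, so the
        # bracketed crossing is unique
        from scipy.special import betainc

        mode = 2.0 ** -6

        def tail(a):
            b = 1 + (a - 1) * (1 - mode) / mode
            return betainc(a, b, mode / 10)

        grid = 1 + np.logspace(-4, 5, 300)
        vals = np.array([tail(a) for a in grid])
        i = vals.argmax()
        diffs = np.diff(vals[i:])
        assert np.all(diffs <= 1e-15)


class TestPSwitch:
    def _dists_prior(self, rng):
        pwm = _random_pwm(rng)
        db, dnb = score_distribution(pwm, "B"), score_distribution(pwm, "NB")
        prior = solve_beta_prior(max(pwm.information_content(), 0.05))
        return db, dnb, prior

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            db, dnb, prior = self._dists_prior(rng)
            sa, sr = rng.normal(scale=3, size=2)
            p = p_switch(sa, sr, db, dnb, prior)
            assert 0.0 <= p <= 1.0
            assert p == p_switch(sr, sa, db, dnb, prior)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            db, dnb, prior = self._dists_prior(rng)
            sa, sr = rng.normal(scale=2, size=2)
            p = p_switch(sa, sr, db, dnb, prior)
            x = rng.beta(prior.alpha, prior.beta, size=100_000)
            phis = (phi(sr, db), phi(sr, dnb), phi(sa, db), phi(sa, dnb))
            mc = p_switch_conditional(x, *phis).mean()
            assert abs(p - mc) < 0.01


class TestRbpScorer:
    def test_planted_consensus_destruction_negative_m(self):
        counts = np.zeros((5, 4))
        consensus = "ACGTA"
        for i, b in enumerate(consensus):
            counts[i] = 2.0
            counts[i, "ACGT".index(b)] = 94.0
        pwm = RbpPwm("planted", counts, 100.0)
        scorer = RbpScorer([pwm])
        ref_ctx = "TT" + consensus + "TT"
        alt_ctx = ref_ctx[:4] + "C" + ref_ctx[5:]  # G -> C at motif center
        imp = scorer.impacts(ref_ctx, alt_ctx)[0]
        assert imp.m < 0
        assert imp.score_ref > imp.score_alt

    def test_uniform_pwm_m_zero(self):
        pwm = RbpPwm("u", np.full((4, 4), 25.0), 100.0)
        scorer = RbpScorer([pwm])
        imp = scorer.impacts("ACGTACG", "ACGAACG")[0]
        assert imp.m == pytest.approx(0.0, abs=1e-12)

    def test_strand_flip_symmetry(self):
        rng = np.random.default_rng(31)
        pwm = _random_pwm(rng, k=5)
        # reverse-complemented motif: reverse positions, swap A<->T, C<->G
        rc_counts = pwm.counts[::-1][:, [3, 2, 1, 0]]
        rc_pwm = RbpPwm("rc", rc_counts, pwm.n_sites)
        from intronscore.annotate import revcomp

        ref_ctx = "ACGTAGGCA"
        alt_ctx = "ACGTCGGCA"
        a = RbpScorer([pwm]).impacts(ref_ctx, alt_ctx)[0]
        b = RbpScorer([rc_pwm]).impacts(revcomp(ref_ctx), revcomp(alt_ctx))[0]
        assert a.m == pytest.approx(b.m, abs=1e-9)
        assert a.p == pytest.approx(b.p, abs=1e-9)


def test_pwm_file_roundtrip(tmp_path):
    rng = np.random.default_rng(37)
    pwms = [_random_pwm(rng) for _ in range(3)]
    path = tmp_path / "m.tsv"
    rbp.write_pwms(pwms, path)
    back = rbp.read_pwms(path)
    assert [p.name for p in back] == [p.name for p in pwms]
    for a, b in zip(pwms, back):
        np.testing.assert_allclose(a.counts, b.counts)
        assert a.n_sites == b.n_sites
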