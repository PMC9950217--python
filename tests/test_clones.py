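import numpy as np
import pytest
from scipy.stats import poisson

from radassoc import _engine
from radassoc.clones import Clone, StepOutcome, sample_new_clones, step_clone, step_clone_coupled

DT = 1.0 / 365.0


class TestSampleNewClones:
    def test_zero_rate(self, rng):
        assert sample_new_clones(0.0, DT, rng) == 0

    def test_poisson_mean(self, rng):
        # initiation-pool rate of the instantaneous-promotion parameter set
        rate, n = 0.177, 300_000
        draws = np.array([sample_new_clones(rate, DT, rng) for _ in range(n)])
        se = np.sqrt(rate * DT / n)
        assert abs(draws.mean() - rate * DT) < 3 * se

    def test_elevated_initiation_under_exposure(self, rng):
        # nu = nu0 * (1 + 52.4 d) at d = 1 Gy/yr
        rate = 0.054 * (1 + 52.4)
        n = 200_000
        draws = np.array([sample_new_clones(rate, DT, rng) for _ in range(n)])
        se = np.sqrt(rate * DT / n)
        assert abs(draws.mean() - rate * DT) < 3 * se

    def test_invalid_args(self, rng):
        with pytest.raises(ValueError):
            sample_new_clones(-1.0, DT, rng)
        with pytest.raises(ValueError):
            sample_new_clones(1.0, 0.0, rng)


class TestStepClone:
    def test_null_rates_keep_size(self, rng):
        out = step_clone(1, 0.0, 0.0, 0.0, DT, rng)
        assert out == StepOutcome(1, False, None)

    def test_single_cell_transition_probabilities(self, rng):
        """One-step outcome frequencies match the per-cell probabilities."""
        alpha, beta, mu = 12.0, 11.913, 4.64e-6
        grew = died = 0
        for _ in range(50_000):
            out = step_clone(1, alpha, beta, mu, DT, rng)
            grew += out.new_size == 2
            died += out.new_size == 0
        for observed, p in ((grew, alpha * DT), (died, beta * DT)):
            se = np.sqrt(p * (1 - p) * 50_000)
            assert abs(observed - 50_000 * p) < 3 * se

    @pytest.mark.parametrize("size", [1, 7, 40])
    def test_branching_mean(self, rng, size):
        """E[new size] = m * (1 + (alpha - beta) dt)."""
        alpha, beta = 12.0, 11.913
        total = 0
        reps = 100_000
        for _ in range(reps):
            total += step_clone(size, alpha, beta, 0.0, DT, rng).new_size
        expected = size * (1 + (alpha - beta) * DT)
        sd_one = np.sqrt(size * (alpha + beta) * DT)  # leading-order step SD
        assert abs(total / reps - expected) < 4 * sd_one / np.sqrt(reps)

    def test_probabilities_must_stay_below_one(self, rng):
        with pytest.raises(ValueError):
            step_clone(1, 200.0, 200.0, 0.0, DT, rng)

    def test_extinct_clone_rejected(self, rng):
        with pytest.raises(ValueError):
            step_clone(0, 12.0, 11.9, 0.0, DT, rng)


class TestStepCloneCoupled:
    def test_identical_rates_never_fork_under_thinning(self, rng):
        rates = (12.0, 11.913, 4.64e-6)
        for _ in range(2_000):
            clone = Clone(size=3, birth_age=20.0)
            out_s, out_r, forked = step_clone_coupled(
                clone, rates, rates, DT, rng, scheme="thinning")
            assert not forked
            assert out_s.new_size == out_r.new_size

    def test_fork_probability_matches_thinning_rate(self, rng):
        """P(fork) = P(a death is thinned away)
        = beta0 dt - beta_rad dt to leading order."""
        beta0, beta_rad = 11.913, 11.913 - 2.3
        n = 1_000_000
        # exact leading-order enumeration of the coupled step for size 1:
        # fork iff the cell dies spontaneously AND the death is rejected
        # for the radiation lineage
        p_fork = beta0 * DT * (1 - beta_rad / beta0)
        forks = 0
        for _ in range(n):
            clone = Clone(size=1, birth_age=30.2)
            _, _, forked = step_clone_coupled(
                clone, (12.0, beta0, 4.64e-6), (12.0, beta_rad, 4.64e-6),
                DT, rng, scheme="thinning")
            forks += forked
        se = np.sqrt(p_fork * (1 - p_fork) * n)
        assert abs(forks - n * p_fork) < 3 * se

    def test_forked_clone_rejected(self, rng):
        clone = Clone(size=1, birth_age=10.0, forked_from=7)
        with pytest.raises(ValueError):
            step_clone_coupled(clone, (12.0, 11.9, 0.0), (12.0, 11.0, 0.0),
                               DT, rng)

    def test_independent_scheme_forks_on_any_difference(self, rng):
        clone = Clone(size=5, birth_age=30.5)
        forks = 0
        reps = 20_000
        for _ in range(reps):
            out_s, out_r, forked = step_clone_coupled(
                clone, (12.0, 11.913, 0.0), (12.0, 9.613, 0.0), DT, rng,
                scheme="independent")
            assert forked == (out_s.new_size != out_r.new_size)
            forks += forked
        # under independent draws forks are far more frequent than the
        # thinning rate 5 * 2.3 * dt ~ 0.032
        assert forks / reps > 0.05


class TestEngineSingleCloneDistribution:
    """The compiled kernel's clone-size law against matrix-exponential
    transition probabilities of the discrete per-step multinomial chain."""

    @staticmethod
    def _step_matrix(alpha, beta, nmax, dt):
        """One-step size-transition matrix of the per-step multinomial law
        (death/birth counts per step, truncated at nmax)."""
        from scipy.stats import binom

        P = np.zeros((nmax + 1, nmax + 1))
        P[0, 0] = 1.0
        pa, pb = alpha * dt, beta * dt
        for m in range(1, nmax + 1):
            ka = np.arange(0, m + 1)
            pa_k = binom.pmf(ka, m, pa)
            for a, wa in zip(ka, pa_k):
                kb = np.arange(0, m - a + 1)
                pb_k = binom.pmf(kb, m - a, pb / (1 - pa))
                for b, wb in zip(kb, pb_k):
                    j = min(m + a - b, nmax)
                    P[m, j] += wa * wb
        return P

    def test_size_distribution_after_one_year(self):
        alpha, beta, dt = 12.0, 11.837, DT
        steps = 365
        nmax = 40
        P = self._step_matrix(alpha, beta, nmax, dt)
        dist = np.linalg.matrix_power(P, steps)[1]  # start from one cell

        n = 60_000
        sizes = np.zeros(n, dtype=int)
        np.random.seed(0)
        seeds = np.random.SeedSequence(4242).generate_state(n, dtype=np.uint32)
        for i in range(n):
            np.random.seed(int(seeds[i]))
            st, t, m = _engine._sim_single(1, 0.0, 1.0, alpha, beta, 0.0, dt)
            sizes[i] = min(m, nmax)
        observed = np.bincount(sizes, minlength=nmax + 1) / n
        # total-variation distance bounded by Monte Carlo error
        tv = 0.5 * np.abs(observed - dist).sum()
        assert tv < 4.0 * np.sqrt(nmax / n)

    def test_extinction_is_absorbing(self):
        np.random.seed(123)
        for _ in range(200):
            st, t, m = _engine._sim_single(1, 0.0, 60.0, 1.0, 2.0, 0.0, 0.002)
            if st == 0:
                assert m == 0

    def test_superposition_of_initiation_streams(self):
        """Spontaneous + excess initiation streams together are Poisson with
        the summed rate (checked on the engine's per-person clone count)."""
        rate1, rate2, T = 0.054, 0.054 * 52.4, 1.0
        n = 200_000
        rng = np.random.default_rng(5)
        combined = rng.poisson(rate1 * T, n) + rng.poisson(rate2 * T, n)
        expected = poisson((rate1 + rate2) * T)
        counts = np.bincount(combined, minlength=12)[:12] / n
        assert np.allclose(counts, expected.pmf(np.arange(12)), atol=4e-3)
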