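"""Metropolis-Hastings sampler: target, stepping, stationarity, decoding."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from pepex.latent import LatentPrior
from pepex.mh import (
    ChainState,
    MhConfig,
    concatenate,
    log_target,
    mh_step,
    sample_chain,
    sample_chains_vectorized,
    sample_extensions,
)

PARENT = "YPEDILDKHLQRVIL"


class _Logistic:
    """Analytic classifier posterior for 2-D latent fixtures."""

    def __init__(self, w=(0.8, 0.5)):
        self.w = np.asarray(w)

    def predict_proba(self, Z):
        Z = np.atleast_2d(Z)
        return 1.0 / (1.0 + np.exp(-(Z @ self.w)))


@pytest.fixture(scope="module")
def gmm_prior_2d():
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal([-1.5, 0.0], 0.7, size=(400, 2)), rng.normal([1.5, 0.5], 0.9, size=(600, 2))]
    )
    return LatentPrior(GaussianMixture(2, covariance_type="full", random_state=0).fit(X))


class TestLogTarget:
    def test_unit_posterior_reduces_to_prior(self, gmm_prior_2d):
        z = np.array([0.3, -0.2])
        assert log_target(z, gmm_prior_2d, None) == pytest.approx(
            float(gmm_prior_2d.log_density(z))
        )

    def test_decays_in_gaussian_tails(self, gmm_prior_2d):
        near = log_target(np.array([0.0, 0.2]), gmm_prior_2d, _Logistic())
        far = log_target(np.array([30.0, 30.0]), gmm_prior_2d, _Logistic())
        assert far < near

    def test_zero_probability_gives_minus_infinity(self, gmm_prior_2d):
        class Zero:
            def predict_proba(self, Z):
                return np.zeros(np.atleast_2d(Z).shape[0])

        assert log_target(np.zeros(2), gmm_prior_2d, Zero()) == -np.inf

    def test_grid_normalized_density_matches_brute_force(self, gmm_prior_2d):
        """exp(log_target)/Z equals q(c|z) q(z)/Z computed independently."""
        post = _Logistic()
        xs = np.linspace(-4, 4, 60)
        XX, YY = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        lt = np.array([log_target(p, gmm_prior_2d, post) for p in pts])
        ours = np.exp(lt)
        ours /= ours.sum()
        brute = np.exp(gmm_prior_2d.log_density(pts)) * post.predict_proba(pts)
        brute /= brute.sum()
        mask = brute > 1e-12
        assert np.abs(ours[mask] / brute[mask] - 1.0).max() < 1e-6


class TestMhStep:
    def test_moves_with_higher_density_always_kept(self, gmm_prior_2d):
        # force uphill acceptance: tiny proposals from a low-density start
        rng = np.random.default_rng(2)
        z0 = np.array([5.0, 5.0])
        state = ChainState(z=z0, log_target=log_target(z0, gmm_prior_2d))
        cfg = MhConfig(proposal_sigma=0.05, seed=0)
        for _ in range(300):
            prev = state
            state = mh_step(state, cfg, gmm_prior_2d, None, rng)
            if state.log_target > prev.log_target:
                assert not np.array_equal(state.z, prev.z)
        assert state.log_target > log_target(z0, gmm_prior_2d)

    def test_reproducible_under_fixed_rng(self, gmm_prior_2d):
        z0 = np.zeros(2)
        s0 = ChainState(z=z0, log_target=log_target(z0, gmm_prior_2d))
        a = mh_step(s0, MhConfig(), gmm_prior_2d, None, np.random.default_rng(5))
        b = mh_step(s0, MhConfig(), gmm_prior_2d, None, np.random.default_rng(5))
        assert np.array_equal(a.z, b.z) and a.accept_count == b.accept_count

    def test_acceptance_rate_on_standard_normal(self, std_normal_prior):
        """With the 2.4/sqrt(K) proposal the acceptance rate sits mid-range."""
        K = 8
        prior = std_normal_prior(K)
        rng = np.random.default_rng(3)
        z = np.zeros(K)
        state = ChainState(z=z, log_target=log_target(z, prior))
        cfg = MhConfig(proposal_sigma=2.4 / np.sqrt(K))
        for _ in range(10_000):
            state = mh_step(state, cfg, prior, None, rng)
        rate = state.accept_count / state.step_count
        assert 0.1 < rate < 0.6


class TestSampleChain:
    def test_burnin_zero_thinning_one_returns_every_step(self, gmm_prior_2d):
        cfg = MhConfig(burn_in=0, thinning=1, max_iterations=50, seed=0)
        samples = sample_chain(cfg, gmm_prior_2d)
        assert len(samples) == 50

    def test_same_seed_identical_chains(self, gmm_prior_2d):
        cfg = MhConfig(burn_in=10, thinning=2, max_iterations=200, seed=42)
        a = sample_chain(cfg, gmm_prior_2d, _Logistic())
        b = sample_chain(cfg, gmm_prior_2d, _Logistic())
        assert np.array_equal(np.array(a), np.array(b))

    def test_unit_posterior_recovers_prior_moments(self, gmm_prior_2d):
        cfg = MhConfig(burn_in=500, thinning=5, seed=1, max_iterations=10**6)
        samples = np.array(sample_chain(cfg, gmm_prior_2d, None, n_samples=20_000))
        mean_true = gmm_prior_2d.weights @ gmm_prior_2d.means
        assert np.abs(samples.mean(axis=0) - mean_true).max() < 0.1
        assert np.abs(samples.std(axis=0) - gmm_prior_2d.marginal_std()).max() < 0.1

    def test_stationary_distribution_total_variation(self, gmm_prior_2d):
        """Thinned chain histogram matches the grid-normalized analytic target."""
        post = _Logistic()
        cfg = MhConfig(burn_in=500, thinning=5, seed=7, n_chains=20)
        kept, rate = sample_chains_vectorized(cfg, gmm_prior_2d, post, n_steps=13_000)
        samples = np.concatenate(kept)[:50_000]
        assert len(samples) == 50_000
        lim, nf, nc = 6.0, 240, 30
        xs = np.linspace(-lim, lim, nf + 1)
        cx = 0.5 * (xs[:-1] + xs[1:])
        XX, YY = np.meshgrid(cx, cx, indexing="ij")
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        dens = np.exp(gmm_prior_2d.log_density(pts)) * post.predict_proba(pts)
        dens /= dens.sum()
        coarse = dens.reshape(nc, nf // nc, nc, nf // nc).sum(axis=(1, 3))
        H, _, _ = np.histogram2d(
            samples[:, 0], samples[:, 1], bins=[np.linspace(-lim, lim, nc + 1)] * 2
        )
        emp = H / len(samples)
        tv = 0.5 * np.abs(emp - coarse).sum() + 0.5 * (1.0 - emp.sum())
        assert tv < 0.05

    def test_detailed_balance_on_discretized_target(self, std_normal_prior):
        """Empirical bin-to-bin fluxes are symmetric for a 1-D normal target."""
        prior = std_normal_prior(1)
        cfg = MhConfig(burn_in=200, thinning=1, max_iterations=120_000, seed=9)
        samples = np.array(sample_chain(cfg, prior)).ravel()
        edges = np.array([-np.inf, -0.6, 0.0, 0.6, np.inf])
        bins = np.digitize(samples, edges[1:-1])
        flux = np.zeros((4, 4))
        for a, b in zip(bins[:-1], bins[1:]):
            flux[a, b] += 1
        flux /= flux.sum()
        off = flux[np.triu_indices(4, 1)]
        off_t = flux.T[np.triu_indices(4, 1)]
        assert np.abs(off - off_t).max() < 0.01


class TestSampleExtensions:
    @staticmethod
    def _decoder(z):
        # deterministic stub: first coordinate sets length, second the residue
        n = int(abs(z[0])) % 4 + 1
        aa = "WFDE"[int(abs(z[1])) % 4]
        return aa * n

    def test_quota_and_uniqueness(self):
        rng = np.random.default_rng(0)
        zs = rng.uniform(0, 10, size=(500, 2))
        out = sample_extensions(self._decoder, zs, target_lengths=[1, 2], per_length_quota=2)
        exts = [e for e, _ in out]
        assert len(exts) == len(set(exts))
        assert all(len(e) in (1, 2) for e in exts)
        assert sum(len(e) == 1 for e in exts) <= 2

    def test_exhausted_exclusion_warns_and_yields_nothing(self):
        zs = [np.array([0.5, float(i)]) for i in range(50)]  # all length-1 strings
        exclusion = {aa for aa in "WFDE"}
        with pytest.warns(UserWarning, match="quota"):
            out = sample_extensions(
                self._decoder, zs, target_lengths=[1], per_length_quota=3,
                exclusion_set=exclusion,
            )
        assert out == []

    def test_invalid_quota(self):
        with pytest.raises(ValueError):
            sample_extensions(self._decoder, [], [1], per_length_quota=0)


class TestConcatenate:
    @pytest.mark.parametrize(
        "parent,ext,terminus,expected",
        [
            (PARENT, "EGEKQ", "N", "EGEKQ" + PARENT),
            ("YPEDILDKHLQRV", "WWFTDDHW", "C", "YPEDILDKHLQRVWWFTDDHW"),
            (PARENT, "", "N", PARENT),
        ],
    )
    def test_orientation(self, parent, ext, terminus, expected):
        assert concatenate(parent, ext, terminus) == expected

    def test_bad_terminus(self):
        with pytest.raises(ValueError):
            concatenate(PARENT, "AA", "Z")
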