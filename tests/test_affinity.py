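import numpy as np
import pandas as pd
import pytest

from taxenv import affinity
from taxenv.affinity import (
    AffinityConfig,
    AffinityPosterior,
    classify_affinity,
    cluster_environments,
    fit,
)


def _fake_posterior(lam_cells):
    """Posterior with constant draws equal to lam_cells (I x J)."""
    lam = np.asarray(lam_cells, dtype=float)
    i, j = lam.shape
    draws = np.broadcast_to(lam, (2, 10, i, j)).copy()
    return AffinityPosterior(
        taxa=[f"t{k}" for k in range(i)],
        environments=[f"e{k}" for k in range(j)],
        lambda_draws=draws,
        alpha_draws=np.zeros((2, 10)),
        theta_draws=np.zeros((2, 10, i)),
        gamma_draws=np.zeros((2, 10, j)),
        nu_draws=np.zeros((2, 10, i, j)),
        mix_weight_draws=np.full((2, 10), 0.5),
    )


class TestFitBasics:
    def test_y_equals_e_gives_lambda_near_one(self):
        y = pd.DataFrame(np.full((4, 4), 200.0))
        post = fit(y, np.full((4, 4), 200.0), chains=2, iterations=3000,
                   burn_in=1500, seed=5, compute_diagnostics=False)
        med = post.lambda_median.values
        assert med.min() > 0.8 and med.max() < 1.25

    def test_all_zero_counts_push_lambda_down(self):
        y = pd.DataFrame(np.zeros((4, 4)))
        post = fit(y, np.full((4, 4), 50.0), chains=2, iterations=3000,
                   burn_in=1500, seed=6, compute_diagnostics=False)
        assert (post.lambda_median.values < 1).all()

    def test_poisson_mean_matching(self, rng):
        y = pd.DataFrame(rng.poisson(30, (6, 4)).astype(float))
        e = np.full((6, 4), 30.0)
        post = fit(y, e, chains=2, iterations=3000, burn_in=1500, seed=7,
                   compute_diagnostics=False)
        fitted = (post.lambda_draws.mean(axis=(0, 1)) * e).sum()
        assert abs(fitted / y.values.sum() - 1) < 0.05

    def test_seed_reproducible(self):
        y = pd.DataFrame(np.full((3, 3), 25.0))
        e = np.full((3, 3), 25.0)
        a = fit(y, e, chains=2, iterations=600, burn_in=300, seed=11,
                compute_diagnostics=False)
        b = fit(y, e, chains=2, iterations=600, burn_in=300, seed=11,
                compute_diagnostics=False)
        assert np.array_equal(a.lambda_draws, b.lambda_draws)

    def test_input_validation(self):
        y = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError, match="strictly positive"):
            fit(y, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="burn_in"):
            fit(y, np.ones((3, 3)), iterations=100, burn_in=100)
        with pytest.raises(ValueError, match="chains"):
            fit(y, np.ones((3, 3)), chains=1)
        with pytest.raises(ValueError, match="shape"):
            fit(y, np.ones((2, 3)))

    def test_stalled_sampler_raises(self):
        y = pd.DataFrame(np.full((4, 4), 500.0))
        cfg = AffinityConfig(init_step=200.0, adapt_interval=10_000)
        with pytest.raises(RuntimeError, match="step"):
            fit(y, np.full((4, 4), 500.0), chains=2, iterations=300,
                burn_in=100, seed=8, config=cfg, compute_diagnostics=False)

    def test_permutation_equivariance(self, rng):
        y = pd.DataFrame(rng.poisson(40, (6, 4)).astype(float),
                         index=list("abcdef"), columns=list("wxyz"))
        e = pd.DataFrame(np.full((6, 4), 40.0), index=y.index, columns=y.columns)
        post = fit(y, e, chains=2, iterations=6000, burn_in=3000, seed=9,
                   compute_diagnostics=False)
        rows = list("cafdbe")
        cols = list("ywxz")
        post_p = fit(y.loc[rows, cols], e.loc[rows, cols], chains=2,
                     iterations=6000, burn_in=3000, seed=9,
                     compute_diagnostics=False)
        back = post_p.lambda_median.loc[y.index, y.columns]
        # equality holds in distribution; medians agree within MC error
        assert np.abs(np.log(back.values) - np.log(post.lambda_median.values)).max() < 0.15

    def test_diagnostics_table(self):
        y = pd.DataFrame(np.full((3, 3), 25.0))
        post = fit(y, np.full((3, 3), 25.0), chains=2, iterations=1000,
                   burn_in=500, seed=12)
        assert post.diagnostics is not None
        assert (post.diagnostics["ess"] > 0).all()
        assert post.diagnostics.loc["log_lambda[worst]", "rhat"] < 1.2


class TestCredibleCoverage:
    def test_simulation_based_calibration(self):
        """Data simulated from the model's own (centered) priors must be
        covered by 90% credible intervals for log lambda at 90% +/- 3%."""
        rng = np.random.default_rng(7)
        i_dim, j_dim, e0 = 4, 3, 20.0
        cfg = AffinityConfig(alpha_sd=1.0, thin=2)
        e = np.full((i_dim, j_dim), e0)
        hits = 0
        cells = 0
        for _ in range(200):
            vt = 1.0 / rng.gamma(2.0)
            vg = 1.0 / rng.gamma(2.0)
            while True:
                vn = 1.0 / rng.gamma(2.0)
                vs = 1.0 / rng.gamma(2.0)
                if vn < vs:
                    break
            w = rng.beta(1, 1)
            alpha = rng.normal(0, 1.0)
            theta = rng.normal(0, np.sqrt(vt), i_dim)
            theta -= theta.mean()
            gamma = rng.normal(0, np.sqrt(vg), j_dim)
            gamma -= gamma.mean()
            z = rng.random((i_dim, j_dim)) < w
            nu = np.where(
                z,
                rng.normal(0, np.sqrt(vs), (i_dim, j_dim)),
                rng.normal(0, np.sqrt(vn), (i_dim, j_dim)),
            )
            nu -= nu.mean(axis=1, keepdims=True)
            nu -= nu.mean(axis=0, keepdims=True)
            eta = alpha + theta[:, None] + gamma[None, :] + nu
            y = rng.poisson(e * np.exp(eta))
            post = fit(
                pd.DataFrame(y.astype(float)), e, chains=2, iterations=2400,
                burn_in=1200, seed=int(rng.integers(2**31)), config=cfg,
                compute_diagnostics=False,
            )
            lo, hi = post.credible_interval(0.9)
            hits += ((lo <= eta) & (eta <= hi)).sum()
            cells += eta.size
        coverage = hits / cells
        assert 0.87 <= coverage <= 0.93


class TestClassify:
    def test_certain_affinity(self):
        p = _fake_posterior([[3.0, 1.0], [0.2, 1.0]])
        flags = classify_affinity(p)
        assert flags.iloc[0, 0] == "affinity"
        assert flags.iloc[1, 0] == "under-presence"

    def test_equivocal_is_none(self):
        p = _fake_posterior(np.full((2, 2), 1.1))
        draws = p.lambda_draws.copy()
        draws[0, :5] = 0.9  # a quarter of the draws below 1
        p.lambda_draws = draws
        assert (classify_affinity(p) == "none").all().all()


class TestClusterEnvironments:
    def test_identical_columns_merge_at_zero(self):
        p = _fake_posterior(np.exp(np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])))
        d = cluster_environments(p)
        assert d.linkage[0, 2] == pytest.approx(0.0)

    def test_orthogonal_columns_complete_linkage_height(self):
        # columns e0=(1,0), e1=(0,1) on the log scale: distance sqrt(2)
        p = _fake_posterior(np.exp(np.array([[1.0, 0.0], [0.0, 1.0]])))
        d = cluster_environments(p)
        assert d.linkage[-1, 2] == pytest.approx(np.sqrt(2))

    def test_newick_is_parseable(self):
        from io import StringIO

        from Bio import Phylo

        p = _fake_posterior(np.exp(np.random.default_rng(1).normal(0, 1, (4, 5))))
        tree = Phylo.read(StringIO(cluster_environments(p).to_newick()), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set(p.environments)

    def test_cut_recovers_two_blocks(self):
        block = np.zeros((6, 6))
        block[:3, :3] = 1.5
        block[3:, 3:] = 1.5
        p = _fake_posterior(np.exp(block))
        groups = p.environments
        cut = cluster_environments(p).cut(2)
        left = {g for g in groups[:3]}
        assert len({cut[g] for g in left}) == 1
        assert len({cut[g] for g in groups[3:]}) == 1
        assert cut[groups[0]] != cut[groups[3]]
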