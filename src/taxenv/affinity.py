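"""Bayesian hierarchical Poisson model of taxa-environment affinity.

The observed community matrix Y_ij (distinct OTUs of taxon i in
environment j) is modelled as

    Y_ij ~ Poisson(lambda_ij * E_ij),
    log lambda_ij = alpha + theta_i + gamma_j + nu_ij,

where E_ij is the expected count under independence of taxa and
environments.  lambda_ij > 1 signals affinity of taxon i for environment
j, lambda_ij < 1 under-presence.  Main effects theta and gamma carry
normal priors; the interactions nu_ij carry a two-component normal
mixture in which the narrow component absorbs noise and the wide one
captures genuine departures from the main effects (adjusted affinity).

Inference is Metropolis-within-Gibbs: Gaussian random-walk updates for
alpha, theta, gamma and nu (vectorized over rows, columns and cells,
which is valid because the Poisson likelihood factorizes by cell),
conjugate inverse-gamma updates for the variances, a beta update for the
mixture weight and Bernoulli updates for the per-cell component
indicators.  Identifiability of the decomposition is enforced by
re-centering theta, gamma and the rows/columns of nu after every sweep;
the shifts are absorbed so log lambda is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix


@dataclass
class AffinityConfig:
    """Priors and sampler settings.

    Variances (not standard deviations) of theta, gamma and the two
    mixture components carry inverse-gamma(shape, scale) priors; the
    ordering var_noise < var_signal is enforced by rejection so the
    mixture components cannot swap labels.  Step sizes adapt toward a
    ~40% acceptance rate during burn-in only.
    """

    alpha_sd: float = 10.0
    sigma_shape: float = 2.0
    sigma_scale: float = 1.0
    mix_a: float = 1.0
    mix_b: float = 1.0
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    init_step: float = 0.1
    adapt_interval: int = 100
    target_accept: float = 0.40


@dataclass
class AffinityPosterior:
    """Posterior draws and summaries of the affinity model.

    Draw arrays are indexed (chain, draw, ...).  ``lambda_median`` and
    ``prob_gt1`` are taxa x environment DataFrames on the affinity scale.
    """

    taxa: list[str]
    environments: list[str]
    lambda_draws: np.ndarray          # (chains, draws, I, J)
    alpha_draws: np.ndarray           # (chains, draws)
    theta_draws: np.ndarray           # (chains, draws, I)
    gamma_draws: np.ndarray           # (chains, draws, J)
    nu_draws: np.ndarray              # (chains, draws, I, J)
    mix_weight_draws: np.ndarray      # (chains, draws)
    variance_draws: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    @property
    def lambda_median(self) -> pd.DataFrame:
        med = np.median(self.lambda_draws, axis=(0, 1))
        return pd.DataFrame(med, index=self.taxa, columns=self.environments)

    @property
    def prob_gt1(self) -> pd.DataFrame:
        p = (self.lambda_draws > 1.0).mean(axis=(0, 1))
        return pd.DataFrame(p, index=self.taxa, columns=self.environments)

    def credible_interval(self, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        """Equal-tailed credible bounds for log lambda, per cell."""
        tail = (1.0 - level) / 2.0
        logs = np.log(self.lambda_draws)
        lo = np.quantile(logs, tail, axis=(0, 1))
        hi = np.quantile(logs, 1.0 - tail, axis=(0, 1))
        return lo, hi

    def summary_table(self, prob_cut: float = 0.95) -> pd.DataFrame:
        med = self.lambda_median.stack()
        prob = self.prob_gt1.stack()
        flags = classify_affinity(self, prob_cut).stack()
        out = pd.DataFrame(
            {"lambda_median": med, "prob_gt1": prob, "flag": flags}
        )
        out.index.names = ["taxon", "environment"]
        return out.reset_index()


def _invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


class _ChainState:
    """Mutable per-chain sampler state with cached Poisson means."""

    def __init__(self, y: np.ndarray, e: np.ndarray, cfg: AffinityConfig, rng: np.random.Generator):
        self.y = y
        self.e = e
        self.cfg = cfg
        self.rng = rng
        i, j = y.shape
        # moment-based initialization keeps early sweeps in a sane region
        total_ratio = max(y.sum() / e.sum(), 1e-8)
        self.alpha = math.log(total_ratio)
        row = np.log((y.sum(1) + 0.5) / (e.sum(1) * total_ratio))
        col = np.log((y.sum(0) + 0.5) / (e.sum(0) * total_ratio))
        self.theta = row - row.mean()
        self.gamma = col - col.mean()
        self.nu = np.zeros((i, j))
        self.z = np.zeros((i, j), dtype=bool)
        self.w = 0.1
        self.var_theta = 0.25
        self.var_gamma = 0.25
        self.var_noise = 0.05
        self.var_signal = 1.0
        self.mu = e * np.exp(self.eta())  # cached Poisson mean
        s = cfg.init_step
        self.steps = {"alpha": s, "theta": s, "gamma": s, "nu": s}
        self._acc = {k: 0.0 for k in self.steps}
        self._tries = {k: 0.0 for k in self.steps}
        self.cell_accepts = 0.0
        self.cell_tries = 0.0

    def eta(self) -> np.ndarray:
        return self.alpha + self.theta[:, None] + self.gamma[None, :] + self.nu

    # -- Metropolis updates (likelihood factorizes by cell, so rows,
    #    columns and cells can each be updated in parallel) -------------

    def update_alpha(self) -> None:
        eps = self.rng.normal(0, self.steps["alpha"])
        dll = self.y.sum() * eps - (math.exp(eps) - 1.0) * self.mu.sum()
        a_new = self.alpha + eps
        dprior = (self.alpha**2 - a_new**2) / (2 * self.cfg.alpha_sd**2)
        self._tries["alpha"] += 1
        if math.log(self.rng.random()) < dll + dprior:
            self.alpha = a_new
            self.mu *= math.exp(eps)
            self._acc["alpha"] += 1

    def _update_margin(self, name: str, values: np.ndarray, axis: int, var: float) -> None:
        eps = self.rng.normal(0, self.steps[name], values.shape)
        y_m = self.y.sum(axis=1 - axis)
        mu_m = self.mu.sum(axis=1 - axis)
        dll = y_m * eps - mu_m * (np.exp(eps) - 1.0)
        dprior = (values**2 - (values + eps) ** 2) / (2 * var)
        accept = np.log(self.rng.random(values.shape)) < dll + dprior
        values[accept] += eps[accept]
        factor = np.where(accept, np.exp(eps), 1.0)
        self.mu *= factor[:, None] if axis == 0 else factor[None, :]
        self._tries[name] += accept.size
        self._acc[name] += accept.sum()

    def update_theta(self) -> None:
        self._update_margin("theta", self.theta, 0, self.var_theta)

    def update_gamma(self) -> None:
        self._update_margin("gamma", self.gamma, 1, self.var_gamma)

    def update_nu(self) -> None:
        eps = self.rng.normal(0, self.steps["nu"], self.nu.shape)
        dll = self.y * eps - self.mu * (np.exp(eps) - 1.0)
        var = np.where(self.z, self.var_signal, self.var_noise)
        dprior = (self.nu**2 - (self.nu + eps) ** 2) / (2 * var)
        accept = np.log(self.rng.random(self.nu.shape)) < dll + dprior
        self.nu[accept] += eps[accept]
        self.mu[accept] *= np.exp(eps[accept])
        self._tries["nu"] += accept.size
        self._acc["nu"] += accept.sum()
        self.cell_tries += accept.size
        self.cell_accepts += accept.sum()

    # -- conjugate updates ---------------------------------------------

    def update_indicators(self) -> None:
        nu2 = self.nu**2
        log_sig = math.log(self.w) - 0.5 * math.log(self.var_signal) - nu2 / (2 * self.var_signal)
        log_noise = (
            math.log1p(-self.w) - 0.5 * math.log(self.var_noise) - nu2 / (2 * self.var_noise)
        )
        p = 1.0 / (1.0 + np.exp(log_noise - log_sig))
        self.z = self.rng.random(self.nu.shape) < p

    def update_mix_weight(self) -> None:
        n1 = self.z.sum()
        n0 = self.z.size - n1
        self.w = float(
            np.clip(self.rng.beta(self.cfg.mix_a + n1, self.cfg.mix_b + n0), 1e-6, 1 - 1e-6)
        )

    def update_variances(self) -> None:
        a, b = self.cfg.sigma_shape, self.cfg.sigma_scale
        rng = self.rng
        self.var_theta = _invgamma(rng, a + len(self.theta) / 2, b + (self.theta**2).sum() / 2)
        self.var_gamma = _invgamma(rng, a + len(self.gamma) / 2, b + (self.gamma**2).sum() / 2)
        nu2 = self.nu**2
        n1 = self.z.sum()
        n0 = self.z.size - n1
        s1 = nu2[self.z].sum()
        s0 = nu2[~self.z].sum()
        # joint conditional restricted to var_noise < var_signal, by rejection
        for _ in range(100):
            vn = _invgamma(rng, a + n0 / 2, b + s0 / 2)
            vs = _invgamma(rng, a + n1 / 2, b + s1 / 2)
            if vn < vs:
                self.var_noise, self.var_signal = vn, vs
                break

    def recenter(self) -> None:
        """Sum-to-zero identifiability transform; log lambda is invariant."""
        r = self.nu.mean(axis=1)
        self.nu -= r[:, None]
        self.theta += r
        c = self.nu.mean(axis=0)
        self.nu -= c[None, :]
        self.gamma += c
        for vec in (self.theta, self.gamma):
            m = vec.mean()
            vec -= m
            self.alpha += m

    def adapt(self) -> None:
        for name in self.steps:
            if self._tries[name] == 0:
                continue
            rate = self._acc[name] / self._tries[name]
            self.steps[name] *= math.exp(0.3 * (rate - self.cfg.target_accept))
            self._acc[name] = 0.0
            self._tries[name] = 0.0

    def sweep(self) -> None:
        self.update_alpha()
        self.update_theta()
        self.update_gamma()
        self.update_nu()
        self.update_indicators()
        self.update_mix_weight()
        self.update_variances()
        self.recenter()


def fit(
    m: CommunityMatrix | pd.DataFrame,
    E: pd.DataFrame | np.ndarray,
    chains: int = 4,
    iterations: int = 10_000,
    burn_in: int = 5_000,
    seed: int = 0,
    config: AffinityConfig | None = None,
    compute_diagnostics: bool = True,
) -> AffinityPosterior:
    """Sample the posterior of the affinity model by MCMC.

    Parameters follow the community matrix convention: ``m`` holds the
    observed counts Y, ``E`` the strictly positive expected counts under
    independence.  Draws after ``burn_in`` are retained every
    ``config.thin`` sweeps; step sizes adapt only during burn-in so the
    retained draws come from a fixed kernel.
    """
    cfg = config or AffinityConfig()
    counts = m.counts if isinstance(m, CommunityMatrix) else m
    taxa = list(counts.index)
    envs = list(counts.columns)
    y = counts.to_numpy(dtype=float)
    e = E.to_numpy(dtype=float) if isinstance(E, pd.DataFrame) else np.asarray(E, dtype=float)
    if e.shape != y.shape:
        raise ValueError(f"E has shape {e.shape}, expected {y.shape}")
    if (e <= 0).any():
        raise ValueError("expected counts E must be strictly positive")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")

    n_keep = (iterations - burn_in) // cfg.thin
    i_dim, j_dim = y.shape
    lam = np.empty((chains, n_keep, i_dim, j_dim), dtype=np.float32)
    nu_out = np.empty_like(lam)
    theta_out = np.empty((chains, n_keep, i_dim), dtype=np.float32)
    gamma_out = np.empty((chains, n_keep, j_dim), dtype=np.float32)
    alpha_out = np.empty((chains, n_keep))
    w_out = np.empty((chains, n_keep))
    var_out = {
        k: np.empty((chains, n_keep))
        for k in ("var_theta", "var_gamma", "var_noise", "var_signal")
    }

    for c, child_seed in enumerate(np.random.SeedSequence(seed).spawn(chains)):
        rng = np.random.default_rng(child_seed)
        state = _ChainState(y, e, cfg, rng)
        kept = 0
        for it in range(iterations):
            state.sweep()
            in_burn = it < burn_in
            if in_burn and (it + 1) % cfg.adapt_interval == 0:
                state.adapt()
            if not in_burn and (it - burn_in) % cfg.thin == cfg.thin - 1:
                lam[c, kept] = np.exp(state.eta())
                nu_out[c, kept] = state.nu
                theta_out[c, kept] = state.theta
                gamma_out[c, kept] = state.gamma
                alpha_out[c, kept] = state.alpha
                w_out[c, kept] = state.w
                for k in var_out:
                    var_out[k][c, kept] = getattr(state, k)
                kept += 1
        if state.cell_tries and state.cell_accepts / state.cell_tries < 0.01:
            raise RuntimeError(
                "interaction updates accepted in under 1% of proposals; "
                "the sampler has stalled -- lower AffinityConfig.init_step "
                "or increase burn_in"
            )

    posterior = AffinityPosterior(
        taxa=taxa,
        environments=envs,
        lambda_draws=lam[:, :n_keep],
        alpha_draws=alpha_out,
        theta_draws=theta_out,
        gamma_draws=gamma_out,
        nu_draws=nu_out,
        mix_weight_draws=w_out,
        variance_draws=var_out,
    )
    if compute_diagnostics:
        posterior.diagnostics = _diagnostics(posterior)
    return posterior


def _diagnostics(p: AffinityPosterior) -> pd.DataFrame:
    """Effective sample size and split-chain R-hat for the scalar
    parameters and the worst-behaved lambda cells."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        data = {
            "alpha": p.alpha_draws,
            "mix_weight": p.mix_weight_draws,
            **p.variance_draws,
        }
        rows = []
        for name, draws in data.items():
            rows.append(
                (
                    name,
                    float(az.ess(np.asarray(draws, dtype=float))),
                    float(az.rhat(np.asarray(draws, dtype=float))),
                )
            )
        logs = np.log(np.asarray(p.lambda_draws, dtype=float))
        flat = logs.reshape(logs.shape[0], logs.shape[1], -1)
        rhats = np.array([float(az.rhat(flat[:, :, k])) for k in range(flat.shape[2])])
        esss = np.array([float(az.ess(flat[:, :, k])) for k in range(flat.shape[2])])
        rows.append(("log_lambda[worst]", float(esss.min()), float(rhats.max())))
    return pd.DataFrame(rows, columns=["parameter", "ess", "rhat"]).set_index("parameter")


def classify_affinity(p: AffinityPosterior, prob_cut: float = 0.95) -> pd.DataFrame:
    """Flag each cell: 'affinity' when P(lambda > 1) >= prob_cut,
    'under-presence' when P(lambda > 1) <= 1 - prob_cut, else 'none'."""
    prob = p.prob_gt1
    flags = np.full(prob.shape, "none", dtype=object)
    flags[prob.values >= prob_cut] = "affinity"
    flags[prob.values <= 1.0 - prob_cut] = "under-presence"
    return pd.DataFrame(flags, index=prob.index, columns=prob.columns)


@dataclass
class Dendrogram:
    """Environment clustering on log-affinities (agglomerative, Euclidean)."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assign = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        def recurse(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(recurse(ch, node.dist) for ch in (node.left, node.right))
            return f"({children}):{length:.6g}"

        root = to_tree(self.linkage)
        inner = ",".join(recurse(ch, root.dist) for ch in (root.left, root.right))
        return f"({inner});"


def cluster_environments(p: AffinityPosterior, method: str = "complete") -> Dendrogram:
    """Hierarchical clustering of environments by their taxa affinity
    profiles, Euclidean distance on log posterior-median affinities."""
    from scipy.cluster.hierarchy import linkage

    profiles = np.log(p.lambda_median.to_numpy()).T  # environments x taxa
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 environments to cluster")
    z = linkage(profiles, method=method, metric="euclidean")
    return Dendrogram(z, list(p.lambda_median.columns))


def affinity_heatmap(p: AffinityPosterior, path, prob_cut: float = 0.95) -> None:
    """Heat-map of log posterior-median affinities, purple (under-presence)
    to orange (affinity), with environments ordered by the dendrogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    dendro = cluster_environments(p)
    order = leaves_list(dendro.linkage)
    logmed = np.log(p.lambda_median.to_numpy())[:, order]
    bound = max(np.abs(logmed).max(), 1e-3)
    fig, ax = plt.subplots(figsize=(1 + 0.4 * logmed.shape[1], 1 + 0.25 * logmed.shape[0]))
    im = ax.imshow(logmed, cmap="PuOr_r", vmin=-bound, vmax=bound, aspect="auto")
    ax.set_xticks(range(logmed.shape[1]))
    ax.set_xticklabels([p.environments[k] for k in order], rotation=90, fontsize=6)
    ax.set_yticks(range(logmed.shape[0]))
    ax.set_yticklabels(p.taxa, fontsize=5)
    fig.colorbar(im, ax=ax, label="log median affinity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
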