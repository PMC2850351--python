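"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline's input surface:

* community matrices drawn from the affinity model's own generative
  process (Poisson counts with log-linear mean alpha + theta_i + gamma_j
  + nu_ij times an expected count);
* per-sample OTU occurrence tables with planted specialist, cosmopolitan
  and background taxa (presence draws only -- source data carry no
  within-sample genotype abundances);
* 16S-like sequence sets with controlled pairwise identity structure
  (substitutions only, so identity is exactly 1 - Hamming/length and the
  clustering oracle is alignment-free).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .diversity import cosmopolitan_env_threshold
from .seqprep import SequenceRecord

ALPHABET = np.array(list("ACGT"))


@dataclass
class GroundTruth:
    """True parameters behind a synthetic data set.

    theta and gamma follow the model's sum-to-zero convention; nu holds
    the per-cell adjusted affinity (log scale).  planted_roles maps taxon
    name to ("specialist", home_env), ("cosmopolitan", None) or
    ("background", None).
    """

    alpha: float = 0.0
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nu: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    planted_roles: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.nu.shape != (len(self.theta), len(self.gamma)):
            raise ValueError(
                f"nu shape {self.nu.shape} does not match theta "
                f"({len(self.theta)}) x gamma ({len(self.gamma)})"
            )

    @property
    def log_lambda(self) -> np.ndarray:
        return (
            self.alpha
            + self.theta[:, None]
            + self.gamma[None, :]
            + self.nu
        )

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "theta": self.theta.tolist(),
            "gamma": self.gamma.tolist(),
            "nu": self.nu.tolist(),
            "planted_roles": {k: list(v) for k, v in self.planted_roles.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def random_truth(
    n_taxa: int,
    n_envs: int,
    sigma_theta: float = 0.5,
    sigma_gamma: float = 0.5,
    signal_sd: float = 1.0,
    signal_fraction: float = 0.1,
    planted_cells: Mapping[tuple[int, int], float] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw main effects from centered normals and interactions from a
    spike-and-slab: a `signal_fraction` of cells get nu ~ N(0, signal_sd^2),
    the rest are exactly zero.  `planted_cells` pins chosen cells to fixed
    nu values on top of that."""
    rng = np.random.default_rng(seed)
    theta = _center(rng.normal(0, sigma_theta, n_taxa)) if sigma_theta > 0 else np.zeros(n_taxa)
    gamma = _center(rng.normal(0, sigma_gamma, n_envs)) if sigma_gamma > 0 else np.zeros(n_envs)
    nu = np.zeros((n_taxa, n_envs))
    if signal_fraction > 0 and signal_sd > 0:
        mask = rng.random((n_taxa, n_envs)) < signal_fraction
        nu[mask] = rng.normal(0, signal_sd, int(mask.sum()))
    for (i, j), value in (planted_cells or {}).items():
        nu[i, j] = value
    return GroundTruth(alpha=0.0, theta=theta, gamma=gamma, nu=nu)


def generate_community_matrix(
    n_taxa: int,
    n_envs: int,
    truth: GroundTruth,
    baseline_expected: float,
    seed: int = 0,
) -> tuple[CommunityMatrix, GroundTruth]:
    """Simulate Y_ij ~ Poisson(lambda_ij * E_ij) with E_ij constant.

    Heterogeneous expected counts are exercised downstream by feeding the
    model real margins; the generator keeps E flat so cell expectations
    are transparent."""
    if n_taxa < 2 or n_envs < 2:
        raise ValueError("need n_taxa >= 2 and n_envs >= 2")
    if baseline_expected <= 0:
        raise ValueError("baseline_expected must be positive")
    if len(truth.theta) != n_taxa:
        raise ValueError(f"theta has length {len(truth.theta)}, expected {n_taxa}")
    if len(truth.gamma) != n_envs:
        raise ValueError(f"gamma has length {len(truth.gamma)}, expected {n_envs}")

    rng = np.random.default_rng(seed)
    lam = np.exp(truth.log_lambda)
    y = rng.poisson(lam * baseline_expected)
    taxa = [f"taxon{i:03d}" for i in range(n_taxa)]
    envs = [f"env{j:02d}" for j in range(n_envs)]
    counts = pd.DataFrame(y, index=taxa, columns=envs)
    n_samples = pd.Series(1, index=counts.columns, dtype=np.int64)
    return CommunityMatrix(counts, n_samples), truth


@dataclass
class SampleOTUTable:
    """OTU presence set for one labelled sample."""

    sample_id: str
    environment: str
    otu_ids: set[str]


#: Per-sample, per-OTU presence probabilities for the planted roles.
STRONG_PRESETS = {
    "specialist": {"rate_home": 0.8, "rate_away": 0.02},
    "cosmopolitan": {"rate": 0.7},
    "background": {"rate": 0.05},
}


def generate_sample_tables(
    n_envs: int,
    samples_per_env: int,
    planted: Mapping[str, tuple[str, str | None]],
    seed: int = 0,
    otus_per_taxon: int = 3,
    presets: Mapping[str, Mapping[str, float]] = STRONG_PRESETS,
) -> tuple[list[SampleOTUTable], GroundTruth]:
    """Per-sample OTU tables with planted environmental roles.

    ``planted`` maps taxon name to ("specialist", home_env),
    ("cosmopolitan", None) or ("background", None).  Specialists are
    guaranteed >= 90% of their observations in the home environment and
    cosmopolitans >= 5 observations in >= 90% of environments: stochastic
    draws are first taken at the preset rates and then deterministically
    capped/topped-up so the planted property holds by construction.
    """
    if samples_per_env < 1:
        raise ValueError("samples_per_env must be >= 1")
    if not planted:
        raise ValueError("planted map must not be empty")

    rng = np.random.default_rng(seed)
    envs = [f"env{j:02d}" for j in range(n_envs)]
    samples = {
        env: [f"{env}_s{i:02d}" for i in range(samples_per_env)] for env in envs
    }
    # occurrence sets: otu_id -> set of sample ids
    presence: dict[str, set[str]] = {}
    otu_taxa: dict[str, str] = {}

    for t_idx, (taxon, (role, home)) in enumerate(sorted(planted.items())):
        otu_ids = [f"{taxon}_otu{k}" for k in range(otus_per_taxon)]
        for otu in otu_ids:
            otu_taxa[otu] = taxon
            presence[otu] = set()
        if role == "specialist":
            if home not in samples:
                raise ValueError(f"specialist {taxon!r}: unknown home environment {home!r}")
            p_home = presets["specialist"]["rate_home"]
            p_away = presets["specialist"]["rate_away"]
            for otu in otu_ids:
                for s in samples[home]:
                    if rng.random() < p_home:
                        presence[otu].add(s)
            # ensure planted OTUs are not singletons
            for otu in otu_ids:
                while len(presence[otu]) < 2:
                    presence[otu].add(samples[home][len(presence[otu])])
            home_occ = sum(len(presence[otu]) for otu in otu_ids)
            away_budget = home_occ // 9  # keeps home share >= 90%
            away = [
                (otu, s)
                for otu in otu_ids
                for env in envs
                if env != home
                for s in samples[env]
                if rng.random() < p_away
            ]
            for otu, s in away[:away_budget]:
                presence[otu].add(s)
        elif role == "cosmopolitan":
            p = presets["cosmopolitan"]["rate"]
            for otu in otu_ids:
                for env in envs:
                    for s in samples[env]:
                        if rng.random() < p:
                            presence[otu].add(s)
            need_envs = cosmopolitan_env_threshold(n_envs)
            capacity = samples_per_env * otus_per_taxon
            if capacity < 5:
                raise ValueError(
                    f"cosmopolitan {taxon!r}: {samples_per_env} samples x "
                    f"{otus_per_taxon} OTUs cannot reach 5 observations per environment"
                )
            # top up the first `need_envs` environments to >= 5 observations
            for env in envs[:need_envs]:
                occ = sum(1 for otu in otu_ids for s in presence[otu] if s in set(samples[env]))
                slots = [
                    (otu, s)
                    for otu in otu_ids
                    for s in samples[env]
                    if s not in presence[otu]
                ]
                for otu, s in slots[: max(0, 5 - occ)]:
                    presence[otu].add(s)
        elif role == "background":
            p = presets["background"]["rate"]
            for otu in otu_ids:
                for env in envs:
                    for s in samples[env]:
                        if rng.random() < p:
                            presence[otu].add(s)
        else:
            raise ValueError(f"unknown planted role {role!r} for taxon {taxon!r}")

    sample_otus: dict[str, set[str]] = {
        s: set() for env_samples in samples.values() for s in env_samples
    }
    for otu, sample_set in presence.items():
        for s in sample_set:
            sample_otus[s].add(otu)
    tables = [
        SampleOTUTable(s, env, sample_otus[s])
        for env in envs
        for s in samples[env]
    ]
    n_taxa = len(planted)
    truth = GroundTruth(
        theta=np.zeros(n_taxa),
        gamma=np.zeros(n_envs),
        nu=np.zeros((n_taxa, n_envs)),
        planted_roles=dict(planted),
    )
    truth.otu_taxa = otu_taxa  # type: ignore[attr-defined]
    truth.otu_presence = presence  # type: ignore[attr-defined]
    return tables, truth


def generate_sequences(
    n_otus: int,
    members_per_otu: int,
    within_identity: float,
    between_identity_max: float,
    length: int,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Sequence sets with planted OTU structure (substitutions only).

    Each OTU has a random seed sequence; members differ from it at at most
    (1 - within_identity) * length positions.  Seed sequences of distinct
    OTUs differ at more than (1 - between_identity_max) * length positions.
    Record ids carry the planted OTU (``otuK_mJ``) and each OTU's members
    are spread over two samples so planted OTUs are never singletons.
    """
    if not (between_identity_max < 0.97 <= within_identity <= 1.0):
        raise ValueError("need between_identity_max < 0.97 <= within_identity <= 1")
    if not 250 <= length <= 1900:
        raise ValueError("length must lie in [250, 1900]")
    min_between_diff = int((1 - between_identity_max) * length)
    if min_between_diff >= length:
        raise ValueError("between-OTU divergence impossible at this length")

    rng = np.random.default_rng(seed)
    seeds: list[np.ndarray] = []
    for _ in range(n_otus):
        for _attempt in range(1000):
            cand = rng.integers(0, 4, length)
            if all((cand != s).sum() > min_between_diff for s in seeds):
                seeds.append(cand)
                break
        else:
            raise ValueError(
                "could not satisfy between-OTU identity constraints; "
                "lower n_otus or between_identity_max"
            )

    max_sub = int(round((1 - within_identity) * length))
    records: list[SequenceRecord] = []
    for k, seq in enumerate(seeds):
        for j in range(members_per_otu):
            member = seq.copy()
            if j > 0 and max_sub > 0:
                n_sub = int(rng.integers(1, max_sub + 1))
                pos = rng.choice(length, n_sub, replace=False)
                member[pos] = (member[pos] + rng.integers(1, 4, n_sub)) % 4
            records.append(
                SequenceRecord(
                    id=f"otu{k}_m{j}",
                    sample_id=f"s{k}_{j % 2}",
                    residues="".join(ALPHABET[member]),
                )
            )
    return records


def write_sample_tables(tables: Sequence[SampleOTUTable], otu_taxa: Mapping[str, str], path) -> None:
    """Tidy occurrence TSV: sample_id, environment, otu_id, taxon."""
    rows = [
        (t.sample_id, t.environment, otu, otu_taxa.get(otu, ""))
        for t in tables
        for otu in sorted(t.otu_ids)
    ]
    pd.DataFrame(rows, columns=["sample_id", "environment", "otu_id", "taxon"]).to_csv(
        path, sep="\t", index=False
    )
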