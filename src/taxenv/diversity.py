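"""Specificity/cosmopolitanism classification, Hill diversity numbers and
collector's curves.

"Observations" of a taxon are (OTU, sample) presence pairs; OTUs seen in
only one sample are excluded upstream because a single observation cannot
support a statement about environmental distribution.  A taxon is
*specific* when at least 90% of its observations fall in one environment,
and *cosmopolitan* when it has at least 5 observations in at least 90% of
the environments at the chosen hierarchy level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import RankedTaxon


@dataclass
class OccurrenceVector:
    """Per-environment observation counts for one taxon."""

    taxon: str
    counts: np.ndarray
    environments: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.environments):
            raise ValueError("counts length must match environments")


def specificity(
    v: OccurrenceVector | np.ndarray, threshold: float = 0.9
) -> tuple[float, bool, str | None]:
    """Largest single-environment share of a taxon's observations.

    Returns (max_fraction, specific flag, home environment).  A taxon is
    specific when the largest share reaches the threshold; a tie for the
    maximum never yields a home environment.
    """
    counts = v.counts if isinstance(v, OccurrenceVector) else np.asarray(v)
    envs = v.environments if isinstance(v, OccurrenceVector) else list(range(len(counts)))
    total = counts.sum()
    if total <= 0:
        raise ValueError("occurrence vector is all zeros")
    top = counts.max()
    max_fraction = top / total
    tied = int((counts == top).sum()) > 1
    specific = (not tied) and max_fraction >= threshold
    home = envs[int(counts.argmax())] if specific else None
    return float(max_fraction), specific, home


def cosmopolitan_env_threshold(n_envs: int, fraction: float = 0.9) -> int:
    """Minimum number of environments that counts as `fraction` of them,
    with half-up rounding (5 of 5, 18 of 20, 41 of 46 at 90%)."""
    if n_envs < 1:
        raise ValueError("n_envs must be >= 1")
    return int(math.floor(fraction * n_envs + 0.5))


def is_cosmopolitan(
    v: OccurrenceVector | np.ndarray, min_obs: int = 5, fraction: float = 0.9
) -> bool:
    """True when the taxon has >= min_obs observations in at least the
    threshold number of environments."""
    counts = v.counts if isinstance(v, OccurrenceVector) else np.asarray(v)
    need = cosmopolitan_env_threshold(len(counts), fraction)
    return int((counts >= min_obs).sum()) >= need


def hill_number(p_or_counts: Sequence[float], q: int) -> float:
    """Hill diversity number of order q for a count or proportion vector.

    q=0 is richness (number of categories present), q=1 the exponential
    of Shannon entropy (natural log), q=2 the inverse Simpson index.
    """
    x = np.asarray(p_or_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative entries in abundance vector")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    if q == 0:
        return float((x > 0).sum())
    p = x / total
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p**2).sum())
    raise ValueError("q must be 0, 1 or 2")


def environment_diversity(per_env_taxon_presence: pd.DataFrame) -> pd.DataFrame:
    """Hill numbers N0, N1, N2 and the Shannon index per environment.

    Input: taxa x environments table of presence counts (how many samples
    of the environment each taxon appears in).  Environments whose column
    is all zeros are flagged rather than computed.
    """
    rows = []
    for env in per_env_taxon_presence.columns:
        col = per_env_taxon_presence[env].to_numpy(dtype=float)
        if col.sum() <= 0:
            rows.append((env, np.nan, np.nan, np.nan, np.nan, True))
            continue
        n0 = hill_number(col, 0)
        n1 = hill_number(col, 1)
        n2 = hill_number(col, 2)
        rows.append((env, n0, n1, n2, math.log(n1), False))
    return pd.DataFrame(
        rows, columns=["environment", "N0", "N1", "N2", "shannon", "empty"]
    ).set_index("environment")


@dataclass
class CollectorCurve:
    """Average number of distinct OTUs seen after m random draws."""

    depths: np.ndarray
    mean_distinct: np.ndarray
    replicates: int


def collectors_curve(
    metasample: Sequence[tuple[str, str]], repeats: int = 10, seed: int = 0
) -> CollectorCurve:
    """Collector's curve for a pooled environment metasample.

    Sequences (not OTUs) are the sampling units: each replicate draws the
    whole metasample in uniform random order without replacement and
    records the running number of distinct OTUs; replicates are averaged.
    """
    if not metasample:
        raise ValueError("metasample is empty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    otu_codes = pd.factorize(np.asarray([otu for _, otu in metasample]))[0]
    n = len(otu_codes)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(repeats):
        perm = otu_codes[rng.permutation(n)]
        first_seen = ~pd.Series(perm).duplicated().to_numpy()
        acc += np.cumsum(first_seen)
    return CollectorCurve(np.arange(1, n + 1), acc / repeats, repeats)


def expected_collectors_curve(otu_sizes: Sequence[int]) -> np.ndarray:
    """Exact expectation of the collector's curve under uniform sampling
    without replacement: E[distinct at depth m] =
    sum_o [1 - C(n - n_o, m) / C(n, m)]."""
    from scipy.special import gammaln

    sizes = np.asarray(otu_sizes, dtype=np.int64)
    n = int(sizes.sum())
    m = np.arange(1, n + 1)

    def log_comb(a, b):
        # C(a, b) with 0 where b > a
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        with np.errstate(invalid="ignore"):
            val = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return np.where(b > a, -np.inf, val)

    denom = log_comb(n, m)
    expect = np.zeros(n)
    for n_o in sizes:
        expect += 1.0 - np.exp(log_comb(n - n_o, m) - denom)
    return expect


def occurrence_vectors(
    sample_envs: Mapping[str, str],
    otu_taxa: Mapping[str, RankedTaxon | str],
    otu_presence: Mapping[str, set[str]],
    environments: Sequence[str],
    rank: str | None = None,
    exclude_singletons: bool = True,
) -> list[OccurrenceVector]:
    """Tally (OTU, sample) observation pairs per taxon and environment.

    ``sample_envs`` maps each sample to its environment category at the
    chosen hierarchy level; multi-labelled samples can be passed as
    repeated synthetic sample ids upstream.
    """
    env_index = {e: j for j, e in enumerate(environments)}
    vectors: dict[str, np.ndarray] = {}
    for otu_id, presence in otu_presence.items():
        if exclude_singletons and len(presence) <= 1:
            continue
        taxon = otu_taxa.get(otu_id)
        if taxon is None:
            continue
        if isinstance(taxon, RankedTaxon):
            name = taxon.name_at(rank) if rank else taxon.name
            if name is None:
                continue
        else:
            name = taxon
        vec = vectors.setdefault(name, np.zeros(len(environments), dtype=np.int64))
        for sample in presence:
            env = sample_envs.get(sample)
            if env in env_index:
                vec[env_index[env]] += 1
    return [
        OccurrenceVector(taxon, counts, list(environments))
        for taxon, counts in sorted(vectors.items())
    ]


def classify_roles(
    vectors: Iterable[OccurrenceVector],
    specificity_threshold: float = 0.9,
    min_obs: int = 5,
    env_fraction: float = 0.9,
) -> pd.DataFrame:
    """Specificity and cosmopolitanism flags for a set of taxa."""
    rows = []
    for v in vectors:
        frac, spec, home = specificity(v, specificity_threshold)
        cosmo = is_cosmopolitan(v, min_obs, env_fraction)
        rows.append((v.taxon, int(v.counts.sum()), frac, spec, home, cosmo))
    return pd.DataFrame(
        rows,
        columns=["taxon", "n_obs", "max_fraction", "specific", "home_env", "cosmopolitan"],
    ).set_index("taxon")
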