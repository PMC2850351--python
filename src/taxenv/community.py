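"""Environment hierarchy, sample labels and taxa x environment matrices.

Samples are labelled with a three-level nested habitat classification
(supertype > type > subtype).  Presence of OTUs in labelled samples is
tallied into a community matrix of distinct-OTU counts per taxon and
environment, together with the expected counts under independence of taxa
and environments and a per-sample size normalization.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .taxonomy import RANKS, RankedTaxon

LEVELS = ("supertype", "type", "subtype")

#: Name of the catch-all category for samples without a usable label.
UNKNOWN = "Unknown"


class HierarchyError(ValueError):
    """Raised for malformed environment hierarchy definitions."""


@dataclass(frozen=True)
class EnvironmentHierarchy:
    """The nested supertype/type/subtype habitat classification.

    ``subtype`` identifiers are qualified as ``"<type>/<subtype>"`` because
    bare subtype names (e.g. "Other", "Lakes") repeat across types.  A type
    with no finer division acts as its own subtype and keeps its bare name
    as the subtype identifier.
    """

    supertypes: tuple[str, ...]
    type_parent: Mapping[str, str]          # type -> supertype
    subtype_parent: Mapping[str, str]       # qualified subtype -> type

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(self.type_parent)

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(self.subtype_parent)

    def categories(self, level: str) -> tuple[str, ...]:
        if level == "supertype":
            return self.supertypes
        if level == "type":
            return self.types
        if level == "subtype":
            return self.subtypes
        raise ValueError(f"unknown hierarchy level: {level!r}")

    def subtypes_of(self, type_name: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.subtype_parent.items() if t == type_name)


def load_hierarchy(definition: str | Mapping | None = None) -> EnvironmentHierarchy:
    """Parse and validate an environment hierarchy.

    Parameters
    ----------
    definition:
        YAML text or a nested mapping ``{supertype: {type: [subtype, ...]}}``.
        ``None`` loads the bundled default vocabulary (5 supertypes,
        20 types, 46 subtypes).
    """
    if definition is None:
        definition = (
            importlib.resources.files("taxenv.data")
            .joinpath("environment_hierarchy.yaml")
            .read_text()
        )
    if isinstance(definition, str):
        definition = yaml.safe_load(definition)
    if not isinstance(definition, Mapping) or not definition:
        raise HierarchyError("hierarchy definition must be a non-empty mapping")

    supertypes: list[str] = []
    type_parent: dict[str, str] = {}
    subtype_parent: dict[str, str] = {}
    for supertype, types in definition.items():
        supertypes.append(str(supertype))
        if not isinstance(types, Mapping):
            raise HierarchyError(f"supertype {supertype!r} must map to types")
        for type_name, subtypes in types.items():
            type_name = str(type_name)
            if type_name in type_parent:
                raise HierarchyError(f"duplicate type {type_name!r}")
            type_parent[type_name] = str(supertype)
            if subtypes in (None, []):
                # childless type represents itself at the subtype level
                subtype_parent[type_name] = type_name
                continue
            if not isinstance(subtypes, list):
                raise HierarchyError(f"subtypes of {type_name!r} must be a list")
            for sub in subtypes:
                key = f"{type_name}/{sub}"
                if key in subtype_parent:
                    raise HierarchyError(f"duplicate subtype {key!r}")
                subtype_parent[key] = type_name
    return EnvironmentHierarchy(tuple(supertypes), type_parent, subtype_parent)


@dataclass(frozen=True)
class EnvironmentLabel:
    """A validated (supertype, type, subtype) path through the hierarchy."""

    supertype: str
    type: str
    subtype: str | None = None

    def validate(self, hierarchy: EnvironmentHierarchy) -> "EnvironmentLabel":
        if self.type not in hierarchy.type_parent:
            raise HierarchyError(f"unknown environment type {self.type!r}")
        if hierarchy.type_parent[self.type] != self.supertype:
            raise HierarchyError(
                f"type {self.type!r} does not belong to supertype {self.supertype!r}"
            )
        if self.subtype is not None:
            key = self._subtype_key()
            if hierarchy.subtype_parent.get(key) != self.type:
                raise HierarchyError(f"unknown subtype {key!r}")
        return self

    def _subtype_key(self) -> str:
        if self.subtype is None or self.subtype == self.type:
            return self.type
        return f"{self.type}/{self.subtype}"

    def category(self, level: str) -> str:
        """The category identifier of this label at a hierarchy level.

        A label without an explicit subtype falls back to its type's own
        subtype identifier, mirroring how childless types occupy the
        subtype level.
        """
        if level == "supertype":
            return self.supertype
        if level == "type":
            return self.type
        if level == "subtype":
            return self._subtype_key()
        raise ValueError(f"unknown hierarchy level: {level!r}")


@dataclass
class LabelledSample:
    """A sample with one or more environment labels (multi-origin allowed)."""

    sample_id: str
    labels: list[EnvironmentLabel]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"sample {self.sample_id!r} has no labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"sample {self.sample_id!r} has duplicate labels")


def read_labels(path, hierarchy: EnvironmentHierarchy | None = None) -> list[LabelledSample]:
    """Read a sample-label table: TSV with columns sample_id, supertype,
    type, subtype (subtype may be empty); repeated rows for multi-label
    samples."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[EnvironmentLabel]] = {}
    for row in df.itertuples(index=False):
        label = EnvironmentLabel(row.supertype, row.type, row.subtype or None)
        if hierarchy is not None:
            label.validate(hierarchy)
        out.setdefault(row.sample_id, []).append(label)
    return [LabelledSample(s, labels) for s, labels in out.items()]


@dataclass
class CommunityMatrix:
    """Distinct-OTU counts per taxon (rows) and environment (columns).

    ``counts`` is a taxa x environments DataFrame of non-negative integers;
    ``n_samples_per_env`` the number of labelled samples behind each column.
    """

    counts: pd.DataFrame
    n_samples_per_env: pd.Series
    level: str = "type"
    rank: str = "family"

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.n_samples_per_env.index):
            raise ValueError("n_samples_per_env index must match count columns")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def environments(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def build_matrix(
    samples: Iterable[LabelledSample],
    otu_taxa: Mapping[str, RankedTaxon],
    otu_presence: Mapping[str, set[str]],
    level: str = "type",
    rank: str = "family",
    exclude_singletons: bool = True,
    include_unknown: bool = False,
) -> CommunityMatrix:
    """Tally distinct OTUs per taxon and environment.

    Y_ij counts the OTUs assigned (via their lineage) to taxon i at `rank`
    that are present in at least one sample of environment j.  OTUs seen in
    exactly one sample ("singletons") are dropped when ``exclude_singletons``
    is set, since a single observation says nothing about environmental
    distribution.  A sample with several labels contributes to each of its
    environments.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown hierarchy level: {level!r}")
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomic rank: {rank!r}")

    env_samples: dict[str, set[str]] = {}
    for sample in samples:
        cats = {lab.category(level) for lab in sample.labels}
        if not cats:
            cats = {UNKNOWN}
        for cat in cats:
            env_samples.setdefault(cat, set()).add(sample.sample_id)
    if not include_unknown:
        env_samples.pop(UNKNOWN, None)

    environments = sorted(env_samples)
    taxa: set[str] = set()
    tally: dict[tuple[str, str], set[str]] = {}
    for otu_id, presence in otu_presence.items():
        if exclude_singletons and len(presence) <= 1:
            continue
        taxon = otu_taxa.get(otu_id)
        if taxon is None:
            continue
        name = taxon.name_at(rank)
        if name is None:
            continue
        taxa.add(name)
        for env in environments:
            if presence & env_samples[env]:
                tally.setdefault((name, env), set()).add(otu_id)

    taxa_sorted = sorted(taxa)
    counts = pd.DataFrame(
        [[len(tally.get((t, e), ())) for e in environments] for t in taxa_sorted],
        index=taxa_sorted,
        columns=environments,
        dtype=np.int64,
    )
    n_samples = pd.Series({e: len(env_samples[e]) for e in environments}, dtype=np.int64)
    n_samples = n_samples.reindex(environments)
    return CommunityMatrix(counts, n_samples, level=level, rank=rank)


def expected_counts(m: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Expected cell counts under independence of taxa and environments:
    E_ij = row_i total * column_j total / grand total."""
    counts = m.counts if isinstance(m, CommunityMatrix) else m
    y = counts.to_numpy(dtype=float)
    total = y.sum()
    if total <= 0:
        raise ValueError("community matrix is all zeros")
    e = np.outer(y.sum(axis=1), y.sum(axis=0)) / total
    return pd.DataFrame(e, index=counts.index, columns=counts.columns)


def size_normalize(m: CommunityMatrix) -> pd.DataFrame:
    """Average number of OTUs per sample: each column of Y divided by the
    number of samples in that environment."""
    n = m.n_samples_per_env
    if (n <= 0).any():
        bad = list(n.index[n <= 0])
        raise ValueError(f"environments with no samples: {bad}")
    return m.counts / n.astype(float)


def classified_fraction(n_classified: int, n_total: int) -> float:
    """Percentage of samples that received an environment label."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_classified / n_total
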