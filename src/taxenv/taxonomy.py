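"""Taxonomic assignment of sequences and OTU consensus taxonomy.

Sequence-level assignments come from external tools and are consumed as
tables: fixed-rank classifier calls with a confidence score, or similarity
search hits with bit-scores.  This module filters classifier calls,
aggregates hit tables into per-sequence assignments, and derives a
consensus taxon for each OTU as the deepest rank at which a single taxon
dominates the OTU's member sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Taxonomic ranks from shallowest to deepest.
RANKS = ("phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class RankedTaxon:
    """A taxon with its lineage from phylum down to its own rank."""

    rank: str
    name: str
    lineage: tuple[tuple[str, str], ...]  # ((rank, name), ...) phylum-first

    def __post_init__(self) -> None:
        if self.rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {self.rank!r}")
        idx = [_RANK_INDEX[r] for r, _ in self.lineage]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("lineage ranks must strictly descend")
        if not self.lineage or self.lineage[-1] != (self.rank, self.name):
            raise ValueError("lineage must end at (rank, name)")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "RankedTaxon":
        """Build from a phylum-first list of names, e.g. a 4-element list
        gives a family-rank taxon."""
        lineage = tuple(zip(RANKS[: len(names)], names))
        rank, name = lineage[-1]
        return cls(rank, name, lineage)

    def name_at(self, rank: str) -> str | None:
        for r, n in self.lineage:
            if r == rank:
                return n
        return None

    def truncate(self, rank: str) -> "RankedTaxon | None":
        """The ancestor of this taxon at `rank` (or None if too shallow)."""
        cut = _RANK_INDEX[rank]
        lineage = tuple((r, n) for r, n in self.lineage if _RANK_INDEX[r] <= cut)
        if not lineage or lineage[-1][0] != rank:
            return None
        return RankedTaxon(rank, lineage[-1][1], lineage)


@dataclass(frozen=True)
class SequenceAssignment:
    seq_id: str
    taxon: RankedTaxon
    confidence: float
    source: str = "classifier"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class TaxonomyConfig:
    """Thresholds for assignment filtering and OTU consensus.

    min_confidence
        Classifier calls at or below this confidence are discarded
        (strictly-greater rule, so 0.80 itself is dropped).
    hits_per_taxon
        How many best bit-scores per candidate taxon enter the average.
    margin
        Required lead (bit-score units) of the best taxon's average over
        the runner-up before a hit-based assignment is made.
    consensus_min_seqs
        Minimum OTU membership for a consensus call; OTUs need strictly
        more than five member sequences, hence the default 6.
    consensus_min_fraction
        A taxon must cover at least this fraction of the OTU's assigned
        sequences, and be the only taxon doing so at that rank.
    """

    min_confidence: float = 0.80
    hits_per_taxon: int = 5
    margin: float = 5.0
    consensus_min_seqs: int = 6
    consensus_min_fraction: float = 0.25
    denominator: str = "assigned"  # or "members"

    def __post_init__(self) -> None:
        if self.hits_per_taxon < 1:
            raise ValueError("hits_per_taxon must be >= 1")
        if not 0 < self.consensus_min_fraction <= 1:
            raise ValueError("consensus_min_fraction must lie in (0, 1]")
        if self.denominator not in ("assigned", "members"):
            raise ValueError("denominator must be 'assigned' or 'members'")


def filter_classifier_calls(
    calls: Iterable[SequenceAssignment], cfg: TaxonomyConfig | None = None
) -> list[SequenceAssignment]:
    """Keep only calls with confidence strictly above the threshold."""
    cfg = cfg or TaxonomyConfig()
    return [c for c in calls if c.confidence > cfg.min_confidence]


def aggregate_hits(
    hits: Iterable[tuple[RankedTaxon, float]], cfg: TaxonomyConfig | None = None
) -> SequenceAssignment | None:
    """Assign a sequence from a similarity-search hit table.

    For each candidate taxon the top ``hits_per_taxon`` bit-scores are
    averaged; the taxon with the best average wins if it leads the second
    best by at least ``margin``.  Exact ties never produce an assignment.
    With a single candidate the runner-up average is taken as 0.  The
    reported confidence is the lead scaled by the winning average
    (informational only).
    """
    cfg = cfg or TaxonomyConfig()
    by_taxon: dict[RankedTaxon, list[float]] = {}
    for taxon, score in hits:
        by_taxon.setdefault(taxon, []).append(float(score))
    if not by_taxon:
        return None
    averages = {
        taxon: sum(sorted(scores, reverse=True)[: cfg.hits_per_taxon])
        / min(len(scores), cfg.hits_per_taxon)
        for taxon, scores in by_taxon.items()
    }
    ordered = sorted(averages.items(), key=lambda kv: -kv[1])
    best_taxon, best = ordered[0]
    second = ordered[1][1] if len(ordered) > 1 else 0.0
    lead = best - second
    if lead <= 0 or lead < cfg.margin:
        return None
    confidence = min(1.0, lead / best) if best > 0 else 0.0
    return SequenceAssignment(
        seq_id="", taxon=best_taxon, confidence=confidence, source="hit_aggregation"
    )


def consensus_otu_taxon(
    member_ids: Iterable[str],
    assignments: Iterable[SequenceAssignment],
    cfg: TaxonomyConfig | None = None,
) -> RankedTaxon | None:
    """Consensus taxon of an OTU: the deepest rank where exactly one taxon
    covers at least ``consensus_min_fraction`` of the OTU's sequences.

    Returns None for OTUs that do not have strictly more than
    ``consensus_min_seqs - 1`` member sequences, or when no rank yields a
    unique dominant taxon.
    """
    cfg = cfg or TaxonomyConfig()
    members = set(member_ids)
    assignments = list(assignments)
    foreign = {a.seq_id for a in assignments} - members
    if foreign:
        raise ValueError(f"assignments reference non-member sequences: {sorted(foreign)}")
    if len(members) < cfg.consensus_min_seqs:
        return None

    by_seq: dict[str, RankedTaxon] = {a.seq_id: a.taxon for a in assignments}
    for rank in reversed(RANKS):  # species first, phylum last
        votes: dict[str, RankedTaxon] = {}
        tallies: dict[str, int] = {}
        n_assigned = 0
        for taxon in by_seq.values():
            ancestor = taxon.truncate(rank)
            if ancestor is None:
                continue
            n_assigned += 1
            tallies[ancestor.name] = tallies.get(ancestor.name, 0) + 1
            votes[ancestor.name] = ancestor
        denom = n_assigned if cfg.denominator == "assigned" else len(members)
        if denom == 0:
            continue
        dominant = [n for n, k in tallies.items() if k / denom >= cfg.consensus_min_fraction]
        if len(dominant) == 1:
            return votes[dominant[0]]
    return None


# ---------------------------------------------------------------------------
# Tabular I/O

def read_classifier_calls(path) -> list[SequenceAssignment]:
    """Read fixed-rank classifier output: TSV with columns seq_id, rank,
    lineage (semicolon-separated names, phylum first), confidence."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "lineage": str})
    calls = []
    for row in df.itertuples(index=False):
        taxon = RankedTaxon.from_names(row.lineage.split(";"))
        calls.append(SequenceAssignment(row.seq_id, taxon, float(row.confidence)))
    return calls


def read_hit_table(path, lineage_map: Mapping[str, RankedTaxon]) -> dict[str, list[tuple[RankedTaxon, float]]]:
    """Read 12-column tabular similarity-search output and map subjects to
    taxa.  Only query, subject and bitscore columns are used; hits whose
    subject has no lineage entry are dropped."""
    cols = [
        "query", "subject", "identity", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, dtype={"query": str, "subject": str})
    hits: dict[str, list[tuple[RankedTaxon, float]]] = {}
    for row in df.itertuples(index=False):
        taxon = lineage_map.get(row.subject)
        if taxon is None:
            continue
        hits.setdefault(row.query, []).append((taxon, float(row.bitscore)))
    return hits


def write_otu_taxonomy(otu_taxa: Mapping[str, RankedTaxon | None], path) -> None:
    rows = []
    for otu_id, taxon in sorted(otu_taxa.items()):
        if taxon is None:
            rows.append((otu_id, "", ""))
        else:
            rows.append((otu_id, taxon.rank, ";".join(n for _, n in taxon.lineage)))
    pd.DataFrame(rows, columns=["otu_id", "rank", "lineage"]).to_csv(
        path, sep="\t", index=False
    )
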