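"""Sequence preparation: length filtering, deduplication and greedy OTU
clustering at a fixed identity threshold.

The clustering follows the incremental greedy scheme used by the common
16S tools: sequences are processed longest-first, each joins the first
existing cluster whose representative it matches at or above the identity
threshold, otherwise it founds a new cluster.  Identity is matches over
alignment length; for equal-length sequences this is 1 - Hamming/length
(``N`` never counts as a match), for unequal lengths a global edit-distance
alignment is used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class SequenceRecord:
    """One 16S read/genotype and the sample it came from."""

    id: str
    sample_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OTU:
    """A cluster of sequences at >= the clustering identity threshold."""

    otu_id: str
    representative: str
    members: set[str]
    sample_presence: set[str]


@dataclass
class PrepConfig:
    min_len: int = 250
    max_len: int = 1900
    dedup_identity: float = 1.00
    otu_identity: float = 0.97
    min_seqs_per_sample: int = 5
    max_n_fraction: float = 0.10
    kmer_prefilter: bool = False
    kmer_size: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.otu_identity <= self.dedup_identity <= 1:
            raise ValueError("need 0 < otu_identity <= dedup_identity <= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


def length_filter(records: Iterable[SequenceRecord], cfg: PrepConfig | None = None) -> list[SequenceRecord]:
    """Drop sequences shorter than min_len or longer than max_len."""
    cfg = cfg or PrepConfig()
    return [r for r in records if cfg.min_len <= len(r) <= cfg.max_len]


def dedup_identical(
    records: Iterable[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse identical residue strings, keeping the first occurrence.

    Returns the surviving records and a map removed id -> kept id.
    """
    seen: dict[str, str] = {}
    kept: list[SequenceRecord] = []
    removed: dict[str, str] = {}
    for r in records:
        if r.residues in seen:
            removed[r.id] = seen[r.residues]
        else:
            seen[r.residues] = r.id
            kept.append(r)
    return kept, removed


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two sequences.

    Equal lengths: exact position-wise comparison (``N`` mismatches
    everything, including another ``N``).  Unequal lengths: global
    edit-distance alignment, identity = 1 - distance / longer length.
    """
    if len(a) == len(b):
        matches = sum(x == y and x != "N" for x, y in zip(a, b))
        return matches / len(a)
    # N must not match anything: give the two sides disjoint stand-ins
    qa = a.replace("N", "!")
    qb = b.replace("N", "?")
    dist = edlib.align(qa, qb, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def greedy_cluster(records: list[SequenceRecord], cfg: PrepConfig | None = None) -> list[OTU]:
    """Greedy incremental clustering at ``cfg.otu_identity``.

    Longest-first order (ties by id); each sequence joins the first
    cluster founded so far whose representative it matches at or above
    the threshold.  Optional k-mer prefiltering skips representatives that
    provably cannot reach the threshold (equal-length pairs only), so it
    never changes the result.
    """
    cfg = cfg or PrepConfig()
    bad = [r.id for r in records if r.residues.count("N") / len(r) > cfg.max_n_fraction]
    if bad:
        raise ValueError(f"sequences exceed {cfg.max_n_fraction:.0%} N content: {bad}")

    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    otus: list[OTU] = []
    reps: list[SequenceRecord] = []
    rep_kmers: list[set[str]] = []
    k = cfg.kmer_size
    for rec in ordered:
        rec_kmers = _kmers(rec.residues, k) if cfg.kmer_prefilter else None
        placed = False
        for otu, rep, rk in zip(otus, reps, rep_kmers if cfg.kmer_prefilter else reps):
            if rec_kmers is not None and len(rep.residues) == len(rec.residues):
                # d mismatches destroy at most d*k of the L-k+1 k-mers
                max_mismatch = int((1 - cfg.otu_identity) * len(rec))
                needed = (len(rec) - k + 1) - max_mismatch * k
                if needed > 0 and len(rec_kmers & rk) < needed:
                    continue
            if pairwise_identity(rec.residues, rep.residues) >= cfg.otu_identity:
                otu.members.add(rec.id)
                otu.sample_presence.add(rec.sample_id)
                placed = True
                break
        if not placed:
            otus.append(
                OTU(
                    otu_id=f"otu{len(otus):05d}",
                    representative=rec.id,
                    members={rec.id},
                    sample_presence={rec.sample_id},
                )
            )
            reps.append(rec)
            if cfg.kmer_prefilter:
                rep_kmers.append(rec_kmers if rec_kmers is not None else _kmers(rec.residues, k))
    return otus


def drop_small_samples(
    samples: Mapping[str, list[str]], cfg: PrepConfig | None = None
) -> dict[str, list[str]]:
    """Remove samples with fewer than ``min_seqs_per_sample`` sequences."""
    cfg = cfg or PrepConfig()
    return {s: ids for s, ids in samples.items() if len(ids) >= cfg.min_seqs_per_sample}


def group_by_sample(records: Iterable[SequenceRecord]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for r in records:
        out.setdefault(r.sample_id, []).append(r.id)
    return out


# ---------------------------------------------------------------------------
# FASTA I/O: the sample id is carried in the description as `sample=<id>`.

SAMPLE_RE = re.compile(r"sample=(\S+)")


def read_fasta(path, sample_pattern: re.Pattern | str = SAMPLE_RE) -> list[SequenceRecord]:
    if isinstance(sample_pattern, str):
        sample_pattern = re.compile(sample_pattern)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = sample_pattern.search(rec.description)
        if not m:
            raise ValueError(f"no sample id in FASTA header: {rec.description!r}")
        records.append(SequenceRecord(rec.id, m.group(1), str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    out = [
        SeqRecord(Seq(r.residues), id=r.id, description=f"sample={r.sample_id}")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def write_otu_table(otus: Iterable[OTU], records: Mapping[str, SequenceRecord], path) -> None:
    """OTU membership TSV: otu_id, representative, member, sample."""
    import pandas as pd

    rows = [
        (o.otu_id, o.representative, m, records[m].sample_id)
        for o in otus
        for m in sorted(o.members)
    ]
    pd.DataFrame(rows, columns=["otu_id", "representative", "member", "sample"]).to_csv(
        path, sep="\t", index=False
    )
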