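"""End-to-end orchestration: simulate -> prep -> taxonomy -> matrix ->
statistics -> affinity -> ordination, from a single YAML config.

Every stage writes its outputs under the configured output directory and
the run ends with a JSON manifest recording input hashes, seeds, stage
order and the resolved configuration, so a rerun with identical inputs
and seeds is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import affinity, community, diversity, ordination, seqprep, synthetic, taxonomy


@dataclass
class ModelSettings:
    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    thin: int = 5
    prob_cut: float = 0.95


@dataclass
class SimulateSettings:
    n_otus: int = 12
    members_per_otu: int = 12
    within_identity: float = 0.99
    between_identity_max: float = 0.90
    length: int = 500


@dataclass
class PipelineConfig:
    out_dir: str = "taxenv_run"
    seed: int = 0
    fasta: str | None = None            # None -> simulate stage provides it
    labels: str | None = None
    classifier_calls: str | None = None
    level: str = "type"
    rank: str = "family"
    exclude_singletons: bool = True
    exclude_multilabel: bool = False
    include_unknown_env: bool = False
    prep: seqprep.PrepConfig = field(default_factory=seqprep.PrepConfig)
    taxonomy: taxonomy.TaxonomyConfig = field(default_factory=taxonomy.TaxonomyConfig)
    model: ModelSettings = field(default_factory=ModelSettings)
    simulate: SimulateSettings = field(default_factory=SimulateSettings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("prep", seqprep.PrepConfig),
            ("taxonomy", taxonomy.TaxonomyConfig),
            ("model", ModelSettings),
            ("simulate", SimulateSettings),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def subsample_by_size(
    samples: list[community.LabelledSample],
    seq_counts: dict[str, int],
    min_seqs: int,
    max_seqs: int,
) -> list[community.LabelledSample]:
    """Keep samples whose sequence count lies in [min_seqs, max_seqs] --
    the robustness check that re-runs the occurrence statistics on
    comparably sized samples only."""
    if min_seqs > max_seqs:
        raise ValueError("min_seqs must not exceed max_seqs")
    return [
        s for s in samples if min_seqs <= seq_counts.get(s.sample_id, 0) <= max_seqs
    ]


def _simulate_stage(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    """Write a fully synthetic input set: FASTA with planted OTUs, sample
    labels cycling over environment types, and classifier calls derived
    from the planted OTU identity."""
    sim = cfg.simulate
    records = synthetic.generate_sequences(
        sim.n_otus,
        sim.members_per_otu,
        sim.within_identity,
        sim.between_identity_max,
        sim.length,
        seed=cfg.seed,
    )
    fasta = out / "sequences.fasta"
    seqprep.write_fasta(records, fasta)

    hierarchy = community.load_hierarchy()
    types = hierarchy.types
    labels_rows = []
    seen = set()
    for rec in records:
        if rec.sample_id in seen:
            continue
        seen.add(rec.sample_id)
        otu_idx = int(rec.id.split("_")[0].removeprefix("otu"))
        type_name = types[otu_idx % len(types)]
        labels_rows.append(
            (rec.sample_id, hierarchy.type_parent[type_name], type_name, "")
        )
    labels = out / "labels.tsv"
    pd.DataFrame(
        labels_rows, columns=["sample_id", "supertype", "type", "subtype"]
    ).to_csv(labels, sep="\t", index=False)

    calls_rows = []
    for rec in records:
        otu_idx = int(rec.id.split("_")[0].removeprefix("otu"))
        lineage = ";".join(
            [
                f"Phylum{otu_idx % 3}",
                f"Class{otu_idx % 3}",
                f"Order{otu_idx % 3}",
                f"Family{otu_idx}",
            ]
        )
        calls_rows.append((rec.id, "family", lineage, 0.95))
    calls = out / "classifier_calls.tsv"
    pd.DataFrame(
        calls_rows, columns=["seq_id", "rank", "lineage", "confidence"]
    ).to_csv(calls, sep="\t", index=False)
    return {"fasta": fasta, "labels": labels, "classifier_calls": calls}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []
    manifest: dict = {"seed": cfg.seed, "config": cfg.resolved(), "stages": stages_run}

    try:
        if cfg.fasta is None:
            inputs = _simulate_stage(cfg, out)
            stages_run.append("simulate")
        else:
            inputs = {
                "fasta": Path(cfg.fasta),
                "labels": Path(cfg.labels) if cfg.labels else None,
                "classifier_calls": Path(cfg.classifier_calls) if cfg.classifier_calls else None,
            }
        for name, path in inputs.items():
            if path is None or not path.exists():
                raise FileNotFoundError(f"missing input for {name!r}: {path}")
        manifest["inputs"] = {k: _sha256(v) for k, v in inputs.items()}

        # --- prep ----------------------------------------------------
        records = seqprep.read_fasta(inputs["fasta"])
        records = seqprep.length_filter(records, cfg.prep)
        records, removed = seqprep.dedup_identical(records)
        kept_samples = seqprep.drop_small_samples(
            seqprep.group_by_sample(records), cfg.prep
        )
        records = [r for r in records if r.sample_id in kept_samples]
        otus = seqprep.greedy_cluster(records, cfg.prep)
        rec_map = {r.id: r for r in records}
        seqprep.write_otu_table(otus, rec_map, out / "otus.tsv")
        stages_run.append("prep")

        # --- taxonomy ------------------------------------------------
        calls = taxonomy.read_classifier_calls(inputs["classifier_calls"])
        calls = taxonomy.filter_classifier_calls(calls, cfg.taxonomy)
        calls_by_seq: dict[str, list] = {}
        for c in calls:
            calls_by_seq.setdefault(c.seq_id, []).append(c)
        otu_taxa = {}
        for otu in otus:
            member_calls = [c for m in otu.members for c in calls_by_seq.get(m, [])]
            otu_taxa[otu.otu_id] = taxonomy.consensus_otu_taxon(
                otu.members, member_calls, cfg.taxonomy
            )
        taxonomy.write_otu_taxonomy(otu_taxa, out / "otu_taxonomy.tsv")
        stages_run.append("taxonomy")

        # --- matrix --------------------------------------------------
        hierarchy = community.load_hierarchy()
        samples = community.read_labels(inputs["labels"], hierarchy)
        if cfg.exclude_multilabel:
            samples = [s for s in samples if len(s.labels) == 1]
        presence = {o.otu_id: set(o.sample_presence) for o in otus}
        assigned = {k: v for k, v in otu_taxa.items() if v is not None}
        matrix = community.build_matrix(
            samples,
            assigned,
            presence,
            level=cfg.level,
            rank=cfg.rank,
            exclude_singletons=cfg.exclude_singletons,
            include_unknown=cfg.include_unknown_env,
        )
        matrix.to_tsv(out / "community_matrix.tsv")
        expected = community.expected_counts(matrix)
        expected.to_csv(out / "expected_counts.tsv", sep="\t")
        normalized = community.size_normalize(matrix)
        normalized.to_csv(out / "normalized_matrix.tsv", sep="\t")
        stages_run.append("matrix")

        # --- occurrence statistics ----------------------------------
        sample_envs = {
            s.sample_id: lab.category(cfg.level) for s in samples for lab in s.labels
        }
        environments = sorted({e for e in sample_envs.values()})
        vectors = diversity.occurrence_vectors(
            sample_envs, assigned, presence, environments,
            rank=cfg.rank, exclude_singletons=cfg.exclude_singletons,
        )
        if vectors:
            diversity.classify_roles(vectors).to_csv(out / "taxon_roles.tsv", sep="\t")
        diversity.environment_diversity(matrix.counts).to_csv(
            out / "environment_diversity.tsv", sep="\t"
        )
        env_members: dict[str, list[tuple[str, str]]] = {}
        for otu in otus:
            for member in sorted(otu.members):
                env = sample_envs.get(rec_map[member].sample_id)
                if env is not None:
                    env_members.setdefault(env, []).append((member, otu.otu_id))
        curves = {
            env: diversity.collectors_curve(meta, seed=cfg.seed)
            for env, meta in sorted(env_members.items())
        }
        curve_df = pd.DataFrame(
            {env: pd.Series(c.mean_distinct, index=c.depths) for env, c in curves.items()}
        )
        curve_df.to_csv(out / "collector_curves.tsv", sep="\t")
        stages_run.append("stats")

        # --- affinity model ------------------------------------------
        ms = cfg.model
        posterior = affinity.fit(
            matrix,
            expected,
            chains=ms.chains,
            iterations=ms.iterations,
            burn_in=ms.burn_in,
            seed=cfg.seed,
            config=affinity.AffinityConfig(
                chains=ms.chains, iterations=ms.iterations,
                burn_in=ms.burn_in, thin=ms.thin,
            ),
        )
        posterior.summary_table(ms.prob_cut).to_csv(
            out / "affinity_summary.tsv", sep="\t", index=False
        )
        if len(matrix.environments) >= 2:
            dendro = affinity.cluster_environments(posterior)
            (out / "environment_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        stages_run.append("affinity")

        # --- ordination ----------------------------------------------
        if matrix.counts.to_numpy().sum() > 0 and min(matrix.counts.shape) >= 2:
            ca = ordination.correspondence_analysis(normalized)
            if ca.row_scores.shape[1] >= 2:
                ca = ordination.detrend_by_segments(ca)
            ca.row_scores.to_csv(out / "ordination_taxa.tsv", sep="\t")
            ca.col_scores.to_csv(out / "ordination_environments.tsv", sep="\t")
        stages_run.append("ordinate")
    except Exception as err:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for item in out.iterdir():
            if item.name != "failed":
                shutil.move(str(item), failed / item.name)
        stage = stages_run[-1] if stages_run else "inputs"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {err}") from err

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
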