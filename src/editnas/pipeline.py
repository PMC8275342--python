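"""End-to-end reproducible pipeline: simulate -> stats -> train -> eval ->
interpret -> variants, with a manifest recording config, seeds and checksums.

Every stochastic stage has an explicit seed in :class:`PipelineConfig`; the
config round-trips through YAML unchanged, and a rerun with the same config
produces identical checksums for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigError
from .metrics import evaluation_report
from .model import (ArchitectureTokens, ModelConfig, build_model,
                    save_checkpoint, train, predict)
from .mutagenesis import (average_importance, saturated_mutagenesis,
                          select_accurate_sequences, write_importance_tsv)
from .outcomes import TASK_NAMES, profile_table
from .sequences import encode_batch, split_dataset, write_sites_tsv
from .simulate import (PlantedRule, generate_windows,
                       make_fixture_genome_and_vcf, planted_profiles,
                       simulate_event_table)
from .variants import (rank_least_variant_targets, scan_pam_sites,
                       variant_effect_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Seeds, sizes and thresholds for one demo-scale run."""

    n_windows: int = 2000
    event_depth: int = 1000
    min_indel_reads: int = 10
    mutagenesis_tolerance: float = 0.05
    effect_threshold: float = 0.30
    split_ratios: tuple = (0.8, 0.1, 0.1)
    arch_ops: tuple = (1, 2, 7, 7, 7, 7, 7, 7)
    seed_simulate: int = 11
    seed_split: int = 12
    seed_train: int = 13
    seed_fixture: int = 14
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        max_epochs=25, early_stop_patience=10, dropout=0.05))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["split_ratios"] = list(d["split_ratios"])
        d["arch_ops"] = list(d["arch_ops"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        for key in ("split_ratios", "arch_ops"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage on synthetic data and write a run manifest.

    Returns the run directory.  Any stage failure raises with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": None, "stages": {}}
    config.to_yaml(out / "config.yaml")
    manifest["config"] = yaml.safe_load((out / "config.yaml").read_text())

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, *files):
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 2),
            "checksums": {f.name: _sha256(f) for f in files}}
        logger.info("stage %s finished in %.1fs", name, time.time() - t0)

    # simulate: windows, planted profiles, event tables
    t0 = stage("simulate")
    rule = PlantedRule()
    sites = generate_windows(config.n_windows, seed=config.seed_simulate)
    profiles = planted_profiles(sites, rule, seed=config.seed_simulate + 1)
    sites_path = out / "windows.tsv"
    write_sites_tsv(sites, sites_path)
    done("simulate", t0, sites_path)

    # stats: event tables -> recovered profiles
    t0 = stage("stats")
    groups = []
    for i, site in enumerate(sites):
        from .outcomes import OutcomeProfile

        prof = OutcomeProfile.from_array(profiles[i])
        groups.append((site.site_id,
                       simulate_event_table(prof, config.event_depth,
                                            seed=config.seed_simulate + 2 + i)))
    table = profile_table(groups, min_indel_reads=config.min_indel_reads)
    profiles_path = out / "profiles.tsv"
    table.to_csv(profiles_path, sep="\t", index=False)
    done("stats", t0, profiles_path)

    # train on the recovered profiles
    t0 = stage("train")
    by_id = {s.site_id: s for s in sites}
    kept_sites = [by_id[sid] for sid in table["site_id"]]
    Y = table[list(TASK_NAMES)].to_numpy()
    records = list(zip(kept_sites, Y))
    train_r, val_r, test_r = split_dataset(records, config.split_ratios,
                                           seed=config.seed_split)

    def xy(rs):
        return (encode_batch([s for s, _ in rs]),
                np.stack([y for _, y in rs]))

    cfg = dataclasses.replace(config.model, seed=config.seed_train)
    tokens = ArchitectureTokens(
        ops=config.arch_ops,
        residuals=tuple((0,) * t for t in range(len(config.arch_ops))))
    net = build_model(tokens, cfg)
    trained = train(net, xy(train_r), xy(val_r), cfg)
    ckpt_path = out / "model.json"
    save_checkpoint(trained, ckpt_path)
    done("train", t0, ckpt_path)

    # evaluate on the held-out test split
    t0 = stage("eval")
    Xte, Yte = xy(test_r)
    report = evaluation_report(predict(trained, Xte), Yte)
    report_path = out / "evaluation.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    done("eval", t0, report_path)

    # interpret: mutagenesis averaged over accurately predicted test windows
    t0 = stage("interpret")
    test_sites = [s for s, _ in test_r]
    kept = select_accurate_sequences(trained, test_sites, Yte,
                                     tolerance=config.mutagenesis_tolerance)
    use = kept if kept else test_sites
    mats = [saturated_mutagenesis(trained, s)["ins1"] for s in use[:50]]
    avg = average_importance(mats)
    imp_path = out / "importance_ins1.tsv"
    write_importance_tsv(avg, imp_path)
    done("interpret", t0, imp_path)

    # variants: toy genome fixture -> scan -> intersect -> rank
    t0 = stage("variants")
    fixture = make_fixture_genome_and_vcf(config.seed_fixture, out / "fixture")
    pam_sites = scan_pam_sites(fixture["fasta"], fixture["bed"])
    effects = variant_effect_table(trained, pam_sites, fixture["vcf"])
    effects_path = out / "variant_effects.tsv"
    effects.to_csv(effects_path, sep="\t", index=False)
    ranking = rank_least_variant_targets(effects, all_sites=pam_sites)
    ranking_path = out / "target_ranking.tsv"
    ranking.to_csv(ranking_path, sep="\t", index=False)
    done("variants", t0, effects_path, ranking_path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
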