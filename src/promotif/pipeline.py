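"""End-to-end pipeline: configuration, staging and the run driver.

Composes the full analysis: DE-table consensus -> upstream region
extraction -> background model -> subsample-ensemble discovery (run
separately for the over- and under-expressed lists, never pooled) ->
k-medoids clustering -> cluster averages -> genome-wide remapping ->
database annotation.  Every stage's output is serialized into the run
directory and a manifest records parameters and derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .de_consensus import (consensus_gene_lists, load_de_tables,
                           write_consensus)
from .discovery import EngineConfig
from .ensemble import MotifDiscoveryModel
from .genome_io import (build_background, extract_upstream, load_reference,
                        write_background, write_regions_fasta)
from .map_annotate import export_map, match_database, scan_regions
from .motifs import load_motif_database, write_meme

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the study-scale parameters
    (1000 bp flanks, 5000 subsets of 10, q <= 0.05, e-like <= 0.001,
    top 5, minimum width 6)."""

    genome: str = ""
    annotation: str = ""
    de_tables: dict[str, str] = field(default_factory=dict)  # "cv:tp" -> path
    database: str = ""
    output_dir: str = "promotif_run"
    flank_length: int = 1000
    background_order: int = 4
    alpha: float = 0.05
    engines: list[dict] = field(default_factory=lambda: [
        {"engine": "seed_qvalue"}])
    n_subsets: int = 5000
    subset_size: int = 10
    cluster_k: Any = "auto"
    score_fraction: float = 0.85
    match_top_n: int = 5
    seed: int = 0

    def engine_configs(self) -> list[EngineConfig]:
        configs = []
        for spec in self.engines:
            kwargs = dict(spec)
            if "width_range" in kwargs:
                kwargs["width_range"] = tuple(kwargs["width_range"])
            configs.append(EngineConfig(**kwargs))
        return configs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_RANGE_CHECKS = {
    "flank_length": lambda v: v >= 1,
    "background_order": lambda v: v >= 1,
    "alpha": lambda v: 0 < v < 1,
    "n_subsets": lambda v: v >= 1,
    "subset_size": lambda v: v >= 1,
    "score_fraction": lambda v: 0 < v <= 1,
    "match_top_n": lambda v: v >= 1,
}


def validate_config(source) -> PipelineConfig:
    """Parse a YAML config stream/string/dict: defaults injected, unknown
    keys rejected, ranges checked; the resolved config is logged."""
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        data = yaml.safe_load(source.read() if hasattr(source, "read")
                              else source) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = PipelineConfig(**data)
    for key, check in _RANGE_CHECKS.items():
        value = getattr(config, key)
        if not check(value):
            raise ValueError(f"config key {key!r} out of range: {value!r}")
    if config.cluster_k != "auto" and (not isinstance(config.cluster_k, int)
                                       or config.cluster_k < 1):
        raise ValueError(f"config key 'cluster_k' out of range: "
                         f"{config.cluster_k!r}")
    config.engine_configs()  # validates engine specs
    logger.info("resolved config: %s", config.to_dict())
    return config


def _stage(name):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s: start", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> str:
    """Execute every stage; returns the run directory.

    The over- and under-expressed gene lists are processed as independent
    discovery runs.  All randomness derives from ``config.seed``.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "stages": {}}

    # --- DE consensus
    def de_stage():
        keys = {}
        for label, path in config.de_tables.items():
            cultivar, timepoint = label.split(":")
            keys[(cultivar, timepoint)] = path
        tables = load_de_tables(keys)
        return consensus_gene_lists(tables, config.alpha)

    consensus = _stage("de_consensus")(de_stage)
    write_consensus(consensus, os.path.join(out, "over_expressed.txt"),
                    os.path.join(out, "under_expressed.txt"),
                    os.path.join(out, "consensus_summary.json"))
    manifest["stages"]["de_consensus"] = {
        "n_over": len(consensus.over_expressed),
        "n_under": len(consensus.under_expressed),
        "timepoint_only": {t: list(v) for t, v in
                           consensus.timepoint_only.items()}}

    # --- regions + background
    def region_stage():
        contigs, annotations = load_reference(config.genome,
                                              config.annotation)
        regions = extract_upstream(contigs, annotations,
                                   config.flank_length)
        background = build_background(regions, config.background_order)
        return regions, background

    regions, background = _stage("extract_upstream")(region_stage)
    with open(os.path.join(out, "upstream_regions.fasta"), "w") as fh:
        write_regions_fasta(regions, fh)
    write_background(background, os.path.join(out, "background"))
    manifest["stages"]["extract_upstream"] = {"n_regions": len(regions)}

    database = None
    if config.database:
        with open(config.database) as fh:
            database = load_motif_database(fh)

    by_gene = {r.gene_id: r for r in regions}
    for direction, gene_list in (("over", consensus.over_expressed),
                                 ("under", consensus.under_expressed)):
        list_seed = int(rng.integers(2 ** 31))
        stage_name = f"discovery_{direction}"
        list_regions = [by_gene[g] for g in gene_list if g in by_gene]
        skipped = [g for g in gene_list if g not in by_gene]
        if skipped:
            logger.warning("%s: %d genes without upstream regions skipped",
                           stage_name, len(skipped))
        if len(list_regions) < config.subset_size:
            if list_regions:
                raise PipelineError(stage_name, ValueError(
                    f"subset_size {config.subset_size} exceeds the "
                    f"{len(list_regions)} {direction}-expressed regions"))
            logger.warning("%s: empty gene list, skipped", stage_name)
            manifest["stages"][stage_name] = {"n_genes": 0}
            continue

        def discovery_stage():
            model = MotifDiscoveryModel(
                list_regions, background=background,
                engine_configs=config.engine_configs(),
                n_subsets=config.n_subsets,
                subset_size=config.subset_size,
                cluster_k=config.cluster_k)
            return model.fit(seed=list_seed)

        results = _stage(stage_name)(discovery_stage)
        prefix = os.path.join(out, direction)
        with open(f"{prefix}_pooled_motifs.meme", "w") as fh:
            write_meme(results.pooled_motifs, fh)
        with open(f"{prefix}_cluster_averages.meme", "w") as fh:
            write_meme(results.cluster_averages, fh)
        results.summary().to_csv(f"{prefix}_clusters.tsv", sep="\t",
                                 index=False)

        instances = _stage(f"mapping_{direction}")(
            lambda: results.scan(list_regions, config.score_fraction))
        export_map(instances, list_regions, f"{prefix}_instances.bed",
                   f"{prefix}_layout.json")

        matches_rows = []
        if database:
            for cid, matches in results.match_database(
                    database, config.match_top_n).items():
                for m in matches:
                    matches_rows.append((cid, m.database_id, m.mismatches,
                                         m.best_offset, m.orientation,
                                         m.rank))
            with open(f"{prefix}_database_matches.tsv", "w") as fh:
                fh.write("query\tdatabase_id\tmismatches\toffset\t"
                         "orientation\trank\n")
                for row in matches_rows:
                    fh.write("\t".join(str(x) for x in row) + "\n")
        manifest["stages"][stage_name] = {
            "n_genes": len(list_regions),
            "n_pooled_motifs": len(results.pooled_motifs),
            "n_clusters": len(results.clusters),
            "n_instances": len(instances),
            "n_database_matches": len(matches_rows),
            "seed": list_seed}
        logger.info("%s: %d pooled motifs, %d clusters, %d instances",
                    stage_name, len(results.pooled_motifs),
                    len(results.clusters), len(instances))

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
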