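"""Pipeline orchestration: run stages in dependency order with a manifest."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment, setops, synthetic_data
from .io_core import (
    RunConfig,
    SgcapError,
    read_count_matrix,
    write_gene_set,
    write_table,
)

logger = logging.getLogger("sgcap")

KNOWN_STAGES = ("simulate", "enrich", "classify")


class DependencyError(SgcapError):
    """A stage's upstream output is missing."""


@dataclass
class PipelineManifest:
    """Record of a pipeline run: stages, config, seed, outputs."""

    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages},
            indent=2))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PipelineManifest":
        raw = json.loads(Path(path).read_text())
        return cls(config=raw["config"], seed=raw["seed"], stages=raw["stages"])


def run_pipeline(out_dir: str | os.PathLike,
                 config: RunConfig | None = None,
                 stages: tuple[str, ...] = KNOWN_STAGES,
                 n_genes: int = 500,
                 n_enriched: int = 50,
                 n_depleted: int = 20,
                 log2fc: float = 2.0) -> PipelineManifest:
    """Run simulate -> enrich -> classify on a synthetic labeling experiment.

    Each stage validates that its upstream outputs exist before anything
    runs; identical config + seed give byte-identical outputs.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise SgcapError(f"unknown stages: {sorted(unknown)}")

    counts_path = out_dir / "counts.tsv"
    meta_path = out_dir / "metadata.tsv"
    contrast_paths = {name: out_dir / f"contrast_{name}.tsv"
                      for name in enrichment.STANDARD_CONTRASTS}

    # dependency check up front
    if "enrich" in stages and "simulate" not in stages:
        if not counts_path.exists() or not meta_path.exists():
            raise DependencyError("enrich needs counts from a prior simulate run")
    if "classify" in stages and "enrich" not in stages:
        missing = [str(p) for p in contrast_paths.values() if not p.exists()]
        if missing:
            raise DependencyError(f"classify needs contrast tables: {missing}")

    manifest = PipelineManifest(config=config.to_dict(), seed=config.seed)

    if "simulate" in stages:
        logger.info("stage simulate: seed=%d n_genes=%d", config.seed, n_genes)
        cm, truth = synthetic_data.simulate_three_contrast_counts(
            n_genes=n_genes, n_enriched=n_enriched, n_depleted=n_depleted,
            log2fc=log2fc, seed=config.seed)
        write_table(cm.counts, counts_path, config=config)
        write_table(cm.samples, meta_path, config=config)
        truth_path = out_dir / "planted_truth.tsv"
        planted = pd.Series(
            {g: fc for eff in truth.planted_effects
             for g, fc in eff.log2fc.items()}, name="log2fc")
        planted.rename_axis("gene_id").to_frame().to_csv(truth_path, sep="\t")
        manifest.stages.append({"stage": "simulate", "status": "ok",
                                "n_genes": n_genes,
                                "outputs": [str(counts_path), str(meta_path)]})

    if "enrich" in stages:
        cm = read_count_matrix(counts_path, meta_path)
        for name, path in contrast_paths.items():
            logger.info("stage enrich: contrast %s", name)
            table = enrichment.test_contrast(cm, name)
            write_table(table, path, config=config)
        manifest.stages.append({"stage": "enrich", "status": "ok",
                                "outputs": [str(p) for p in contrast_paths.values()]})

    if "classify" in stages:
        tables = {name: enrichment.read_contrast_table(path)
                  for name, path in contrast_paths.items()}
        result = enrichment.classify_transcriptome(
            tables["post_vs_pre"], tables["pa_vs_nopa"],
            tables["targeted_vs_untargeted"], config)
        from .io_core import GeneSetTable
        prox_path = out_dir / "proximal.tsv"
        excl_path = out_dir / "excluded.tsv"
        write_gene_set(GeneSetTable("proximal", result.proximal), prox_path)
        write_gene_set(GeneSetTable("excluded", result.excluded), excl_path)
        manifest.stages.append({
            "stage": "classify", "status": "ok",
            "n_proximal": len(result.proximal),
            "n_excluded": len(result.excluded),
            "outputs": [str(prox_path), str(excl_path)]})

    manifest.save(out_dir / "manifest.json")
    return manifest
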