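"""End-to-end pipeline orchestration from a single YAML config.

Stages: rarefaction -> rule-based annotation -> de-nesting -> diversity and
C:N:S ratios -> heatmap clustering -> (optional) CLPP plate scoring ->
co-occurrence network.  Every stage writes a new file (no stage mutates
another's inputs) and the run manifest echoes versions, seeds and
parameters; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coocnet import (
    edges_to_dataframe,
    infer_network,
    summary_to_dataframe,
)
from .diversity import cns_ratio, diversity_profile
from .ecoplate import clpp_indices, load_layout, read_intensity_csv, score_plate
from .faprotax import annotate, deduplicate, element_totals, load_regroup, load_rules
from .multivariate import bray_curtis, hcluster
from .zotu_io import rarefy, read_zotu_table, write_zotu_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    zotu_table: str
    out_dir: str
    rule_db: str | None = None  # None -> bundled miniature rule set
    regroup: str | None = None
    rarefy_depth: int = 2000
    rarefy_seed: int = 42
    ecoplate_csv: str | None = None
    ecoplate_layout: str | None = None
    ecoplate_thresholds: tuple[float, float, float] | None = None
    network_min_reads: int = 10
    network_k: int = 10
    network_iters: int = 100
    network_alpha: float = 0.05
    network_seed: int = 7
    lake_of_sample: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ecoplate_thresholds" in doc and doc["ecoplate_thresholds"] is not None:
            doc["ecoplate_thresholds"] = tuple(doc["ecoplate_thresholds"])
        return cls(**doc)

    def validate(self) -> None:
        for label, path in [
            ("zotu_table", self.zotu_table),
            ("rule_db", self.rule_db),
            ("regroup", self.regroup),
            ("ecoplate_csv", self.ecoplate_csv),
            ("ecoplate_layout", self.ecoplate_layout),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config {label}: no such file {path!r}")
        if not 0.0 < self.network_alpha < 1.0:
            raise ValueError("network_alpha must be in (0, 1)")
        if self.rarefy_depth < 1:
            raise ValueError("rarefy_depth must be >= 1")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label,
              float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("rarefy")
        table = read_zotu_table(config.zotu_table)
        rarefied = rarefy(table, depth=config.rarefy_depth, seed=config.rarefy_seed)
        path = out / "rarefied.tsv"
        write_zotu_table(rarefied, path)
        outputs["rarefied_table"] = str(path)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise StageError("rarefy", exc) from exc

    try:
        stage("annotate")
        rules = load_rules(config.rule_db)
        ftable = annotate(rarefied, rules)
        path = out / "functions_raw.tsv"
        _write_tsv(ftable.to_dataframe(), path, index_label="function")
        outputs["function_table_raw"] = str(path)
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    try:
        stage("deduplicate")
        regroup, emap = load_regroup(config.regroup)
        dtable = deduplicate(ftable, regroup)
        path = out / "functions_dedup.tsv"
        _write_tsv(dtable.to_dataframe(), path, index_label="function")
        outputs["function_table_dedup"] = str(path)
    except Exception as exc:
        raise StageError("deduplicate", exc) from exc

    try:
        stage("diversity")
        rows = []
        ereads, _ = element_totals(dtable, emap)
        for j, sid in enumerate(dtable.sample_ids):
            prof = diversity_profile(dtable.reads[:, j])
            ratio = cns_ratio({e: float(ereads.loc[e, sid]) for e in ereads.index})
            rows.append(
                {
                    "sample": sid,
                    "richness_S": prof.richness,
                    "shannon_H": round(prof.shannon, 6),
                    "evenness_J": round(prof.evenness, 6),
                    "menhinick": round(prof.menhinick, 6),
                    "chao1": round(prof.chao1, 6),
                    "cns_ratio": ratio.format(),
                }
            )
        path = out / "diversity.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        outputs["diversity_table"] = str(path)
    except Exception as exc:
        raise StageError("diversity", exc) from exc

    try:
        stage("cluster")
        dm = bray_curtis(
            dtable.reads.T.astype(float), labels=list(dtable.sample_ids)
        )
        dendro = hcluster(dm, linkage="complete")
        path = out / "sample_dendrogram.nwk"
        path.write_text(dendro.newick + "\n", encoding="utf-8")
        outputs["sample_dendrogram"] = str(path)
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    if config.ecoplate_csv is not None:
        try:
            stage("ecoplate")
            layout = load_layout(config.ecoplate_layout)
            wells = read_intensity_csv(config.ecoplate_csv)
            if config.ecoplate_thresholds is None:
                from .ecoplate import default_thresholds

                thresholds = default_thresholds(wells, layout)
            else:
                thresholds = config.ecoplate_thresholds
            profile = score_plate(wells, layout, thresholds)
            sub_df = pd.DataFrame(
                {
                    "substrate": list(layout.substrate_ids),
                    "group": [layout.group_of[s] for s in layout.substrate_ids],
                    "mean_score": [
                        round(profile.mean_score[s], 6) for s in layout.substrate_ids
                    ],
                    "used": [profile.used[s] for s in layout.substrate_ids],
                }
            )
            path = out / "ecoplate_substrates.tsv"
            _write_tsv(sub_df, path)
            outputs["ecoplate_substrates"] = str(path)
            indices = clpp_indices(profile)
            idx_df = pd.DataFrame([{k: round(float(v), 6) for k, v in indices.items()}])
            path = out / "ecoplate_indices.tsv"
            _write_tsv(idx_df, path)
            outputs["ecoplate_indices"] = str(path)
        except Exception as exc:
            raise StageError("ecoplate", exc) from exc

    try:
        stage("network")
        result = infer_network(
            rarefied,
            lake_of=config.lake_of_sample or None,
            min_total=config.network_min_reads,
            k=config.network_k,
            n_iter=config.network_iters,
            alpha=config.network_alpha,
            seed=config.network_seed,
        )
        path = out / "network_edges.tsv"
        _write_tsv(edges_to_dataframe(result.edges), path)
        outputs["network_edges"] = str(path)
        path = out / "network_degrees.tsv"
        _write_tsv(summary_to_dataframe(result.summary), path)
        outputs["network_degrees"] = str(path)
    except Exception as exc:
        raise StageError("network", exc) from exc

    manifest = {
        "polarfunc_version": __version__,
        "parameters": {
            "rarefy_depth": config.rarefy_depth,
            "rarefy_seed": config.rarefy_seed,
            "network_min_reads": config.network_min_reads,
            "network_k": config.network_k,
            "network_iters": config.network_iters,
            "network_alpha": config.network_alpha,
            "network_seed": config.network_seed,
        },
        "outputs": outputs,
        "sha256": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in outputs.items()
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
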