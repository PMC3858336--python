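"""Umbrella pipeline: simulate -> epistasis -> genesets -> gsea.

A :class:`PipelineConfig` (usually loaded from YAML) selects stages and
carries each stage's parameter block; :func:`run_pipeline` executes the
enabled stages in dependency order and writes a :class:`RunManifest`
recording the resolved configuration, every seed consumed, input checksums
and the per-stage output files, so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSet, PermutationConfig, permutation_significance
from .epistasis import DEFAULT_DESIGN, EpistasisDesign, run_epistasis_panel
from .genesets import (FilterParams, average_replicates, classify_myb_response,
                       kix_sensitivity, presence_filter)
from .io import (read_counts_csv, read_design_yaml, read_expression, read_gmt,
                 write_cls, write_counts_csv, write_expression, write_gmt)
from .synthetic import (BloodSimConfig, ExprSimConfig, simulate_blood_counts,
                        simulate_expression)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "STAGES"]

logger = logging.getLogger("epistatrio")

STAGES = ("simulate", "epistasis", "genesets", "gsea")


@dataclass
class PipelineConfig:
    """Stage selection plus the parameter block of every enabled stage."""

    stages: tuple[str, ...] = STAGES
    out_dir: str = "epistatrio_out"
    seed: int | None = None
    counts_path: str | None = None          # external counts; else simulated
    expr_gct: str | None = None             # external expression; else simulated
    expr_annot: str | None = None
    gmt_path: str | None = None             # external gene sets; else from genesets stage
    blood_sim: dict = field(default_factory=dict)
    expr_sim: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    phenotypes: list[str] | None = None
    filter_params: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError("unknown stage(s): %s (valid: %s)"
                             % (", ".join(unknown), ", ".join(STAGES)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError("unknown config key(s): %s" % ", ".join(sorted(bad)))
        return cls(**raw)


@dataclass
class RunManifest:
    """What a run did: version, config, seeds, checksums, outputs, failures."""

    version: str
    timestamp: str
    config: dict
    seeds: dict
    input_checksums: dict
    outputs: dict
    failures: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _design_from(config: PipelineConfig) -> EpistasisDesign:
    if not config.design:
        return DEFAULT_DESIGN
    lower = {k.lower(): v for k, v in config.design.items()}
    return EpistasisDesign(**{r: lower[r] for r in ("wt0", "cm1", "cp2", "th3") if r in lower})


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order, writing outputs and a manifest.

    A stage failure halts the stages that depend on its outputs; the
    manifest records the failure and the manifest is still written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds: dict = {"global": config.seed}
    outputs: dict[str, list[str]] = {}
    failures: dict[str, str] = {}
    checksums: dict[str, str] = {}
    for p in (config.counts_path, config.expr_gct, config.expr_annot, config.gmt_path):
        if p and Path(p).exists():
            checksums[str(p)] = _sha256(p)

    counts = None
    expr = None
    gene_sets_for_gsea: dict[str, list[str]] | None = None

    enabled = [s for s in STAGES if s in config.stages]

    if "simulate" in enabled:
        try:
            bcfg = BloodSimConfig(**{**config.blood_sim, "seed": config.seed})
            ecfg = ExprSimConfig(**{**config.expr_sim,
                                    "seed": None if config.seed is None else config.seed + 1})
            seeds["blood_sim"] = bcfg.seed
            seeds["expr_sim"] = ecfg.seed
            counts = simulate_blood_counts(bcfg)
            expr = simulate_expression(ecfg)
            counts_path = out_dir / "counts.csv"
            write_counts_csv(counts, counts_path)
            paths = write_expression(expr, out_dir)
            outputs["simulate"] = [str(counts_path)] + [str(p) for p in paths.values()]
            logger.info("simulate: %d animals, %d genes", len(counts), len(expr.gene_ids))
        except Exception as exc:  # manifest records the failure
            failures["simulate"] = str(exc)

    if "epistasis" in enabled and "simulate" not in failures:
        try:
            if counts is None:
                if not config.counts_path:
                    raise ValueError("epistasis stage needs counts_path or the simulate stage")
                counts = read_counts_csv(config.counts_path)
            table = run_epistasis_panel(counts, design=_design_from(config),
                                        phenotypes=config.phenotypes)
            path = out_dir / "epistasis.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs["epistasis"] = [str(path)]
            logger.info("epistasis: %d phenotype(s)", len(table))
        except Exception as exc:
            failures["epistasis"] = str(exc)

    if "genesets" in enabled and "simulate" not in failures:
        try:
            if expr is None:
                if not (config.expr_gct and config.expr_annot):
                    raise ValueError("genesets stage needs expr_gct+expr_annot or the simulate stage")
                expr = read_expression(config.expr_gct, config.expr_annot)
            params = FilterParams(**config.filter_params)
            means, _ = average_replicates(expr)
            present = presence_filter(means, ["WT:ctrl", "WT:myb"], params.presence_floor)
            act, rep, ratios = classify_myb_response(means, "WT:ctrl", "WT:myb",
                                                     params, genes=present)
            gsr = kix_sensitivity(act, rep, means, "WT:myb", "KIX:myb", params)
            sets = {"myb_activated": list(act), "myb_repressed": list(rep),
                    "kix_sensitive_activated": list(gsr.kix_sensitive_activated),
                    "kix_sensitive_repressed": list(gsr.kix_sensitive_repressed)}
            sets = {k: v for k, v in sets.items() if v}
            gmt_path = out_dir / "myb_genesets.gmt"
            write_gmt(sets, gmt_path)
            ratio_path = out_dir / "myb_ratios.tsv"
            ratios.to_frame().to_csv(ratio_path, sep="\t")
            gene_sets_for_gsea = sets
            outputs["genesets"] = [str(gmt_path), str(ratio_path)]
            logger.info("genesets: %d activated, %d repressed", len(act), len(rep))
        except Exception as exc:
            failures["genesets"] = str(exc)

    if "gsea" in enabled and not ({"simulate", "genesets"} & set(failures)):
        try:
            if expr is None:
                if not (config.expr_gct and config.expr_annot):
                    raise ValueError("gsea stage needs expr_gct+expr_annot or the simulate stage")
                expr = read_expression(config.expr_gct, config.expr_annot)
            if config.gmt_path:
                gene_sets_for_gsea = read_gmt(config.gmt_path)
            if not gene_sets_for_gsea:
                raise ValueError("gsea stage needs gmt_path or the genesets stage")
            pcfg_args = dict(config.permutation)
            pcfg_args.setdefault("seed", None if config.seed is None else config.seed + 2)
            pcfg = PermutationConfig(**pcfg_args)
            seeds["gsea"] = pcfg.seed
            # compare genotypes within the c-Myb-treated samples
            myb = expr.samples[expr.samples["treatment"] == "myb"]
            classes = myb["genotype"]
            sets = [GeneSet(name=k, members=frozenset(v))
                    for k, v in gene_sets_for_gsea.items()]
            results = permutation_significance(
                expr, classes, sets, class_a="WT", class_b="KIX", config=pcfg)
            table = pd.DataFrame([r.to_dict() for r in results])
            path = out_dir / "gsea.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            cls_path = out_dir / "gsea_classes.cls"
            write_cls([classes[s] for s in expr.values.columns if s in classes.index],
                      cls_path)
            outputs["gsea"] = [str(path), str(cls_path)]
            logger.info("gsea: %d set(s) analysed", len(results))
        except Exception as exc:
            failures["gsea"] = str(exc)

    manifest = RunManifest(
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=dataclasses.asdict(config),
        seeds=seeds,
        input_checksums=checksums,
        outputs=outputs,
        failures=failures,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
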