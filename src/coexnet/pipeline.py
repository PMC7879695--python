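"""End-to-end pipeline driver.

One YAML configuration drives the full chain
simulate|ingest -> preprocess -> diffexpr -> coexpression ->
regulation_network -> enrichment. Every stage writes plain TSV (plus a SIF
edge list) into the output directory through a temporary ``.partial`` file
that is renamed only on success, and the run ends with a JSON manifest
recording the config snapshot, per-stage file digests and counts. The
manifest deliberately contains no timestamps or absolute paths, so two runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from . import __version__
from .coexpression import coexpression_screen, write_pairs_table
from .diffexpr import (
    de_counts,
    differential_expression,
    write_de_table,
)
from .enrichment import ora, write_enrichment_table
from .errors import ConfigError, PipelineStageError
from .io_formats import (
    read_annotation,
    read_expression,
    read_gmt,
    write_expression,
    write_pairs_sif,
)
from .preprocess import log2_transform, quantile_normalize
from .regulation_network import (
    build_trans_network,
    classify_cis_trans,
    mnc_scores,
    regulation_counts,
    top_k_pairs,
    write_regulation_table,
    write_scores_table,
)
from .synthetic_data import CorrPairSpec, SimConfig, generate_dataset, write_dataset

logger = logging.getLogger("coexnet")

STAGES = ("data", "preprocess", "diffexpr", "coexpression", "regulation", "enrichment")

DEFAULTS: dict[str, dict[str, Any]] = {
    "preprocess": {"log2_offset": 0.0},
    "diffexpr": {
        "case": "tibetan",
        "control": "han",
        "fc_log2": 1.0,
        "alpha": 0.05,
        "use_adjusted": False,
        "welch": False,
    },
    "coexpression": {"r_threshold": 0.7, "alpha": 0.05, "sample_scope": "all"},
    "regulation": {
        "window_bp": 300_000,
        "top_k": 100,
        "neighborhood": "open",
    },
    "enrichment": {"top": 30},
}


@dataclass
class StageRecord:
    name: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    counts: dict[str, int]


@dataclass
class RunManifest:
    version: str
    seed: int | None
    config: dict
    stages: list[StageRecord] = field(default_factory=list)

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _digests(paths: dict[str, Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(paths.values())}


def _write_atomic(path: Path, writer: Callable[[Path], None]) -> Path:
    """Write through a .partial temporary; only successful stages leave a
    final file behind."""
    tmp = path.with_name(path.name + ".partial")
    writer(tmp)
    tmp.replace(path)
    return path


def _merged(config: dict, section: str) -> dict[str, Any]:
    merged = dict(DEFAULTS.get(section, {}))
    user = config.get(section, {}) or {}
    unknown = set(user) - set(merged)
    if unknown:
        raise ConfigError(f"unknown keys in '{section}' block: {sorted(unknown)}")
    merged.update(user)
    return merged


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    if ("simulate" in config) == ("input" in config):
        raise ConfigError("config needs exactly one of 'simulate' or 'input'")
    if "input" in config:
        inp = config["input"] or {}
        for key in ("matrix", "groups", "annotation", "gmt"):
            if key not in inp:
                raise ConfigError(f"config key 'input.{key}' is missing")
    return config


def _sim_config(block: dict, seed: int | None) -> SimConfig:
    block = dict(block or {})
    pairs = [
        spec if isinstance(spec, CorrPairSpec) else CorrPairSpec(**spec)
        for spec in block.pop("corr_pairs", [])
    ]
    if "baseline_log2_range" in block:
        block["baseline_log2_range"] = tuple(block["baseline_log2_range"])
    if seed is not None:
        block.setdefault("seed", seed)
    try:
        return SimConfig(corr_pairs=pairs, **block)
    except TypeError as exc:
        raise ConfigError(f"bad simulate block: {exc}") from exc


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the full chain; returns (and writes) the run manifest."""
    config = load_config(config)
    seed = config.get("seed")
    if out_dir is None:
        out_dir = config.get("out_dir")
    if out_dir is None:
        raise ConfigError("config key 'out_dir' is missing")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest_config = {k: v for k, v in config.items() if k != "out_dir"}
    manifest = RunManifest(version=__version__, seed=seed, config=manifest_config)

    stage = "data"
    try:
        if "simulate" in config:
            cfg = _sim_config(config["simulate"], seed)
            matrix, annotation, gene_sets, _truth = generate_dataset(cfg)
            data_paths = write_dataset(matrix, annotation, gene_sets, _truth, out_dir)
            inputs: dict[str, str] = {}
        else:
            inp = config["input"]
            data_paths = {k: Path(v) for k, v in inp.items()}
            matrix = read_expression(data_paths["matrix"], data_paths["groups"])
            annotation = read_annotation(data_paths["annotation"])
            gene_sets = read_gmt(data_paths["gmt"])
            inputs = _digests(data_paths)
        manifest.stages.append(
            StageRecord(
                stage,
                inputs=inputs,
                outputs=_digests(data_paths) if "simulate" in config else {},
                counts={
                    "probes": matrix.n_probes,
                    "samples": matrix.n_samples,
                    "gene_sets": len(gene_sets),
                },
            )
        )
        logger.info("data: %d probes x %d samples", matrix.n_probes, matrix.n_samples)

        stage = "preprocess"
        opts = _merged(config, "preprocess")
        normalized, report = quantile_normalize(matrix)
        log2m = log2_transform(normalized, offset=float(opts["log2_offset"]))
        norm_path = _write_atomic(
            out_dir / "norm_log2.tsv", lambda p: write_expression(log2m, p)
        )
        manifest.stages.append(
            StageRecord(
                stage,
                inputs={},
                outputs=_digests({"norm": norm_path}),
                counts={"probes": report.n_probes, "samples": report.n_samples},
            )
        )
        logger.info("preprocess: normalized %d probes", report.n_probes)

        stage = "diffexpr"
        opts = _merged(config, "diffexpr")
        de = differential_expression(
            log2m,
            annotation,
            case_label=opts["case"],
            control_label=opts["control"],
            fc_log2=float(opts["fc_log2"]),
            alpha=float(opts["alpha"]),
            use_adjusted=bool(opts["use_adjusted"]),
            equal_var=not bool(opts["welch"]),
        )
        de_path = _write_atomic(out_dir / "de.tsv", lambda p: write_de_table(de, p))
        counts = de_counts(de)
        manifest.stages.append(
            StageRecord(stage, inputs={}, outputs=_digests({"de": de_path}), counts=counts)
        )
        logger.info("diffexpr: %s", counts)

        stage = "coexpression"
        opts = _merged(config, "coexpression")
        pairs, grid = coexpression_screen(
            log2m,
            de,
            sample_scope=opts["sample_scope"],
            case_label=_merged(config, "diffexpr")["case"],
            r_threshold=float(opts["r_threshold"]),
            alpha=float(opts["alpha"]),
        )
        pairs_path = _write_atomic(
            out_dir / "coexpr_pairs.tsv", lambda p: write_pairs_table(pairs, p)
        )
        grid_path = _write_atomic(
            out_dir / "coexpr_grid.tsv",
            lambda p: grid.to_csv(p, sep="\t"),
        )
        manifest.stages.append(
            StageRecord(
                stage,
                inputs={},
                outputs=_digests({"pairs": pairs_path, "grid": grid_path}),
                counts={"pairs_retained": len(pairs)},
            )
        )
        logger.info("coexpression: %d pairs retained", len(pairs))

        stage = "regulation"
        opts = _merged(config, "regulation")
        rpairs = classify_cis_trans(pairs, annotation, window_bp=int(opts["window_bp"]))
        reg_counts = regulation_counts(rpairs)
        graph = build_trans_network(rpairs)
        scores = mnc_scores(graph, neighborhood=opts["neighborhood"])
        top = top_k_pairs(rpairs, k=int(opts["top_k"]), class_filter="trans")
        reg_path = _write_atomic(
            out_dir / "regulation_pairs.tsv", lambda p: write_regulation_table(rpairs, p)
        )
        scores_path = _write_atomic(
            out_dir / "node_scores.tsv", lambda p: write_scores_table(scores, p)
        )
        top_path = _write_atomic(
            out_dir / "trans_top.tsv", lambda p: write_regulation_table(top, p)
        )
        sif_path = _write_atomic(
            out_dir / "trans_network.sif",
            lambda p: write_pairs_sif(
                [rp for rp in rpairs if rp.regulation == "trans"], p
            ),
        )
        manifest.stages.append(
            StageRecord(
                stage,
                inputs={},
                outputs=_digests(
                    {
                        "pairs": reg_path,
                        "scores": scores_path,
                        "top": top_path,
                        "sif": sif_path,
                    }
                ),
                counts={
                    **reg_counts,
                    "pairs_retained": len(rpairs),
                    "top_k": len(top),
                    "network_nodes": graph.number_of_nodes(),
                    "network_edges": graph.number_of_edges(),
                },
            )
        )
        logger.info("regulation: %s", reg_counts)

        stage = "enrichment"
        opts = _merged(config, "enrichment")
        universe = annotation.symbols_of_biotype("mRNA")
        de_mrna_symbols = [
            r.gene_symbol for r in de if r.status != "ns" and r.biotype == "mRNA"
        ]
        enr = ora(de_mrna_symbols, gene_sets, universe, top=None)
        top_n = opts["top"]
        enr_path = _write_atomic(
            out_dir / "enrichment.tsv",
            lambda p: write_enrichment_table(
                enr if top_n is None else enr[: int(top_n)], p
            ),
        )
        manifest.stages.append(
            StageRecord(
                stage,
                inputs={},
                outputs=_digests({"enrichment": enr_path}),
                counts={"sets_tested": len(enr), "de_mrna_symbols": len(set(de_mrna_symbols))},
            )
        )
        logger.info("enrichment: %d sets tested", len(enr))
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc

    _write_atomic(out_dir / "manifest.json", manifest.save)
    return manifest


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
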