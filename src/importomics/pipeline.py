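"""End-to-end runs: config parsing, stage orchestration, manifest emission.

A run is described by one YAML config file; every parameter that reaches a
module surface is either present in the config or a documented default, and
the full resolved parameter set is written into the run manifest so a rerun
with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from importomics import enrichment as enr
from importomics.importome import (
    call_fixed_fold,
    call_importome,
    identify_new_candidates,
    reference_overlap_summary,
    volcano_table,
)
from importomics.mia_motif import predict_mia_substrates, predictions_to_rows
from importomics.quant_io import (
    ColumnMap,
    ReferenceSet,
    Replicate,
    ReplicateDesign,
    read_fasta,
    read_quant_table,
    read_reference_set,
    write_results_table,
)
from importomics.replicate_stats import FilterPolicy, apply_identification_filter
from importomics.synthetic import (
    SyntheticQuantConfig,
    simulate_proteome_sequences,
    simulate_quant_dataset,
    write_dataset,
    write_fasta,
)
from importomics.threshold_f1 import curve_to_rows, scan_f1

log = logging.getLogger(__name__)

_TOP_LEVEL_KEYS = {
    "experiment_name",
    "mode",
    "alpha",
    "fold",
    "grid_step",
    "start_rule",
    "candidates",
    "mass_cutoff_da",
    "min_motifs",
    "count_mode",
    "inputs",
    "design",
    "columns",
    "filter",
    "simulate",
    "seed",
}
_INPUT_KEYS = {
    "quant_table",
    "positive_reference",
    "negative_reference",
    "fasta",
    "annotations",
    "ancestors",
    "slim_terms",
    "hit_list",
    "predicted_list",
    "background_list",
}


class ConfigError(ValueError):
    """A run configuration is malformed; the message names the offending key."""


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated run configuration (one experiment, one mode)."""

    experiment_name: str = "experiment"
    mode: str = "f1_threshold"  # or "fixed_fold"
    alpha: float = 0.05
    fold: float | None = None
    grid_step: float = 0.01
    start_rule: str = "literal"
    candidates: str = "grid"
    mass_cutoff_da: float = 50_000.0
    min_motifs: int = 2
    count_mode: str = "same-type"
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    design: ReplicateDesign | None = None
    columns: ColumnMap | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    simulate: SyntheticQuantConfig | None = None

    @staticmethod
    def from_mapping(raw: Mapping[str, Any], base_dir: Path | None = None) -> "RunConfig":
        _check_keys(raw, _TOP_LEVEL_KEYS, "config")
        inputs = dict(raw.get("inputs") or {})
        _check_keys(inputs, _INPUT_KEYS, "inputs")
        if base_dir is not None:
            inputs = {
                k: str((base_dir / v).resolve()) if not Path(v).is_absolute() else v
                for k, v in inputs.items()
            }

        design = None
        if "design" in raw:
            spec = raw["design"]
            _check_keys(spec, {"labeling_scheme", "replicates"}, "design")
            design = ReplicateDesign(
                replicates=tuple(
                    Replicate(replicate_id=r["id"], induced_channel=r["induced_channel"])
                    for r in spec["replicates"]
                ),
                labeling_scheme=spec.get("labeling_scheme", "silac"),
            )

        columns = None
        if "columns" in raw:
            spec = dict(raw["columns"])
            _check_keys(
                spec,
                {"protein_id", "description", "n_peptides", "n_unique_peptides",
                 "ratios", "evidence"},
                "columns",
            )
            columns = ColumnMap(
                protein_id=spec.get("protein_id", "protein_id"),
                description=spec.get("description", "description"),
                n_peptides=spec.get("n_peptides", "n_peptides"),
                n_unique_peptides=spec.get("n_unique_peptides", "n_unique_peptides"),
                ratio_columns=dict(spec.get("ratios", {})),
                evidence_columns=dict(spec.get("evidence", {})),
            )

        policy = FilterPolicy()
        if "filter" in raw:
            spec = dict(raw["filter"])
            allowed = {f.name for f in fields(FilterPolicy)}
            _check_keys(spec, allowed, "filter")
            policy = FilterPolicy(**spec)

        sim = None
        if "simulate" in raw:
            spec = dict(raw["simulate"])
            allowed = {f.name for f in fields(SyntheticQuantConfig)}
            _check_keys(spec, allowed, "simulate")
            if "label_switch_replicates" in spec:
                spec["label_switch_replicates"] = tuple(spec["label_switch_replicates"])
            sim = SyntheticQuantConfig(**spec)

        mode = raw.get("mode", "f1_threshold")
        if mode not in ("f1_threshold", "fixed_fold"):
            raise ConfigError(f"unknown mode {mode!r}")
        if mode == "fixed_fold" and raw.get("fold") is None:
            raise ConfigError("mode fixed_fold requires the 'fold' key")

        return RunConfig(
            experiment_name=str(raw.get("experiment_name", "experiment")),
            mode=mode,
            alpha=float(raw.get("alpha", 0.05)),
            fold=None if raw.get("fold") is None else float(raw["fold"]),
            grid_step=float(raw.get("grid_step", 0.01)),
            start_rule=str(raw.get("start_rule", "literal")),
            candidates=str(raw.get("candidates", "grid")),
            mass_cutoff_da=float(raw.get("mass_cutoff_da", 50_000.0)),
            min_motifs=int(raw.get("min_motifs", 2)),
            count_mode=str(raw.get("count_mode", "same-type")),
            seed=int(raw.get("seed", 0)),
            inputs=inputs,
            design=design,
            columns=columns,
            filter_policy=policy,
            simulate=sim,
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(raw, base_dir=path.parent)


def _require_input(config: RunConfig, key: str) -> Path:
    try:
        return Path(config.inputs[key])
    except KeyError:
        raise ConfigError(f"config inputs is missing required key {key!r}") from None


def _manifest(config: RunConfig, stage: str, **extra: Any) -> dict[str, Any]:
    manifest: dict[str, Any] = {
        "experiment_name": config.experiment_name,
        "stage": stage,
        "mode": config.mode,
        "parameters": {
            "alpha": config.alpha,
            "fold": config.fold,
            "grid_step": config.grid_step,
            "start_rule": config.start_rule,
            "candidates": config.candidates,
            "mass_cutoff_da": config.mass_cutoff_da,
            "min_motifs": config.min_motifs,
            "count_mode": config.count_mode,
            "seed": config.seed,
            "filter": asdict(config.filter_policy),
        },
        "inputs": dict(sorted(config.inputs.items())),
    }
    manifest.update(extra)
    return manifest


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


@dataclass
class ImportomeResult:
    stats: list
    scan: Any
    calls: list
    new_candidates: set[str]
    overlap: Any
    volcano: pd.DataFrame
    manifest: dict[str, Any]


def run_importome(config: RunConfig, outdir: str | Path) -> ImportomeResult:
    """Full importome analysis: read, filter, threshold, call, export."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.design is None:
        raise ConfigError("importome run requires a replicate design")
    started = time.perf_counter()

    records = read_quant_table(
        _require_input(config, "quant_table"), config.design, config.columns
    )
    stats = apply_identification_filter(records, config.filter_policy)
    positive = read_reference_set(
        _require_input(config, "positive_reference"), "positive_reference"
    )
    negative = read_reference_set(
        _require_input(config, "negative_reference"), "negative_reference"
    )

    scan = None
    if config.mode == "f1_threshold":
        scan = scan_f1(
            stats,
            positive,
            negative,
            grid_step=config.grid_step,
            start_rule=config.start_rule,  # type: ignore[arg-type]
            candidates=config.candidates,  # type: ignore[arg-type]
        )
        calls = call_importome(stats, scan.chosen_threshold, alpha=config.alpha)
        write_results_table(
            pd.DataFrame(curve_to_rows(scan.curve_positive_ref)),
            outdir / "f1_curve_positive.tsv",
        )
        write_results_table(
            pd.DataFrame(curve_to_rows(scan.curve_negative_ref)),
            outdir / "f1_curve_negative.tsv",
        )
    else:
        assert config.fold is not None
        calls = call_fixed_fold(stats, config.fold, alpha=config.alpha)

    new_candidates = identify_new_candidates(calls, positive)
    overlap = reference_overlap_summary(calls, positive, negative)
    volcano = volcano_table(stats, calls, positive, negative)

    stats_rows = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in stats],
            "n_quantified": [s.n_quantified for s in stats],
            "mean_log2": [s.mean_log2 for s in stats],
            "p_value": [s.p_value for s in stats],
            "passed_filter": [s.passed_filter for s in stats],
        }
    )
    write_results_table(stats_rows, outdir / "protein_statistics.tsv")
    write_results_table(calls, outdir / "importome_calls.tsv")
    (outdir / "new_candidates.txt").write_text(
        "\n".join(sorted(new_candidates)) + ("\n" if new_candidates else "")
    )
    write_results_table(volcano, outdir / "volcano.tsv")

    n_imported = sum(1 for c in calls if c.call == "imported")
    manifest = _manifest(
        config,
        stage="importome",
        counts={
            "n_records": len(records),
            "n_passed_filter": int(stats_rows["passed_filter"].sum()),
            "n_imported": n_imported,
            "n_new_candidates": len(new_candidates),
        },
        thresholds=(
            None
            if scan is None
            else {"t1": scan.t1, "t2": scan.t2, "chosen": scan.chosen_threshold}
        ),
        overlap=asdict(overlap),
    )
    _write_manifest(manifest, outdir)
    log.info(
        "importome stage finished in %.2fs (%d imported)",
        time.perf_counter() - started,
        n_imported,
    )
    return ImportomeResult(stats, scan, calls, new_candidates, overlap, volcano, manifest)


def run_mia_scan(config: RunConfig, outdir: str | Path):
    """Motif-scan stage: FASTA in, substrate prediction table out."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = read_fasta(_require_input(config, "fasta"))
    predictions = predict_mia_substrates(
        sequences,
        mass_cutoff_da=config.mass_cutoff_da,
        min_motifs=config.min_motifs,
        count_mode=config.count_mode,  # type: ignore[arg-type]
    )
    write_results_table(
        pd.DataFrame(predictions_to_rows(predictions)), outdir / "mia_predictions.tsv"
    )
    n_predicted = sum(p.is_predicted_substrate for p in predictions)
    _write_manifest(
        _manifest(
            config,
            stage="mia_scan",
            counts={"n_sequences": len(sequences), "n_predicted": n_predicted},
        ),
        outdir,
    )
    return predictions


def run_enrichment(config: RunConfig, outdir: str | Path) -> list[enr.EnrichmentRecord]:
    """Enrichment stage: substrate and/or term overrepresentation tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hit_set = set(
        read_reference_set(_require_input(config, "hit_list"), "hit_list").ids
    )
    background = set(
        read_reference_set(_require_input(config, "background_list"), "background").ids
    )
    results: list[enr.EnrichmentRecord] = []
    if "predicted_list" in config.inputs:
        predicted = set(
            read_reference_set(config.inputs["predicted_list"], "predicted").ids
        )
        results.append(enr.test_substrate_enrichment(hit_set, predicted, background))
    if "annotations" in config.inputs:
        assignments = enr.read_annotation_map(config.inputs["annotations"])
        if "ancestors" in config.inputs and "slim_terms" in config.inputs:
            assignments = enr.reduce_to_slim(
                assignments,
                enr.read_ancestor_map(config.inputs["ancestors"]),
                enr.read_term_list(config.inputs["slim_terms"]),
            )
        results.extend(
            enr.term_enrichment(hit_set, assignments, background, alpha=config.alpha)
        )
    write_results_table(results, outdir / "enrichment.tsv")
    _write_manifest(
        _manifest(
            config,
            stage="enrichment",
            counts={
                "n_hits": len(hit_set),
                "n_background": len(background),
                "n_tests": len(results),
                "n_significant": sum(r.p_adjusted < config.alpha for r in results),
            },
        ),
        outdir,
    )
    return results


def run_simulate(config: RunConfig, outdir: str | Path):
    """Generate a fixture bundle plus a ready-to-run importome config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = config.simulate or SyntheticQuantConfig(seed=config.seed)
    dataset = simulate_quant_dataset(sim_config)
    paths = write_dataset(dataset, outdir)

    sequences, seq_truth = simulate_proteome_sequences(
        n_proteins=200, substrate_fraction=0.25, seed=sim_config.seed
    )
    write_fasta(sequences, outdir / "proteome.fasta")

    chained = {
        "experiment_name": config.experiment_name,
        "mode": "f1_threshold",
        "alpha": config.alpha,
        "inputs": {
            "quant_table": paths["quant_table"].name,
            "positive_reference": paths["positive_reference"].name,
            "negative_reference": paths["negative_reference"].name,
            "fasta": "proteome.fasta",
        },
        "design": {
            "labeling_scheme": dataset.design.labeling_scheme,
            "replicates": [
                {"id": r.replicate_id, "induced_channel": r.induced_channel}
                for r in dataset.design.replicates
            ],
        },
        "filter": asdict(config.filter_policy),
    }
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(chained, sort_keys=False))
    _write_manifest(
        _manifest(
            config,
            stage="simulate",
            counts={
                "n_records": len(dataset.records),
                "n_sequences": len(sequences),
            },
        ),
        outdir,
    )
    return dataset
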