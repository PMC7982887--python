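"""Command-line entry points: filter, fit, dsep, simulate, recover, summarize.

Thin wrappers over the library. Structured logging goes to stderr; results
only to files. Option precedence: CLI flag > config file > default. Every
run writes a manifest (config hash, seed, package version) next to its
outputs so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import yaml

from . import __version__
from .lineage_data import (filter_lineages, read_lineage_table, summarize,
                           write_lineage_table)
from .path_sem import PathConfig, run_path_analysis
from .phylo_cov import prune_to_dataset, read_newick, read_tip_mapping
from .synthetic_data import (SimulationParams, recovery_study,
                             simulate_dataset)

logger = logging.getLogger("ploidypath")


def _setup_logging(verbose: bool) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def _load_config(path: str | None) -> dict:
    if not path:
        return {}
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise click.ClickException("config file must hold a mapping")
    return data


def _write_manifest(out_dir: Path, command: str, options: dict) -> None:
    payload = json.dumps(options, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "options": options,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "ploidypath_version": __version__,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8")


def _path_config(cfg: dict, method: str | None) -> PathConfig:
    fields = {f.name for f in dataclasses.fields(PathConfig)}
    kw = {k: v for k, v in cfg.items() if k in fields}
    if method:
        kw["method"] = method.upper()
    return PathConfig(**kw)


@click.group()
@click.option("--verbose", is_flag=True, help="Debug logging to stderr.")
def main(verbose: bool) -> None:
    """Phylogenetic path analysis of island polyploidy."""
    _setup_logging(verbose)


@main.command("filter")
@click.option("--lineages", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_filter(lineages: str, out: str) -> None:
    """Apply the inclusion criteria; write the filtered CSV + report."""
    records = read_lineage_table(lineages)
    dataset = filter_lineages(records)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_lineage_table(dataset.records, out_dir / "filtered.csv")
    (out_dir / "exclusion_report.json").write_text(
        json.dumps(dataset.exclusion_report, indent=2), encoding="utf-8")
    if not dataset.records:
        logger.warning("no lineages passed the inclusion criteria")
    _write_manifest(out_dir, "filter", {"lineages": lineages})
    click.echo(f"retained {len(dataset)} of {len(records)} lineages", err=True)


@main.command("summarize")
@click.option("--lineages", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_summarize(lineages: str, out: str) -> None:
    """Per-archipelago summary table of the filtered dataset."""
    dataset = filter_lineages(read_lineage_table(lineages))
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    summarize(dataset).to_csv(out_dir / "summary.csv")
    _write_manifest(out_dir, "summarize", {"lineages": lineages})


def _fit_common(lineages, tree, tip_map, config, method):
    dataset = filter_lineages(read_lineage_table(lineages))
    mapping = read_tip_mapping(tip_map) if tip_map else None
    pruned = prune_to_dataset(read_newick(tree), dataset, tip_map=mapping)
    cfg = _path_config(_load_config(config), method)
    return run_path_analysis(dataset, tree=pruned, config=cfg), cfg


@main.command("fit")
@click.option("--lineages", required=True, type=click.Path(exists=True))
@click.option("--tree", required=True, type=click.Path(exists=True))
@click.option("--tip-map", type=click.Path(exists=True))
@click.option("--config", type=click.Path(exists=True))
@click.option("--method", type=click.Choice(["ml", "reml"]))
@click.option("--out", required=True, type=click.Path())
def cli_fit(lineages, tree, tip_map, config, method, out) -> None:
    """Full path analysis: JSON report + CSV path table."""
    result, cfg = _fit_common(lineages, tree, tip_map, config, method)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.to_json(out_dir / "path_analysis.json")
    result.path_table.to_csv(out_dir / "path_table.csv", index=False)
    result.island_effects.to_csv(out_dir / "island_effects.csv", index=False)
    _write_manifest(out_dir, "fit", {
        "lineages": lineages, "tree": tree, "tip_map": tip_map,
        "config": dataclasses.asdict(cfg)})


@main.command("dsep")
@click.option("--lineages", required=True, type=click.Path(exists=True))
@click.option("--tree", required=True, type=click.Path(exists=True))
@click.option("--tip-map", type=click.Path(exists=True))
@click.option("--config", type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_dsep(lineages, tree, tip_map, config, out) -> None:
    """Directed-separation claims and Fisher's C only."""
    result, cfg = _fit_common(lineages, tree, tip_map, config, None)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "dsep.json").write_text(json.dumps(
        result.to_dict()["dsep"], indent=2), encoding="utf-8")
    _write_manifest(out_dir, "dsep", {
        "lineages": lineages, "tree": tree,
        "config": dataclasses.asdict(cfg)})


@main.command("simulate")
@click.option("--config", type=click.Path(exists=True))
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_simulate(config, seed, out) -> None:
    """Simulate one dataset: lineage CSV + Newick tree + truth JSON."""
    cfg = _load_config(config)
    fields = {f.name for f in dataclasses.fields(SimulationParams)}
    params = SimulationParams(
        **{k: v for k, v in cfg.items() if k in fields}, seed=seed)
    dataset, tree, truth = simulate_dataset(params)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_lineage_table(dataset.records, out_dir / "lineages.csv")
    tree.write(path=str(out_dir / "tree.nwk"), schema="newick")
    (out_dir / "truth.json").write_text(
        json.dumps(truth, indent=2), encoding="utf-8")
    _write_manifest(out_dir, "simulate",
                    {"seed": seed, "params": dataclasses.asdict(params)})


@main.command("recover")
@click.option("--config", type=click.Path(exists=True))
@click.option("--n-reps", type=int, default=100, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_recover(config, n_reps, seed, out) -> None:
    """Parameter-recovery study; writes a per-coefficient CSV."""
    if n_reps < 1:
        raise click.BadParameter("n-reps must be >= 1")
    cfg = _load_config(config)
    fields = {f.name for f in dataclasses.fields(SimulationParams)}
    params = SimulationParams(**{k: v for k, v in cfg.items()
                                 if k in fields})
    report = recovery_study(params, n_reps=n_reps, seed=seed)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(out_dir / "recovery.csv", index=False)
    (out_dir / "recovery_meta.json").write_text(json.dumps({
        "fisher_rejection_rate": report.attrs["fisher_rejection_rate"],
        "n_failures": report.attrs["n_failures"],
        "n_ok": report.attrs["n_ok"],
    }, indent=2), encoding="utf-8")
    _write_manifest(out_dir, "recover",
                    {"seed": seed, "n_reps": n_reps,
                     "params": dataclasses.asdict(params)})


if __name__ == "__main__":
    main()
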