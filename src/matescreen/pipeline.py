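"""End-to-end orchestration: simulate -> extract -> score -> evaluate.

Every stage writes plain-text artifacts (TSV/JSON) into an output
directory, plus a manifest recording the seed and parameters, so an entire
run is reproducible byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .enrichment_stats import (
    call_enrichment,
    call_enrichment_grouped,
    group_library_on_library,
    normalize_to_control,
)
from .performance_eval import GroundTruthTable, plot_roc, roc_curve, screen_performance
from .read_extraction import CountTable, build_count_table, read_manifest
from .screen_model import AmpliconScheme, ScreenDesign, load_strain_registry
from .synthetic_screen import FixtureBundle, generate_screen_fixture


class ConfigError(ValueError):
    """Bad configuration: unknown preset, missing file, malformed design."""


class DataError(ValueError):
    """Data that cannot be analyzed: no assignable reads, absent control."""


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_simulate(
    preset: str,
    seed: int,
    out_dir: str | Path,
    read_depth: int | None = None,
    replicates: int | None = None,
    per_base_error: float | None = None,
) -> FixtureBundle:
    """Generate a simulated screen bundle and its manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    try:
        bundle = generate_screen_fixture(
            preset, seed, out_dir,
            read_depth=read_depth, replicates=replicates, per_base_error=per_base_error,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    cfg = next(iter(bundle.configs.values()))
    _write_json(
        {
            "stage": "simulate",
            "preset": preset,
            "seed": seed,
            "read_depth": cfg.read_depth,
            "replicates": cfg.replicates,
            "per_base_error": cfg.per_base_error,
            "scheme_mode": bundle.scheme.mode,
            "version": __version__,
        },
        out_dir / "manifest.json",
    )
    return bundle


def run_extract(
    manifest: str | Path | pd.DataFrame,
    registry_path: str | Path,
    scheme_mode: str,
    out_dir: str | Path,
    min_mean_q: float = 20.0,
    hamming1: bool = False,
) -> CountTable:
    """Extract and count one screen's FASTQ files into ``out_dir``/counts.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        mdf = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
        registry = load_strain_registry(registry_path)
        scheme = AmpliconScheme.for_mode(scheme_mode)
    except (FileNotFoundError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    fastq_by_rep = dict(zip(mdf["replicate"], mdf["fastq"]))
    arms = dict(zip(mdf["replicate"], mdf["arm"]))
    table = build_count_table(
        fastq_by_rep, scheme, registry,
        replicate_arms=arms, min_mean_q=min_mean_q, hamming1=hamming1,
    )
    table.save(out_dir)
    stats = {
        "assigned": {r: int(n) for r, n in table.counts.sum(axis=0).items()},
        "unassigned": {
            status: {r: int(n) for r, n in row.items()}
            for status, row in table.unassigned.iterrows()
        },
        "total": {r: int(n) for r, n in table.total_reads().items()},
    }
    _write_json(stats, out_dir / "extraction_stats.json")
    return table


def run_score(
    table: CountTable,
    design: ScreenDesign,
    registry_path: str | Path,
    scheme_mode: str,
    out_dir: str | Path,
    pseudocount: float = 0.0,
    tails: str = "two",
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Normalize to the internal control and write enrichment calls."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if int(table.counts.to_numpy().sum()) == 0:
        raise DataError("no assignable reads in any replicate")
    try:
        if scheme_mode == "barcode_pair":
            registry = load_strain_registry(registry_path)
            ratios = group_library_on_library(
                table, registry, design.internal_control, pseudocount
            )
            enrichment = call_enrichment_grouped(ratios, design, tails=tails, welch=welch, bh=bh)
        else:
            ratios = normalize_to_control(table, design.internal_control, pseudocount)
            enrichment = call_enrichment(
                ratios, table.replicate_arms, design, tails=tails, welch=welch, bh=bh
            )
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    ratios.to_csv(out_dir / "normalized_ratios.tsv", sep="\t")
    enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t")
    return enrichment


def run_evaluate(
    enrichment: pd.DataFrame,
    truth: GroundTruthTable,
    out_dir: str | Path,
    internal_control: str | None = None,
    roc_plot: str | Path | None = None,
) -> dict:
    """Score enrichment calls against ground truth; write performance.json.

    The internal control is excluded from the comparison (its ratio is 1 by
    construction and it has no biological label of interest).  ROC scores
    are the mean experimental-arm normalized ratios, restricted to labeled
    variants.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = enrichment.drop(index=internal_control, errors="ignore")
    calls = set(df.index[df["call"]])
    try:
        report = screen_performance(calls, truth)
        scores = {
            str(v): float(df.loc[v, "mean_experimental"])
            for v in df.index
            if v in truth.variants
        }
        labels = {truth.table.loc[v, "cognate"] for v in scores}
        if len(labels) == 2:
            report.roc_points, report.auc = roc_curve(scores, truth)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    report.save(out_dir / "performance.json")
    if roc_plot is not None and report.roc_points is not None:
        plot_roc(report.roc_points, roc_plot, auc=report.auc)
    return report.to_dict()


@dataclass
class RunResult:
    bundle: FixtureBundle
    table: CountTable
    enrichment: pd.DataFrame
    performance: dict | None


def run_all(
    preset: str,
    seed: int,
    out_dir: str | Path,
    read_depth: int | None = None,
    replicates: int | None = None,
    per_base_error: float | None = None,
    min_mean_q: float = 20.0,
    pseudocount: float = 0.0,
) -> RunResult:
    """Simulate a preset screen and push it through the whole pipeline."""
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    bundle = run_simulate(
        preset, seed, sim_dir,
        read_depth=read_depth, replicates=replicates, per_base_error=per_base_error,
    )
    manifest = read_manifest(bundle.manifest_path)
    table = run_extract(
        manifest, bundle.registry_path, bundle.scheme.mode, out_dir, min_mean_q=min_mean_q
    )
    enrichment = run_score(
        table, bundle.design, bundle.registry_path, bundle.scheme.mode, out_dir,
        pseudocount=pseudocount,
    )
    truth = GroundTruthTable.from_tsv(
        bundle.ground_truth_path, threshold=bundle.design.activation_threshold
    )
    performance = run_evaluate(
        enrichment, truth, out_dir, internal_control=bundle.design.internal_control
    )
    _write_json(
        {
            "stage": "run_all",
            "preset": preset,
            "seed": seed,
            "min_mean_q": min_mean_q,
            "pseudocount": pseudocount,
            "version": __version__,
        },
        out_dir / "manifest.json",
    )
    return RunResult(bundle=bundle, table=table, enrichment=enrichment, performance=performance)


__all__ = [
    "ConfigError",
    "DataError",
    "RunResult",
    "run_all",
    "run_evaluate",
    "run_extract",
    "run_score",
    "run_simulate",
]
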