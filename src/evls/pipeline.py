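"""End-to-end orchestration: simulate/load -> filter -> combine -> metrics
-> diversity -> benchmark, driven by a YAML/JSON configuration.

Every report carries provenance (config hash, seed, package version, filter
decisions) because the scientific conclusions depend on exactly which
conformers and binders were dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .benchmark import benchmark_report
from .combine import combine
from .data_model import (
    EnsembleScreen,
    read_ligand_annotations,
    read_score_table,
    write_ligand_annotations,
    write_ranked_list,
    write_score_table,
)
from .diversity import format_chemotype_set, top_fraction_chemotypes
from .filtering import apply_library_filter, cognate_ligand_filter, drop_all_positive_runs
from .metrics import DEFAULT_ALPHA, metric_report
from .simulate import SyntheticConfig, generate_screen

logger = logging.getLogger("evls")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _provenance(config: Mapping[str, Any], seed: int | None) -> dict:
    return {
        "tool": "evls",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
    }


def _load_screens(config: Mapping[str, Any], seed: int | None) -> list[EnsembleScreen]:
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        for tuple_key in ("conformers_range", "mw_range"):
            if tuple_key in sim_kwargs:
                sim_kwargs[tuple_key] = tuple(sim_kwargs[tuple_key])
        return generate_screen(SyntheticConfig(**sim_kwargs))
    inputs = config.get("inputs")
    if not inputs or "scores" not in inputs:
        raise PipelineError("input stage: config needs a 'simulate' or 'inputs.scores' entry")
    if "annotations" not in inputs:
        raise PipelineError("input stage: annotations required for real score tables")
    library = read_ligand_annotations(inputs["annotations"])
    screens = read_score_table(
        inputs["scores"],
        library=library,
        invert_sign=bool(inputs.get("invert_sign", False)),
    )
    return list(screens.values())


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    dry_run: bool = False,
) -> dict:
    """Execute the configured stage sequence and write report files.

    Returns the report dictionary.  With ``dry_run=True`` the validated plan
    is returned and nothing is written.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "evls_out"))
    seed = seed if seed is not None else config.get("seed")

    methods = list(config.get("methods", ["mrc_score", "mrc_rank"]))
    metrics = list(config.get("metrics", ["auac", "ef", "bedroc"]))
    chi_values = [float(c) for c in config.get("chi", [0.01, 0.10])]
    alpha = float(config.get("alpha", DEFAULT_ALPHA))
    filters = config.get("filters", {}) or {}

    plan = {
        "stages": ["load", "filter", "combine", "metrics", "diversity", "benchmark"],
        "methods": methods,
        "metrics": metrics,
        "chi": chi_values,
        "alpha": alpha,
        "filters": filters,
        "out_dir": str(out_dir),
        "provenance": _provenance(config, seed),
    }
    if dry_run:
        logger.info("dry run: %s", json.dumps(plan, indent=2))
        return plan

    t0 = time.perf_counter()
    try:
        screens = _load_screens(config, seed)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc
    logger.info("loaded %d targets in %.2fs", len(screens), time.perf_counter() - t0)

    out_dir.mkdir(parents=True, exist_ok=True)
    filter_decisions: dict[str, dict] = {}

    # --- filter stage -----------------------------------------------------
    t0 = time.perf_counter()
    filtered: list[EnsembleScreen] = []
    for screen in screens:
        decisions: dict[str, Any] = {}
        if filters.get("drop_all_positive"):
            screen, removed = drop_all_positive_runs(screen)
            decisions["removed_conformers"] = removed
        if filters.get("drop_cognate") and not screen.excluded:
            result = cognate_ligand_filter(screen)
            decisions["removed_binders"] = result.removed_binders
            decisions["removed_chemotypes"] = result.removed_chemotypes
            if result.excluded:
                screen.excluded = True
            else:
                screen = apply_library_filter(screen, result.library)
        decisions["excluded"] = screen.excluded
        if decisions:
            filter_decisions[screen.target_id] = decisions
        filtered.append(screen)
    screens = filtered
    usable = [s for s in screens if not s.excluded]
    logger.info(
        "filter stage kept %d/%d targets in %.2fs",
        len(usable), len(screens), time.perf_counter() - t0,
    )

    # --- combine + metrics + diversity ------------------------------------
    t0 = time.perf_counter()
    metric_rows: dict[str, dict] = {}
    diversity_rows: dict[str, dict] = {}
    for screen in usable:
        per_method = {}
        div_per_method = {}
        for method in methods:
            ranked = combine(screen, method)
            write_ranked_list(
                ranked, out_dir / f"ranked_{screen.target_id}_{method}.tsv"
            )
            per_method[method] = metric_report(
                ranked, screen.library, chi_values, alpha
            ).to_dict()
            nb, nc, labels = top_fraction_chemotypes(
                ranked, screen.library, chi_values[0]
            )
            div_per_method[method] = {
                "chi": chi_values[0],
                "n_binders_top": nb,
                "n_chemotypes_top": nc,
                "chemotypes": format_chemotype_set(labels),
            }
        metric_rows[screen.target_id] = per_method
        diversity_rows[screen.target_id] = div_per_method
    logger.info("combine/metrics stage in %.2fs", time.perf_counter() - t0)

    # --- benchmark --------------------------------------------------------
    t0 = time.perf_counter()
    bench = benchmark_report(
        usable, methods=methods, metrics=metrics, chi_values=chi_values, alpha=alpha
    )
    logger.info("benchmark stage in %.2fs", time.perf_counter() - t0)

    report = {
        "provenance": _provenance(config, seed),
        "filters": filter_decisions,
        "metrics": metric_rows,
        "diversity": diversity_rows,
        "benchmark": bench.to_dict(),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    bench.per_target.to_csv(out_dir / "benchmark.csv", index=False)
    (out_dir / "removed.json").write_text(json.dumps(filter_decisions, indent=2))
    if "simulate" in config:
        write_score_table(screens_by_id(usable), out_dir / "scores.tsv")
        for screen in usable:
            write_ligand_annotations(
                screen.library, out_dir / f"annotations_{screen.target_id}.tsv"
            )
    logger.info("wrote reports to %s", out_dir)
    return report


def screens_by_id(screens: list[EnsembleScreen]) -> dict[str, EnsembleScreen]:
    return {s.target_id: s for s in screens}
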