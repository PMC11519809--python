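"""End-to-end orchestration: simulate/load -> score -> select -> screen ->
criteria -> evaluate, with persisted intermediates and a reproducible report.

The run report deliberately excludes timestamps, hostnames and absolute
paths, so two runs with the same configuration and seed produce byte-
identical report JSON and ranking TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from mszscreen import io as mio
from mszscreen.criteria import apply_marker_criteria, evaluate_recovery
from mszscreen.regional import binarize_regions, regional_specificity_filter
from mszscreen.scoring import (
    ScoringParams,
    SelectionParams,
    aggregate_and_rank,
    normalize_counts,
    score_all_pairs,
    select_candidates,
)
from mszscreen.simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one screening run.

    Exactly one input mode must be used: simulation (``simulation`` set) or
    real inputs (all of ``counts_path``, ``samples_path``, ``regional_path``,
    ``stages_path`` set; ``truth_path`` optional, enabling recovery metrics).
    ``seed``, when given, overrides the simulation config's seed.
    """

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    counts_path: str | None = None
    samples_path: str | None = None
    regional_path: str | None = None
    stages_path: str | None = None
    truth_path: str | None = None
    scoring: ScoringParams = field(default_factory=ScoringParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    delta_regional: float = 1.0
    delta_stage: float = 1.0
    require_midline: bool = False
    allow_midline_at_initiation: bool = False
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        real = [self.counts_path, self.samples_path, self.regional_path,
                self.stages_path]
        if self.simulation is not None:
            if any(p is not None for p in real):
                raise ValueError(
                    "config mixes simulation mode with real-input paths; "
                    "set simulation to null to use real inputs"
                )
            self.simulation.validate()
        else:
            names = ["counts_path", "samples_path", "regional_path", "stages_path"]
            missing = [n for n, p in zip(names, real) if p is None]
            if missing:
                raise ValueError(
                    f"real-input mode is missing required path(s): {missing}"
                )

    @staticmethod
    def from_dict(data: Mapping) -> "PipelineConfig":
        data = dict(data)
        sim = data.get("simulation", "default")
        if sim == "default":
            simulation = SimulationConfig() if "counts_path" not in data else None
        elif sim is None:
            simulation = None
        else:
            sim = dict(sim)
            for key in ("methods",):
                if key in sim:
                    sim[key] = tuple(sim[key])
            simulation = SimulationConfig(**sim)
        scoring = ScoringParams(**data.get("scoring", {}))
        sel = dict(data.get("selection", {}))
        if "discard" in sel:
            sel["discard"] = frozenset(sel["discard"])
        selection = SelectionParams(**sel)
        kwargs = {
            k: data[k]
            for k in (
                "counts_path", "samples_path", "regional_path", "stages_path",
                "truth_path", "delta_regional", "delta_stage",
                "require_midline", "allow_midline_at_initiation",
                "seed", "log_level",
            )
            if k in data
        }
        return PipelineConfig(
            simulation=simulation, scoring=scoring, selection=selection, **kwargs
        )

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        return PipelineConfig.from_dict(mio.read_yaml(path))


def _params_echo(config: PipelineConfig) -> dict:
    """JSON-serializable, path-free echo of the effective parameters."""
    echo: dict = {}
    if config.simulation is not None:
        sim = dataclasses.asdict(config.simulation)
        sim["methods"] = list(sim["methods"])
        for key in (
            "class_counts", "dispersion_by_method", "dropout_prob_by_method",
            "contamination_by_method", "library_scale_by_method",
        ):
            sim[key] = dict(sim[key])
        echo["simulation"] = sim
    else:
        echo["simulation"] = None
    echo["scoring"] = dataclasses.asdict(config.scoring)
    sel = dataclasses.asdict(config.selection)
    sel["discard"] = sorted(sel["discard"])
    echo["selection"] = sel
    for k in (
        "delta_regional", "delta_stage", "require_midline",
        "allow_midline_at_initiation",
    ):
        echo[k] = getattr(config, k)
    return echo


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute the full screen and return the run report.

    Every intermediate artifact (inputs or simulated tables, pair scores,
    ranking, selected/kept gene lists, marker calls, recovery metrics,
    report) is written under ``outdir``.  A stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are retained.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stages_run: list[str] = []
    report: dict = {"parameters": _params_echo(config), "stages": stages_run}

    def stage(name: str):
        def deco(fn):
            def run(*args, **kwargs):
                logger.info("stage %s", name)
                try:
                    result = fn(*args, **kwargs)
                except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc
                stages_run.append(name)
                return result
            return run
        return deco

    @stage("load_inputs")
    def load_inputs():
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = sim.replace(seed=config.seed)
            ds = generate_dataset(sim)
            mio.write_counts_tsv(ds.counts, os.path.join(outdir, "counts.tsv"))
            mio.write_sample_sheet(ds.samples, os.path.join(outdir, "samples.csv"))
            mio.write_regional_tsv(ds.regional, os.path.join(outdir, "regional.tsv"))
            mio.write_stage_tsv(ds.stages, os.path.join(outdir, "stages.tsv"))
            mio.write_truth_csv(ds.truth, os.path.join(outdir, "truth.csv"))
            report["seed"] = sim.seed
            return ds.counts, ds.samples, ds.regional, ds.stages, ds.truth
        counts = mio.read_counts_tsv(config.counts_path)
        samples = mio.read_sample_sheet(config.samples_path)
        regional = mio.read_regional_tsv(config.regional_path)
        stages_tbl = mio.read_stage_tsv(config.stages_path)
        truth = (
            mio.read_truth_csv(config.truth_path) if config.truth_path else None
        )
        report["seed"] = config.seed
        return counts, samples, regional, stages_tbl, truth

    @stage("score")
    def score(counts, samples):
        abundances = normalize_counts(counts, config.scoring)
        ps = score_all_pairs(abundances, samples, config.scoring)
        ps.scores.to_csv(os.path.join(outdir, "pair_scores.tsv"), sep="\t",
                         index_label="gene_id")
        ps.fold_changes.to_csv(os.path.join(outdir, "fold_changes.tsv"), sep="\t",
                               index_label="gene_id")
        ranking = aggregate_and_rank(ps)
        ranking.to_csv(os.path.join(outdir, "ranking.tsv"), sep="\t", index=False)
        return ps, ranking

    @stage("select")
    def select(ranking, ps):
        selected = select_candidates(ranking, ps, config.selection)
        mio.write_gene_list(selected, os.path.join(outdir, "selected.txt"))
        return selected

    @stage("regional_screen")
    def screen(regional, selected):
        presence = binarize_regions(regional, config.delta_regional)
        kept = regional_specificity_filter(
            presence, selected, require_midline=config.require_midline
        )
        mio.write_gene_list(kept, os.path.join(outdir, "regional_kept.txt"))
        return kept

    @stage("marker_criteria")
    def criteria(stages_tbl, kept):
        calls = apply_marker_criteria(
            stages_tbl, kept, delta=config.delta_stage,
            allow_midline_at_initiation=config.allow_midline_at_initiation,
        )
        calls.to_csv(os.path.join(outdir, "marker_calls.csv"), index=False)
        return calls

    @stage("evaluate")
    def evaluate(calls, truth):
        metrics = evaluate_recovery(calls, truth)
        with open(os.path.join(outdir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return metrics

    counts, samples, regional, stages_tbl, truth = load_inputs()
    ps, ranking = score(counts, samples)
    selected = select(ranking, ps)
    kept = screen(regional, selected)
    calls = criteria(stages_tbl, kept)

    markers = calls.loc[calls["is_marker"], "gene_id"].to_list() if len(calls) else []
    mio.write_gene_list(markers, os.path.join(outdir, "markers.txt"))
    report["counts"] = {
        "n_input": int(counts.shape[0]),
        "n_after_selection": len(selected),
        "n_after_regional": len(kept),
        "n_markers": len(markers),
    }
    report["markers"] = markers
    report["recovery"] = evaluate(calls, truth) if truth is not None else None

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
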