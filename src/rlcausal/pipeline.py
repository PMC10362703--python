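"""End-to-end orchestration: read and normalize the table, run the
actor-critic graph search, annotate the best graph with IIE strengths,
prune weak edges, and write the outputs (edge list, adjacency matrix,
DOT graph, JSON run report)."""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import Dataset, read_table, normalize
from .strength import WeightedCausalGraph, annotate_and_prune
from .trainer import TrainingConfig, train

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_outputs"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str
    delimiter: str = ","
    normalization: str = "minmax"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    threshold: float = 0.5
    tie_policy: str = "drop"
    outdir: str = None

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("strength threshold must be nonnegative")


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def run_pipeline(cfg: PipelineConfig, log_path=None):
    """Execute the full two-stage pipeline.

    Returns ``(WeightedCausalGraph, report)`` and, when ``cfg.outdir``
    is set, writes edges.tsv / adjacency.csv / graph.dot / report.json
    there.  Any stage error aborts with the stage name; partially
    written outputs are removed.
    """
    t0 = time.time()
    raw = _stage("read", read_table, cfg.input_path, cfg.delimiter)
    data = _stage("normalize", normalize, raw, cfg.normalization)
    state = _stage("train", train, data, cfg.training, log_path)
    best = state.best_record
    pruned = _stage("strength", annotate_and_prune, best.graph, data,
                    cfg.threshold, cfg.tie_policy)

    tc = state.config
    report = {
        "input": str(cfg.input_path),
        "m": data.m,
        "d": data.d,
        "variables": list(data.columns),
        "seed": tc.seed,
        "normalization": cfg.normalization,
        "tie_policy": cfg.tie_policy,
        "threshold": cfg.threshold,
        "iterations": tc.iterations,
        "graphs_per_iteration": tc.graphs_per_iteration,
        "learning_rate": tc.learning_rate,
        "critic_hidden": tc.critic_hidden,
        "score_normalization": tc.score_normalization,
        "lambda1": tc.reward_config.lambda1,
        "lambda2": tc.reward_config.lambda2,
        "encoder": asdict(tc.encoder_config),
        "best_reward": best.reward,
        "best_is_dag": best.is_dag,
        "best_h": best.h,
        "bic_bounds": list(state.bic_bounds),
        "edges_before_pruning": int(best.graph.sum()),
        "edges_after_pruning": len(pruned.edges),
        "runtime_seconds": round(time.time() - t0, 3),
    }
    if cfg.outdir is not None:
        _stage("write", write_outputs, pruned, best.graph, report, cfg.outdir)
    return pruned, report


def _dot_source(graph: WeightedCausalGraph) -> str:
    lines = ["digraph causal {"]
    for name in graph.variables:
        lines.append(f'    "{name}";')
    for src, dst, strength in graph.edges:
        lines.append(f'    "{src}" -> "{dst}" [label="{strength:.6g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_outputs(graph: WeightedCausalGraph, adjacency: np.ndarray,
                  report: dict, outdir) -> list:
    """Write edges.tsv, adjacency.csv, graph.dot and report.json.

    ``adjacency`` is the stage-1 (pre-pruning) adjacency matrix.
    Returns the list of written paths; on failure, files written so far
    are removed.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    try:
        path = os.path.join(outdir, "edges.tsv")
        with open(path, "w") as f:
            f.write("source\ttarget\tstrength\n")
            for src, dst, strength in graph.edges:
                f.write(f"{src}\t{dst}\t{strength:.6g}\n")
        written.append(path)

        path = os.path.join(outdir, "adjacency.csv")
        with open(path, "w") as f:
            f.write(",".join(graph.variables) + "\n")
            for row in np.asarray(adjacency, dtype=int):
                f.write(",".join(str(v) for v in row) + "\n")
        written.append(path)

        path = os.path.join(outdir, "graph.dot")
        with open(path, "w") as f:
            f.write(_dot_source(graph))
        written.append(path)

        path = os.path.join(outdir, "report.json")
        with open(path, "w") as f:
            json.dump(report, f, indent=2)
            f.write("\n")
        written.append(path)
    except OSError:
        for p in written:
            try:
                os.remove(p)
            except OSError:
                pass
        raise
    return written
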