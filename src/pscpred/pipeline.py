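"""End-to-end orchestration: extract -> select -> evaluate.

A :class:`RunConfig` (YAML-serializable) fully determines a run; with a
fixed seed the run directory contents are byte-identical across reruns.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from pscpred.assembly import FeatureConfig, FeatureMatrix, build_feature_matrix
from pscpred.io_formats import Dataset, assemble_dataset
from pscpred.riforest import RIResult, SelectionResult, ri_scores, select_feature_subset
from pscpred.simulate import simulate_protein_dataset
from pscpred.svm_eval import (
    EvalReport,
    SvmParams,
    grid_search_params,
    jackknife_evaluate,
    jackknife_evaluate_nested,
    make_jackknife_eval,
)

DEFAULT_SIZE_GRID = (10, 20, 50, 100, 200, 400)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending ids."""


@dataclass
class RunConfig:
    # inputs: either the three file paths, or simulate_* to generate data
    fasta: str | None = None
    ss: str | None = None
    labels: str | None = None
    simulate_n_per_class: int | None = None
    simulate_length_range: tuple[int, int] = (100, 300)
    # feature families
    psf: bool = True
    ppf: bool = True
    rcf: bool = True
    pssf: bool = True
    ss_preset: str = "full"
    # forest
    forest_s: int | None = None
    forest_t: int = 50
    # selection
    size_grid: tuple[int, ...] | None = None
    # svm
    svm_min_exp: int = -10
    svm_max_exp: int = 10
    cv_folds: int = 10
    standardize: bool = True
    nested: bool = False
    # bookkeeping
    seed: int = 0
    outdir: str = "run"

    @property
    def exponents(self) -> tuple[int, ...]:
        return tuple(range(self.svm_min_exp, self.svm_max_exp + 1))

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            psf=self.psf,
            ppf=self.ppf,
            rcf=self.rcf,
            pssf=self.pssf,
            ss_preset=self.ss_preset,
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulate_length_range" in raw:
            raw["simulate_length_range"] = tuple(raw["simulate_length_range"])
        if raw.get("size_grid") is not None:
            raw["size_grid"] = tuple(raw["size_grid"])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["simulate_length_range"] = list(self.simulate_length_range)
        if self.size_grid is not None:
            d["size_grid"] = list(self.size_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class RunResult:
    outdir: Path
    dataset: Dataset
    matrix: FeatureMatrix
    ri: RIResult
    params: SvmParams
    full_report: EvalReport
    selection: SelectionResult
    chosen_report: EvalReport


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("load")
def _load_dataset(config: RunConfig) -> Dataset:
    if config.simulate_n_per_class is not None:
        return simulate_protein_dataset(
            config.simulate_n_per_class,
            tuple(config.simulate_length_range),
            seed=config.seed,
        )
    if not (config.fasta and config.labels):
        raise ValueError("either simulate_n_per_class or fasta+labels is required")
    return assemble_dataset(config.fasta, config.ss, config.labels)


def default_size_grid(d: int) -> tuple[int, ...]:
    grid = [q for q in DEFAULT_SIZE_GRID if q < d]
    grid.append(d)
    return tuple(grid)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and write all artifacts into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed: {config.seed}"]

    ds = _load_dataset(config)
    y = [r.label for r in ds]
    if any(lab is None for lab in y):
        raise PipelineError(
            "stage 'load' failed: unlabeled records: "
            f"{[r.id for r in ds if r.label is None]}"
        )

    matrix = _stage("extract")(build_feature_matrix)(ds, config.feature_config())
    matrix.to_csv(outdir / "features.csv")
    log_lines.append(f"features: n={matrix.n_samples} d={matrix.n_features}")

    s = config.forest_s or max(1, math.ceil(matrix.n_features / 30))
    ri = _stage("select")(ri_scores)(
        matrix, y, s=s, t=config.forest_t, seed=config.seed
    )
    ri.to_tsv(outdir / "ri_scores.tsv")
    log_lines.append(f"forest: s={ri.s} t={ri.t} subset_sizes={list(ri.subset_sizes)}")

    params = _stage("evaluate")(grid_search_params)(
        matrix,
        y,
        seed=config.seed,
        exponents=config.exponents,
        n_folds=config.cv_folds,
        standardize=config.standardize,
    )
    with open(outdir / "svm_params.json", "w") as fh:
        json.dump(params.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log_lines.append(f"svm: C={params.C} gamma={params.gamma}")

    full_report = _stage("evaluate")(jackknife_evaluate)(
        matrix, y, params, standardize=config.standardize
    )
    log_lines.append(f"jackknife (all features): {full_report.overall_accuracy:.4f}")

    grid = config.size_grid or default_size_grid(matrix.n_features)
    grid = tuple(q for q in grid if q <= matrix.n_features)
    eval_fn = make_jackknife_eval(params, standardize=config.standardize)
    selection = _stage("select")(select_feature_subset)(matrix, y, ri, grid, eval_fn)
    with open(outdir / "selection.json", "w") as fh:
        json.dump(selection.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "score_vs_size.csv", "w") as fh:
        fh.write("size,overall_accuracy\n")
        for q in sorted(selection.scores):
            fh.write(f"{q},{format(selection.scores[q], '.17g')}\n")
    log_lines.append(
        f"selection: chosen_size={selection.chosen_size} "
        f"scores={ {q: round(v, 4) for q, v in sorted(selection.scores.items())} }"
    )

    chosen_matrix = matrix.subset(selection.chosen)
    if config.nested:
        chosen_report = _stage("evaluate")(jackknife_evaluate_nested)(
            chosen_matrix,
            y,
            seed=config.seed,
            exponents=config.exponents,
            n_folds=config.cv_folds,
            standardize=config.standardize,
        )
    else:
        chosen_report = _stage("evaluate")(jackknife_evaluate)(
            chosen_matrix, y, params, standardize=config.standardize
        )
    chosen_report.to_json(outdir / "eval_report.json")
    chosen_report.confusion_to_csv(outdir / "confusion.csv")
    log_lines.append(
        f"jackknife (chosen {selection.chosen_size}): "
        f"{chosen_report.overall_accuracy:.4f}"
    )

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return RunResult(
        outdir=outdir,
        dataset=ds,
        matrix=matrix,
        ri=ri,
        params=params,
        full_report=full_report,
        selection=selection,
        chosen_report=chosen_report,
    )


def format_report(report: EvalReport) -> str:
    """Human-readable per-class Sens/Spec/F1 block plus an accuracy row."""
    lines = [f"{'class':<12}{'Sens':>8}{'Spec':>8}{'F1':>8}{'Acc':>8}"]
    for cls in report.classes:
        lines.append(
            f"{cls:<12}"
            f"{report.sens[cls] * 100:>8.2f}"
            f"{report.spec[cls] * 100:>8.2f}"
            f"{report.f1[cls] * 100:>8.2f}"
            f"{report.per_class_accuracy[cls] * 100:>8.2f}"
        )
    lines.append(f"overall accuracy: {report.overall_accuracy * 100:.2f}%")
    if report.flags:
        lines.append("flags: " + "; ".join(report.flags))
    return "\n".join(lines)
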