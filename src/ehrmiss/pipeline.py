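"""End-to-end pipeline driver.

Runs the stages simulate -> preprocess -> characterize -> match -> ampute ->
impute -> evaluate as toggled by a :class:`PipelineConfig`, handing results
between stages in memory while writing every artifact as delimited text.  A
manifest (JSON) records the configuration, the derived per-stage seeds, and
a SHA-256 checksum of every output file, so any artifact can be regenerated
from config + seed and reruns can be verified checksum-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ampute as ampute_mod
from . import io
from .ampute import derive_rng
from .characterize import missingness_ranking, predict_presence
from .complete_cases import add_age, extract_complete_cases, match_representative_sample
from .evaluate import evaluate as evaluate_set
from .impute import ImputationConfig, impute
from .preprocess import boxcox_z, filter_records, window_and_aggregate
from .synth import default_config, generate_population

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate", "preprocess", "characterize", "match", "ampute", "impute",
    "evaluate",
)

#: stage -> stages able to feed it (any one enabled suffices)
_REQUIRES = {
    "preprocess": ("simulate",),
    "characterize": ("preprocess",),
    "match": ("preprocess",),
    "ampute": ("preprocess",),
    "impute": ("ampute",),
    "evaluate": ("impute",),
}

#: per-stage params that satisfy the dependency from files instead
_FILE_INPUTS = {
    "preprocess": ("events", "demographics"),
    "characterize": ("matrix",),
    "match": ("matrix", "demographics"),
    "ampute": ("matrix",),
    "impute": ("masked",),
    "evaluate": (),
}


@dataclass
class PipelineConfig:
    """Stage toggles, per-stage parameter blocks, master seed, output dir."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)
        for stage in self.stages:
            needs = _REQUIRES.get(stage, ())
            if not needs:
                continue
            fed = any(dep in self.stages for dep in needs)
            file_fed = all(
                key in self.params.get(stage, {})
                for key in _FILE_INPUTS.get(stage, ())
            ) and bool(_FILE_INPUTS.get(stage))
            if not fed and not file_fed:
                raise ValueError(
                    f"stage {stage!r} is enabled but none of its inputs are: "
                    f"enable {needs} or pass file inputs "
                    f"{_FILE_INPUTS.get(stage)}"
                )


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return PipelineConfig(
        out_dir=raw.get("out_dir", "pipeline_out"),
        seed=int(raw.get("seed", 0)),
        stages=tuple(raw.get("stages", STAGE_ORDER)),
        params=raw.get("params", {}),
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    return int(derive_rng(master, "stage", stage).integers(2**31))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the artifact directory.

    A stage failure raises an error naming the stage; artifacts written by
    earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    outputs: list[Path] = []
    stage_seeds = {s: _stage_seed(config.seed, s) for s in config.stages}

    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        logger.info("stage %s starting (seed %d)", stage, stage_seeds[stage])
        try:
            runner = globals()[f"_run_{stage}"]
            runner(state, params, stage_dir, stage_seeds[stage], outputs)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "stage_seeds": stage_seeds,
        "params": config.params,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(outputs), out)
    return out


def _emit(outputs: list[Path], path: Path) -> Path:
    outputs.append(path)
    return path


def _run_simulate(state, params, stage_dir, seed, outputs):
    n_patients = int(params.get("n_patients", 500))
    cfg = default_config(n_patients=n_patients, seed=seed)
    demographics, events = generate_population(cfg)
    state["demographics"] = demographics
    state["events"] = events
    state["panel_map"] = cfg.panel_map
    logger.info("simulated %d patients, %d events", len(demographics),
                len(events))
    io.write_demographics(demographics, _emit(outputs,
                                              stage_dir / "demographics.csv"))
    io.write_long_events(events, _emit(outputs, stage_dir / "events.csv"))
    io.write_panel_map(cfg.panel_map, _emit(outputs,
                                            stage_dir / "panel_map.csv"))


def _run_preprocess(state, params, stage_dir, seed, outputs):
    if "events" in params:
        state["events"] = io.read_long_events(params["events"])
        state["demographics"] = io.read_demographics(params["demographics"])
    events = filter_records(
        state["events"], state["demographics"],
        min_prevalence=float(params.get("min_prevalence", 0.005)),
    )
    matrix = window_and_aggregate(events, panel_map=state.get("panel_map"))
    matrix, transforms = boxcox_z(matrix)
    state["matrix"] = matrix
    logger.info("matrix: %d patients x %d variables, %d missing cells",
                matrix.shape[0], matrix.shape[1],
                int(matrix.values.isna().sum().sum()))
    io.write_wide_matrix(matrix, _emit(outputs, stage_dir / "matrix.csv"))
    io.write_transforms(transforms, _emit(outputs,
                                          stage_dir / "transforms.csv"))


def _run_characterize(state, params, stage_dir, seed, outputs):
    if "matrix" in params:
        state["matrix"] = io.read_wide_matrix(params["matrix"])
    matrix = state["matrix"]
    ranking = missingness_ranking(matrix)
    ranking.to_csv(_emit(outputs, stage_dir / "ranking.csv"), index=False,
                   lineterminator="\n")
    targets = params.get("targets", [])
    rows = []
    for target in targets:
        result = predict_presence(
            matrix, target, folds=int(params.get("folds", 10)), seed=seed
        )
        rows.append({"target": target, "mean_auroc": result.mean_auroc,
                     **{f"fold_{i}": a
                        for i, a in enumerate(result.fold_aurocs)}})
    if rows:
        import pandas as pd

        pd.DataFrame(rows).to_csv(
            _emit(outputs, stage_dir / "presence_auroc.csv"), index=False,
            lineterminator="\n",
        )


def _demo_with_age(state):
    events = state.get("events")
    ref = int(events["date"].median()) if events is not None and len(events) \
        else 15000
    return add_age(state["demographics"], ref_date=ref)


def _run_match(state, params, stage_dir, seed, outputs):
    matrix = state["matrix"]
    complete = extract_complete_cases(matrix)
    demo = _demo_with_age(state)
    cc_demo = demo.loc[demo["patient_id"].isin(complete.values.index)]
    n = int(params.get("n", min(len(demo), max(len(demo) // 5, 1))))
    matches = match_representative_sample(demo, cc_demo, n=n, seed=seed)
    state["matches"] = matches
    state["complete"] = complete
    matches.to_csv(_emit(outputs, stage_dir / "matches.csv"), index=False,
                   lineterminator="\n")


def _run_ampute(state, params, stage_dir, seed, outputs):
    matrix = state.get("complete")
    if matrix is None:
        matrix = extract_complete_cases(state["matrix"])
    truth = matrix.values.dropna()
    mechanism = params.get("mechanism", "mcar").lower()
    if mechanism == "mcar":
        ds = ampute_mod.ampute_mcar(truth, p=float(params.get("p", 0.3)),
                                    seed=seed)
    elif mechanism == "mar":
        cols = list(truth.columns)
        ds = ampute_mod.ampute_mar(
            truth, params.get("col_a", cols[0]), params.get("col_b", cols[1]),
            quartile=int(params.get("quartile", 1)),
            frac=float(params.get("frac", 0.5)), seed=seed,
        )
    elif mechanism == "mnar":
        ds = ampute_mod.ampute_mnar(
            truth, params.get("col", list(truth.columns)[0]),
            quartile=int(params.get("quartile", 1)),
            frac=float(params.get("frac", 0.5)), seed=seed,
        )
    elif mechanism in ("real", "realistic"):
        demo = _demo_with_age(state)
        complete = state.get("complete") or extract_complete_cases(
            state["matrix"]
        )
        cc_demo = demo.loc[demo["patient_id"].isin(complete.values.index)]
        ds = ampute_mod.ampute_realistic(
            complete, cc_demo, state["matrix"], demo
        )
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    state["masked_dataset"] = ds
    io.write_wide_matrix(ds.truth, _emit(outputs, stage_dir / "truth.csv"))
    io.write_mask(ds.mask, _emit(outputs, stage_dir / "mask.csv"))
    io.write_wide_matrix(ds.masked, _emit(outputs, stage_dir / "masked.csv"))
    (stage_dir / "spec.json").write_text(
        json.dumps({"label": ds.spec.label()}, indent=2)
    )
    outputs.append(stage_dir / "spec.json")


def _run_impute(state, params, stage_dir, seed, outputs):
    if "masked" in params:
        masked = io.read_wide_matrix(params["masked"]).values
    else:
        masked = state["masked_dataset"].masked
    config = ImputationConfig(
        method=params.get("method", "ce_pmm"),
        m=int(params.get("m", 5)),
        seed=seed,
    )
    completed = impute(masked, config)
    state["completed"] = completed
    for i, copy in enumerate(completed.copies, start=1):
        io.write_wide_matrix(copy, _emit(outputs,
                                         stage_dir / f"completed_{i}.csv"))


def _run_evaluate(state, params, stage_dir, seed, outputs):
    import pandas as pd

    ds = state["masked_dataset"]
    report = evaluate_set(state["completed"], ds.truth, ds.mask)
    per_var = report.per_variable_rmse.rename("rmse").rename_axis("variable")
    per_var.to_csv(_emit(outputs, stage_dir / "rmse_per_variable.csv"),
                   lineterminator="\n")
    summary = {
        "overall_rmse": report.overall_rmse,
        "md": report.md,
        **report.metadata,
    }
    path = stage_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs.append(path)
    if report.calibration is not None:
        report.calibration.to_csv(
            _emit(outputs, stage_dir / "calibration.csv"), index=False,
            lineterminator="\n",
        )
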