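"""End-to-end pipeline driver with provenance.

A single YAML config drives simulate -> split -> rank -> train-base -> stack
-> evaluate -> importance -> validate-external.  Each stage records the
SHA-256 of its config block, inputs and outputs in a run manifest; a rerun
with an unchanged config skips stages whose artifacts still match their
checksums.  One global seed fans out to per-stage seeds through a documented
counter scheme (stage i uses numpy SeedSequence([seed, i])), so every stage
is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import evaluation, external, firth, importance, simulate, stacking
from .cohort import (
    Cohort,
    TableDialect,
    assign_time_groups,
    read_cohort,
    stratified_split,
    write_cohort,
)
from .learners import FAMILIES, CVPlan

log = logging.getLogger("serostack")

STAGES = ("simulate", "split", "rank", "train_base", "stack", "evaluate",
          "importance", "validate_external")


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed fan-out (kept below 2**31)."""
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cfg_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "outdir" not in cfg:
        raise PipelineError("config", "config must be a mapping with an 'outdir'")
    cfg.setdefault("seed", 0)
    return cfg


def save_stack_model(model: stacking.StackModel, path) -> None:
    joblib.dump(model, path)


def load_stack_model(path) -> stacking.StackModel:
    return joblib.load(path)


def _cv_plan(block: dict, seed: int) -> CVPlan:
    return CVPlan(
        n_folds=int(block.get("n_folds", 10)),
        n_repeats=int(block.get("n_repeats", 5)),
        oversample=bool(block.get("oversample", True)),
        seed=seed,
    )


def _sim_config(block: dict, seed: int) -> simulate.SimulationConfig:
    effects = block.get("effects")
    kwargs = {k: v for k, v in block.items() if k not in ("effects", "null")}
    if effects is not None:
        kwargs["effects"] = tuple(
            simulate.MarkerEffect(e["name"], float(e["delta"]), float(e.get("tau", 1.5)))
            for e in effects
        )
    cfg = simulate.SimulationConfig(seed=seed, **kwargs)
    return cfg.null() if block.get("null") else cfg


class Runner:
    def __init__(self, config: dict):
        self.cfg = config
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}}
        self.manifest["config_hash"] = _cfg_hash(config)
        self.manifest["seed"] = config["seed"]

    # -- caching ---------------------------------------------------------
    def _fresh(self, stage: str, block_hash: str, outputs: list[Path]) -> bool:
        rec = self.manifest["stages"].get(stage)
        if rec is None or rec["config_hash"] != block_hash:
            return False
        for path, digest in rec["outputs"].items():
            p = Path(path)
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise PipelineError(stage, f"checksum mismatch for artifact {path}")
        return True

    def _record(self, stage: str, block_hash: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "config_hash": block_hash,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _run_stage(self, stage: str, func, outputs: list[Path]) -> None:
        block = self.cfg.get(stage, {}) or {}
        block_hash = _cfg_hash([block, self.cfg["seed"]])
        if self._fresh(stage, block_hash, outputs):
            log.info("stage %s: unchanged, skipped", stage)
            return
        log.info("stage %s: running", stage)
        t0 = time.time()
        try:
            func(block)
        except Exception as exc:
            self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
            raise PipelineError(stage, str(exc)) from exc
        self._record(stage, block_hash, outputs)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)

    # -- stages ----------------------------------------------------------
    def run(self) -> dict:
        o = self.outdir
        seed = self.cfg["seed"]
        paths = {
            "cohort": o / "cohort.csv",
            "split": o / "split.csv",
            "ranking": o / "ranking.csv",
            "layer": o / "base_layer.joblib",
            "prob_matrix": o / "prob_matrix.csv",
            "model": o / "stack_model.joblib",
            "report": o / "report.json",
            "importance": o / "importance.csv",
            "marginal": o / "marginal.json",
        }

        def do_simulate(block):
            cfg = _sim_config(block, stage_seed(seed, 0))
            cohort = simulate.simulate_cohort(cfg)
            cohort = assign_time_groups(cohort)
            write_cohort(cohort, paths["cohort"])

        def do_split(block):
            cohort = read_cohort(paths["cohort"])
            assignment = stratified_split(
                cohort, float(block.get("frac_train", 2 / 3)),
                seed=stage_seed(seed, 1),
            )
            pd.DataFrame(
                {"sample_id": cohort.df["sample_id"], "partition": assignment}
            ).to_csv(paths["split"], index=False)

        def do_rank(block):
            cohort, train, _ = self._load_split(paths)
            from .cohort import impute_low

            features = train.marker_cols + [
                c for c in ("age", "bmi", "hrt", "ocp", "diabetes")
                if c in train.df.columns
            ]
            ranking = firth.rank_features(impute_low(train), features)
            ranking.to_csv(paths["ranking"], index=False)

        def do_train(block):
            _, train, _ = self._load_split(paths)
            ranking = pd.read_csv(paths["ranking"])
            panel_size = int(block.get("panel_size", 20))
            panel = ranking["feature"].head(panel_size).tolist()
            plan = _cv_plan(block, stage_seed(seed, 3))
            arch = self.cfg.get("stack", {}).get("architecture", "jtg2l")
            layer_kind = "jtg2l" if arch == "jtg2l" else "stg"
            from .learners import load_search_spaces

            layer = stacking.train_base_layer(
                train, layer_kind, panel,
                joined_group=block.get("joined_group", "0-4+"),
                plan=plan,
                n_search=int(block.get("n_search", 25)),
                families=tuple(block.get("families", FAMILIES)),
                seed=stage_seed(seed, 3),
                spaces=load_search_spaces(profile=block.get("profile", "default")),
            )
            joblib.dump(layer, paths["layer"])
            layer.P.assign(sample_id=layer.sample_ids).to_csv(
                paths["prob_matrix"], index=False
            )

        def do_stack(block):
            layer = joblib.load(paths["layer"])
            model = stacking.fit_stack_model(
                layer,
                block.get("architecture", "jtg2l"),
                block.get("kind", "bma"),
                seed=stage_seed(seed, 4),
                occam_odds=float(block.get("occam_odds", 20.0)),
                max_subset=block.get("max_subset"),
            )
            save_stack_model(model, paths["model"])

        def do_evaluate(block):
            _, _, test = self._load_split(paths)
            model = load_stack_model(paths["model"])
            groups = block.get("groups", ["0-1", "0-2", "0-3", "0-4", "0-4+"])
            reports = {}
            for g in groups:
                sub = test.time_group_subset(g)
                y = sub.status.to_numpy()
                if y.sum() == 0 or (1 - y).sum() == 0:
                    continue
                scores = stacking.predict(model, sub)
                reports[g] = evaluation.performance_report(
                    scores, y,
                    spec_target=float(block.get("spec_target", 0.90)),
                    n_boot=int(block.get("n_boot", 2000)),
                    seed=stage_seed(seed, 5),
                    group=g,
                ).to_dict()
            paths["report"].write_text(json.dumps(reports, indent=2))

        def do_importance(block):
            _, train, _ = self._load_split(paths)
            model = load_stack_model(paths["model"])
            from .cohort import build_design, impute_low

            X = build_design(impute_low(train), model.panel)
            raw = {}
            for name, (tl, g) in model.base.items():
                raw[(tl.family, g)] = importance.model_importances(
                    tl, X, grid_size=int(block.get("grid_size", 20)),
                    seed=stage_seed(seed, 6),
                )
            table = importance.scale_and_aggregate(raw)
            table.to_csv(paths["importance"])

        def do_validate(block):
            model = load_stack_model(paths["model"])
            cfg = _sim_config(self.cfg.get("simulate", {}) or {}, stage_seed(seed, 7))
            ext = simulate.simulate_external_set(
                cfg, tuple(block.get("missing", ("hrt", "ocp")))
            )
            report = external.marginal_validate(
                model, ext,
                missing=tuple(block.get("missing", ("hrt", "ocp"))),
                n_rand=int(block.get("n_rand", 1000)),
                mode=block.get("mode", "frequency"),
                seed=stage_seed(seed, 7),
            )
            paths["marginal"].write_text(json.dumps(report.to_dict(), indent=2))

        self._run_stage("simulate", do_simulate, [paths["cohort"]])
        self._run_stage("split", do_split, [paths["split"]])
        self._run_stage("rank", do_rank, [paths["ranking"]])
        self._run_stage("train_base", do_train, [paths["layer"], paths["prob_matrix"]])
        self._run_stage("stack", do_stack, [paths["model"]])
        self._run_stage("evaluate", do_evaluate, [paths["report"]])
        self._run_stage("importance", do_importance, [paths["importance"]])
        if (self.cfg.get("validate_external") or {}).get("enabled", False):
            self._run_stage("validate_external", do_validate, [paths["marginal"]])
        return self.manifest

    def _load_split(self, paths):
        cohort = read_cohort(paths["cohort"])
        split = pd.read_csv(paths["split"])
        part = cohort.df["sample_id"].map(
            dict(zip(split["sample_id"], split["partition"]))
        )
        train = cohort.subset((part == "train").to_numpy())
        test = cohort.subset((part == "test").to_numpy())
        return cohort, train, test


def run_pipeline(config_path) -> dict:
    """Run the full analysis from a YAML config; returns the run manifest."""
    return Runner(load_config(config_path)).run()
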