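"""Experiment orchestration: staged runs, manifests, reports, CLI.

Each stage (curate, train-generator, train-predictor, rl-train, sample,
evaluate) reads plain-text inputs (.smi / CSV / YAML config), executes the
corresponding library call, and writes its artifacts plus a ``manifest.json``
recording the config echo, content hashes of the inputs, the seed, wall
time and the artifact list — enough to verify a rerun reproduced a run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import smiles_data as sd
from .generator import SmilesGenerator
from .metrics import desirability_logp, desirability_pic50, evaluate_generated_set
from .predictor import train_qsar
from .rl_engine import ReinforceOptimizer, RewardSpec, logp_oracle

STAGES = ("curate", "train-generator", "train-predictor", "rl-train",
          "sample", "evaluate")


@dataclass
class RunConfig:
    stage: str
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    stage_config: dict = field(default_factory=dict)
    scale: str = "fixture"

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; one of {STAGES}")
        if "out" not in self.paths:
            raise ValueError("paths.out is required")
        for key, value in self.paths.items():
            if key != "out" and not Path(value).exists():
                raise ValueError(f"input path {key}={value!r} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for sub in sorted(p for p in path.rglob("*") if p.is_file()):
            h.update(sub.name.encode())
            h.update(sub.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig) -> Path:
    """Execute one stage; returns the run directory containing a manifest."""
    config.validate()
    out = Path(config.paths["out"])
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    input_hashes = {k: _sha256(Path(v)) for k, v in config.paths.items()
                    if k != "out"}
    artifacts = _STAGE_FNS[config.stage](config, out)
    manifest = {
        "stage": config.stage,
        "seed": config.seed,
        "scale": config.scale,
        "stage_config": config.stage_config,
        "paths": config.paths,
        "input_sha256": input_hashes,
        "wall_seconds": round(time.time() - started, 3),
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# -- stage implementations ---------------------------------------------------

def _stage_curate(config: RunConfig, out: Path) -> list[str]:
    cfg = config.stage_config
    smiles = sd.read_smi(config.paths["corpus"])
    records, log = sd.curate_corpus(
        smiles,
        logp_range=tuple(cfg.get("logp_range", (-2.0, 6.0))),
        mw_range=tuple(cfg.get("mw_range", (200.0, 600.0))),
    )
    sd.write_smi([r.canonical_smiles for r in records], out / "curated.smi")
    (out / "curation_log.json").write_text(json.dumps(vars(log), indent=2))
    return ["curated.smi", "curation_log.json"]


def _stage_train_generator(config: RunConfig, out: Path) -> list[str]:
    corpus = sd.read_smi(config.paths["corpus"])
    model = SmilesGenerator(random_state=config.seed, **config.stage_config)
    model.fit(corpus)
    model.save(out / "generator")
    return ["generator/weights.npz", "generator/model.json"]


def _stage_train_predictor(config: RunConfig, out: Path) -> list[str]:
    cfg = dict(config.stage_config)
    model_kind = cfg.pop("model_kind", "smiles_rnn")
    df = sd.curate_activity_table(sd.read_activity_csv(config.paths["data"]))
    ensemble = train_qsar(df, model_kind=model_kind, config=cfg,
                          seed=config.seed)
    report = {
        "model_kind": model_kind,
        "mse": ensemble.report.mse,
        "q2": ensemble.report.q2,
        "per_fold": ensemble.report.per_fold,
    }
    (out / "qsar_report.json").write_text(json.dumps(report, indent=2))
    return ["qsar_report.json"]


def _make_objective(cfg: dict, predictor=None) -> RewardSpec:
    mode = cfg.get("objective", "logp_range")
    if mode == "logp_range":
        return RewardSpec(mode=mode, property_oracle=logp_oracle,
                          logp_bounds=tuple(cfg.get("logp_bounds", (1.0, 4.0))))
    if predictor is None:
        raise ValueError(f"objective {mode!r} requires a trained predictor")
    return RewardSpec(mode=mode, property_oracle=predictor)


def _stage_rl_train(config: RunConfig, out: Path) -> list[str]:
    cfg = dict(config.stage_config)
    g_u = SmilesGenerator.load(config.paths["generator"])
    objective = _make_objective(cfg)
    cfg.pop("objective", None)
    cfg.pop("logp_bounds", None)
    engine = ReinforceOptimizer(objective=objective,
                                random_state=config.seed, **cfg)
    engine.fit(g_u)
    engine.generator_.save(out / "biased")
    with (out / "iterations.jsonl").open("w") as fh:
        for record in engine.log_:
            fh.write(json.dumps(record) + "\n")
    return ["biased/weights.npz", "biased/model.json", "iterations.jsonl"]


def _stage_sample(config: RunConfig, out: Path) -> list[str]:
    cfg = config.stage_config
    model = SmilesGenerator.load(config.paths["generator"])
    results = model.sample(int(cfg.get("n", 1000)),
                           temperature=cfg.get("temperature"),
                           seed=config.seed)
    sd.write_smi([r.smiles for r in results if r.smiles], out / "samples.smi")
    return ["samples.smi"]


def _stage_evaluate(config: RunConfig, out: Path) -> list[str]:
    cfg = config.stage_config
    samples = sd.read_smi(config.paths["samples"])
    if not samples:
        raise ValueError("samples file is empty")
    reference = (sd.read_smi(config.paths["reference"])
                 if "reference" in config.paths else None)
    rule = None
    if cfg.get("desirability") == "logp":
        rule = desirability_logp(tuple(cfg.get("logp_bounds", (1.0, 4.0))))
    report = evaluate_generated_set(
        samples, reference=reference, desirability_rule=rule,
        distances=tuple(cfg.get("distances", ("tanimoto",))))
    (out / "evaluation.json").write_text(json.dumps(report.as_dict(), indent=2))
    return ["evaluation.json"]


_STAGE_FNS = {
    "curate": _stage_curate,
    "train-generator": _stage_train_generator,
    "train-predictor": _stage_train_predictor,
    "rl-train": _stage_rl_train,
    "sample": _stage_sample,
    "evaluate": _stage_evaluate,
}


# -- reporting ---------------------------------------------------------------

def render_report(run_dir: str | Path) -> str:
    """Plain-text table of an evaluated run (desirability/uniqueness/
    validity/diversity columns)."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    eval_path = run_dir / "evaluation.json"
    if not eval_path.exists():
        raise FileNotFoundError(f"no evaluation artifact in {run_dir}")
    rep = json.loads(eval_path.read_text())

    def fmt(x):
        return "-" if x is None else f"{x:.1f}"

    div = rep.get("internal_diversity", {}).get("tanimoto")
    lines = [
        "% Desirable  % Unique  % Valid  Diversity",
        f"{fmt(rep['pct_desirable']):>11}  {fmt(rep['pct_unique']):>8}  "
        f"{fmt(rep['pct_valid']):>7}  "
        f"{'-' if div is None else f'{div:.3f}':>9}",
    ]
    return "\n".join(lines)


# -- CLI ---------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Diversity-oriented RL molecule generation toolkit."""


def _common(stage: str, paths: dict, seed: int, config_file: str | None,
            **stage_config) -> None:
    if config_file:
        stage_config = {**yaml.safe_load(Path(config_file).read_text()),
                        **stage_config}
    run = run_experiment(RunConfig(stage=stage, paths=paths, seed=seed,
                                   stage_config=stage_config))
    click.echo(f"run complete: {run}")


@cli.command("curate")
@click.option("--corpus", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--seed", default=0, type=int)
def cmd_curate(corpus, out, seed):
    _common("curate", {"corpus": corpus, "out": out}, seed, None)


@cli.command("train-generator")
@click.option("--corpus", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--config", "config_file", type=click.Path(exists=True))
@click.option("--seed", default=0, type=int)
def cmd_train_generator(corpus, out, config_file, seed):
    _common("train-generator", {"corpus": corpus, "out": out}, seed,
            config_file)


@cli.command("train-predictor")
@click.option("--data", required=True, type=click.Path(exists=True))
@click.option("--model", "model_kind", default="smiles_rnn")
@click.option("--out", required=True, type=click.Path())
@click.option("--config", "config_file", type=click.Path(exists=True))
@click.option("--seed", default=0, type=int)
def cmd_train_predictor(data, model_kind, out, config_file, seed):
    _common("train-predictor", {"data": data, "out": out}, seed,
            config_file, model_kind=model_kind)


@cli.command("rl-train")
@click.option("--generator", required=True, type=click.Path(exists=True))
@click.option("--objective", default="logp_range")
@click.option("--out", required=True, type=click.Path())
@click.option("--config", "config_file", type=click.Path(exists=True))
@click.option("--seed", default=0, type=int)
def cmd_rl_train(generator, objective, out, config_file, seed):
    _common("rl-train", {"generator": generator, "out": out}, seed,
            config_file, objective=objective)


@cli.command("sample")
@click.option("--generator", required=True, type=click.Path(exists=True))
@click.option("--n", default=1000, type=int)
@click.option("--out", required=True, type=click.Path())
@click.option("--seed", default=0, type=int)
def cmd_sample(generator, n, out, seed):
    _common("sample", {"generator": generator, "out": out}, seed, None, n=n)


@cli.command("evaluate")
@click.option("--samples", required=True, type=click.Path(exists=True))
@click.option("--reference", type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--desirability", type=click.Choice(["logp", "none"]),
              default="none")
@click.option("--seed", default=0, type=int)
def cmd_evaluate(samples, reference, out, desirability, seed):
    paths = {"samples": samples, "out": out}
    if reference:
        paths["reference"] = reference
    stage_config = {}
    if desirability != "none":
        stage_config["desirability"] = desirability
    _common("evaluate", paths, seed, None, **stage_config)


@cli.command("report")
@click.argument("run_dir", type=click.Path(exists=True))
def cmd_report(run_dir):
    click.echo(render_report(run_dir))
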