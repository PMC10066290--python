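"""End-to-end orchestration: synth -> enhance -> augment -> train ->
evaluate -> plan-edges -> simulate-loop, with per-stage seeds derived from
one global seed and a JSON-ready aggregate report."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import classifier as clf
from . import edge_planner, evaluation, preprocess, retrain_sim
from . import synthetic_data as synth
from .config import PipelineConfig, stage_seed

logger = logging.getLogger("fangmark")

STAGES = ("synth", "enhance", "augment", "train", "evaluate",
          "plan_edges", "simulate_loop")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _percent(fraction: float, decimals: int = 1) -> str:
    return f"{fraction * 100.0:.{decimals}f}%"


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute all stages in order and aggregate their outputs.

    Returns the report dict; with ``write_outputs`` the per-stage artifacts
    (PNGs, CSVs, JSON) land under ``cfg.out_dir`` as well.
    """
    out = Path(cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    state: dict = {}
    for stage in STAGES:
        seed = stage_seed(cfg.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            runner = globals()[f"_stage_{stage}"]
            report["stages"][stage] = runner(cfg, seed, state, out,
                                             write_outputs)
        except Exception as exc:  # abort with the stage name attached
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    if write_outputs:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def _stage_synth(cfg, seed, state, out, write):
    images = synth.generate_dataset(cfg.generator.n_cobra,
                                    cfg.generator.n_other,
                                    cfg.generator_config(), seed)
    states = synth.generate_state_table(cfg.planner.n_states, seed + 1)
    state["images"], state["states"] = images, states
    if write:
        synth.write_dataset(images, out / "synth")
        synth.write_state_table(states, out / "states.csv")
    return {"n_images": len(images), "n_states": len(states), "seed": seed}


def _stage_enhance(cfg, seed, state, out, write):
    enh_cfg = cfg.enhance_config()
    enhanced = [synth.LabeledImage(
        pixels=preprocess.enhance(im.pixels, enh_cfg),
        label=im.label, meta=dict(im.meta))
        for im in state["images"]]
    state["enhanced"] = enhanced
    if write:
        synth.write_dataset(enhanced, out / "enhanced")
    gain = float(np.mean([e.pixels.mean() - i.pixels.mean()
                          for e, i in zip(enhanced, state["images"])]))
    return {"n_images": len(enhanced), "mean_intensity_gain": gain,
            "seed": seed}


def _stage_augment(cfg, seed, state, out, write):
    rng = np.random.default_rng(seed)
    augmented: list[synth.LabeledImage] = []
    for im in state["enhanced"]:
        aug_cfg = cfg.augment_config(int(rng.integers(0, 2 ** 31 - 1)))
        for variant in preprocess.augment(im.pixels, aug_cfg):
            augmented.append(synth.LabeledImage(
                pixels=variant, label=im.label, meta=dict(im.meta)))
    state["augmented"] = augmented
    if write:
        synth.write_dataset(augmented, out / "augmented")
    return {"n_images": len(augmented), "seed": seed}


def _stage_train(cfg, seed, state, out, write):
    train_cfg = cfg.train_config(seed)
    model = clf.build_model(train_cfg)
    result = clf.train(model, state["augmented"], train_cfg)
    state["model"], state["result"] = model, result
    history_rows = [dataclasses.asdict(rec) for rec in result.history]
    if write:
        model.save(out / "model.ckpt.npz")
        with open(out / "history.csv", "w") as fh:
            fh.write("epoch,train_loss,train_acc,val_acc\n")
            for rec in result.history:
                fh.write(f"{rec.epoch},{rec.train_loss},{rec.train_acc},"
                         f"{rec.val_acc}\n")
    return {"epochs": len(result.history),
            "final_train_acc": result.history[-1].train_acc,
            "final_val_acc": result.history[-1].val_acc,
            "history": history_rows, "seed": seed}


def _stage_evaluate(cfg, seed, state, out, write):
    result = state["result"]
    test_idx = result.splits["test"] or result.splits["train"]
    dataset = state["augmented"]
    truth = [dataset[i].label for i in test_idx]
    preds, scores = clf.predict(state["model"],
                                [dataset[i] for i in test_idx])
    cm = evaluation.confusion(truth, preds)
    try:
        metrics = evaluation.metrics_report(cm, scores, truth)
    except evaluation.EvaluationError:
        metrics = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
                   "accuracy": evaluation.accuracy(cm)}
    metrics["accuracy_percent"] = _percent(metrics["accuracy"],
                                           cfg.evaluation.percent_decimals)
    if write:
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
    return {"metrics": metrics, "n_test": len(test_idx), "seed": seed}


def _stage_plan_edges(cfg, seed, state, out, write):
    plans = {}
    swarm = cfg.swarm_config(seed)
    for epi in state["states"]:
        problem = edge_planner.PlannerProblem.with_per_node_cost(
            cfg.planner.budget, epi, cfg.planner.cost_per_node)
        plan = edge_planner.optimize(problem, swarm,
                                     method=cfg.planner.method)
        plans[epi.state] = {"k_star": plan.k_star,
                            "profit": plan.best_profit,
                            "trace": plan.trace}
    if write:
        with open(out / "plan.json", "w") as fh:
            json.dump(plans, fh, indent=2)
    return {"plans": plans, "method": cfg.planner.method, "seed": seed}


def _stage_simulate_loop(cfg, seed, state, out, write):
    loop_cfg = retrain_sim.LoopConfig(
        rounds=cfg.loop.rounds, cases_per_round=cfg.loop.cases_per_round,
        n_edges=cfg.loop.n_edges, initial_cobra=cfg.loop.initial_cobra,
        initial_other=cfg.loop.initial_other,
        holdout_per_class=cfg.loop.holdout_per_class,
        retrain_epochs=cfg.loop.retrain_epochs,
        confirmation_lag=cfg.loop.confirmation_lag,
        train_config=clf.TrainConfig(
            epochs=cfg.loop.initial_epochs,
            learning_rate=cfg.train.learning_rate,
            epsilon=cfg.train.epsilon, batch_size=cfg.train.batch_size,
            input_side=32),
        generator=synth.GeneratorConfig(image_size=32),
        seed=seed)
    logs = retrain_sim.run_loop(loop_cfg)
    rows = [dataclasses.asdict(log) for log in logs]
    if write:
        with open(out / "rounds.csv", "w") as fh:
            fh.write("round,edge_errors,dataset_size,accuracy,mean_delay\n")
            for log in logs:
                errors = ";".join(str(e) for e in log.edge_errors)
                fh.write(f"{log.round_index},{errors},{log.dataset_size},"
                         f"{log.accuracy},{log.mean_delay}\n")
    return {"rounds": rows, "seed": seed}
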