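"""The end-to-end pipeline: generate data, train, synthesize (both
strategies), evaluate, cross-validate.

Each stage writes its artifacts under the run directory and is skipped on
rerun if its outputs already exist *and* no upstream stage re-ran; deleting
one stage's outputs therefore regenerates that stage and everything
downstream of it.  The exact config used is frozen into the run directory
together with a structured per-stage log (wall time, seed), so
deterministic stages are bit-reproducible from the frozen copy.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from .classifier import BranchConfig, cross_validate
from .config import RunConfig, save_config
from .diffusion import TrainConfig, train
from .io import load_checkpoint, save_checkpoint, write_volume
from .metrics import compare
from .model import EmbeddingConfig, NoisePredictor
from .phantoms import generate_dataset
from .schedule import make_schedule
from .synthesis import one_way_synthesize, two_way_synthesize

__all__ = ["run_pipeline", "make_fold_synthesizer"]

logger = logging.getLogger("pseudopet.pipeline")


def make_fold_synthesizer(config: RunConfig, seed: int):
    """Factory for the CV harness: trains a synthesis model on the fold's
    training pairs and returns a per-pair two-way synthesized view."""

    def fold_synthesizer(train_pairs):
        schedule = make_schedule(
            config.schedule.T,
            config.schedule.beta_start,
            config.schedule.beta_end,
            config.schedule.n_sample_steps,
        )
        model = NoisePredictor(
            depth=config.model.depth,
            base_width=config.model.base_width,
            ndim=len(config.phantoms.image_shape),
            emb_config=EmbeddingConfig(config.model.emb_dim, config.model.emb_mp),
            seed=seed,
        )
        train(
            train_pairs,
            model,
            schedule,
            TrainConfig(
                epochs=config.training.epochs,
                batch_size=config.training.batch_size,
                learning_rate=config.training.learning_rate,
                modality_mix=config.training.modality_mix,
                seed=seed,
            ),
        )

        def synth(pair):
            result = two_way_synthesize(
                model, pair.structural, schedule, brain_mask=pair.brain_mask
            )
            return {"functional_synth_two_way": result.functional_hat}

        return synth

    return fold_synthesizer


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    log_rows = []

    def stage(name, outputs, fn, upstream_ran):
        missing = [p for p in outputs if not p.exists()]
        if not missing and not upstream_ran:
            logger.info("stage %s: outputs exist, skipping", name)
            return False
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log_rows.append(
            {"stage": name, "seconds": time.perf_counter() - t0, "seed": config.seed}
        )
        logger.info("stage %s: done in %.1fs", name, log_rows[-1]["seconds"])
        return True

    phantom_cfg = config.phantoms.to_phantom_config(config.seed)
    data_dir = out / "data"
    ckpt = out / "checkpoint.npz"
    synth_dir = out / "synth"
    metrics_csv = out / "metrics.csv"
    cv_csv = out / "cv_results.csv"

    pairs = None

    def _generate():
        nonlocal pairs
        pairs = generate_dataset(phantom_cfg, out_dir=data_dir)

    ran = stage("generate-data", [data_dir / "manifest.csv"], _generate, False)
    if pairs is None:
        pairs = generate_dataset(phantom_cfg)

    schedule = make_schedule(
        config.schedule.T,
        config.schedule.beta_start,
        config.schedule.beta_end,
        config.schedule.n_sample_steps,
    )

    def _train():
        model = NoisePredictor(
            depth=config.model.depth,
            base_width=config.model.base_width,
            ndim=len(phantom_cfg.image_shape),
            emb_config=EmbeddingConfig(config.model.emb_dim, config.model.emb_mp),
            seed=config.seed,
        )
        result = train(
            pairs,
            model,
            schedule,
            TrainConfig(
                epochs=config.training.epochs,
                batch_size=config.training.batch_size,
                learning_rate=config.training.learning_rate,
                modality_mix=config.training.modality_mix,
                seed=config.seed,
            ),
        )
        save_checkpoint(ckpt, result.model, schedule)
        pd.DataFrame({"loss": result.loss_trace}).to_csv(
            out / "loss_trace.csv", index_label="step"
        )

    ran = stage("train", [ckpt], _train, ran)

    def _synthesize():
        model, sched = load_checkpoint(ckpt)
        synth_dir.mkdir(exist_ok=True)
        for i, pair in enumerate(pairs):
            one = one_way_synthesize(model, pair.structural, sched, seed=config.seed + i)
            two = two_way_synthesize(model, pair.structural, sched)
            for result, tag in [(one, "one_way"), (two, "two_way")]:
                path = synth_dir / f"{pair.subject_id}_{tag}.nii"
                write_volume(path, result.functional_hat)
                with open(path.with_suffix(".json"), "w") as fh:
                    json.dump(result.provenance(), fh, indent=2)

    ran = stage("synthesize", [synth_dir], _synthesize, ran)

    def _evaluate():
        from .io import read_volume

        rows = []
        for pair in pairs:
            for tag in ("one_way", "two_way"):
                vol, _ = read_volume(synth_dir / f"{pair.subject_id}_{tag}.nii")
                rep = compare(pair.functional, vol)
                rows.append(
                    {"subject_id": pair.subject_id, "strategy": tag, **rep.as_dict()}
                )
        df = pd.DataFrame(rows)
        summary = (
            df.groupby("strategy")[["mae", "mse", "zncc", "ssim", "psnr"]]
            .agg(["mean", "std"])
        )
        df.to_csv(metrics_csv, index=False)
        summary.to_csv(out / "metrics_summary.csv")

    ran = stage("evaluate", [metrics_csv], _evaluate, ran)

    def _cross_validate():
        tasks = {
            name: tuple(name.split("/")) for name in config.classifier.tasks
        }
        result = cross_validate(
            pairs,
            k=config.classifier.k,
            tasks=tasks,
            views=list(config.classifier.views),
            seed=config.seed,
            branch_config=BranchConfig(
                hidden=config.classifier.hidden, seed=config.seed
            ),
            fold_synthesizer=make_fold_synthesizer(config, config.seed),
        )
        result.table.to_csv(cv_csv, index=False)

    stage("cross-validate", [cv_csv], _cross_validate, ran)

    with open(out / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "stages": log_rows}, fh, indent=2)
    return out
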