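"""End-to-end audit batteries for the bundled use-case presets.

Each battery runs the full protocol (generate → encode → split → fit →
exchange → diagnostics) for one scenario and aggregates the regime-level
quantities the scenario is about. Because single synthetic studies carry
seed-level fluctuation (extrapolated predictions wander pseudo-randomly in
carved-out regions), the number-prompt battery reports medians over a small
number of replicate studies, and the trial-series battery reports medians
over its simulated participants — the same aggregation a simulation study
would publish.
"""

from __future__ import annotations

import numpy as np

from ._utils import derive_seed
from .datasets import StudyDataset, generate_feedback_prompts
from .diagnostics import log_sd_distribution, repeated_random_oos, run_evaluation
from .encoders import SyntheticEncoder
from .presets import PRESETS, build_preset
from .regression import EmbeddingLogisticRidge
from .splits import SplitSpec

__all__ = [
    "usecase1_battery",
    "sd_consistency_battery",
    "trial_prompt_battery",
    "horizon_battery",
]


def _encoder_for(preset, seed: int) -> SyntheticEncoder:
    cfg = {k: v for k, v in preset.encoder.items() if k != "name"}
    return SyntheticEncoder(seed=seed, **cfg)


def _regime_summary(report) -> dict:
    y = report.test_targets
    return {
        "r": report.metrics.r,
        "accuracy": report.metrics.accuracy,
        "sd": report.sd_score,
        "reversal": report.ordinal.reversal,
        "pred_mean": float(report.predictions_from_train.mean()),
        "obs_mean": float(y.mean()),
    }


def usecase1_battery(seed: int, n_studies: int = 7) -> dict:
    """Number-prompt audit (linear and V-shaped targets, four regimes).

    Runs ``n_studies`` replicate studies under sub-seeds of ``seed`` and
    returns, per target shape and regime, the per-study summaries plus
    medians (and the majority reversal verdict).
    """
    regimes = {
        "random": lambda s: SplitSpec("random", fraction=0.33, seed=derive_seed(s, "split")),
        "lowest": lambda s: SplitSpec("quantile", fraction=0.33, region="lowest"),
        "middle": lambda s: SplitSpec("quantile", fraction=0.33, region="middle"),
        "top": lambda s: SplitSpec("quantile", fraction=0.33, region="top"),
    }
    shapes = {"linear": "usecase1-linear", "vshape": "usecase1-vshape"}
    runs = {shape: {name: [] for name in regimes} for shape in shapes}
    target_ranges = []
    for i in range(n_studies):
        sub = derive_seed(seed, "uc1-study", i)
        datasets = {shape: build_preset(pname, sub)[0] for shape, pname in shapes.items()}
        preset = PRESETS["usecase1-linear"]
        enc = _encoder_for(preset, derive_seed(sub, "encoder"))
        emb = enc.encode(datasets["linear"].prompt_set)
        yv = datasets["linear"].behavior.values
        target_ranges.append(float(yv.max() - yv.min()))
        for shape, ds in datasets.items():
            for name, make in regimes.items():
                report = run_evaluation(ds, make(sub), embeddings=emb, seed=sub)
                runs[shape][name].append(_regime_summary(report))
    out = {"target_range": float(np.median(target_ranges)), "n_studies": n_studies,
           "runs": runs, "median": {}}
    for shape in shapes:
        out["median"][shape] = {}
        for name in regimes:
            entries = runs[shape][name]
            out["median"][shape][name] = {
                "r": float(np.median([e["r"] for e in entries])),
                "sd": float(np.median([e["sd"] for e in entries])),
                "reversal": sum(e["reversal"] for e in entries) > n_studies / 2,
                "pred_minus_obs_mean": float(np.median(
                    [e["pred_mean"] - e["obs_mean"] for e in entries])),
            }
    return out


def sd_consistency_battery(seed: int, n_repeats: int = 100, band: float = 0.2):
    """log(SD) distribution across repeated random OOS runs of the linear study."""
    dataset, preset = build_preset("usecase1-linear", seed)
    enc = _encoder_for(preset, derive_seed(seed, "encoder"))
    reports = repeated_random_oos(dataset, n_repeats, fraction=0.33,
                                  encoder=enc, seed=seed)
    return log_sd_distribution([r.sd_score for r in reports], band=band)


def trial_prompt_battery(seed: int, n_participants: int = 30) -> dict:
    """Trial-prompt vs feedback-prompt audit over simulated AR(1) participants.

    For each participant: a random OOS and a top-33% OOD evaluation with
    trial-index prompts, plus a random OOS evaluation with concept-free
    feedback prompts on the identical series. Medians across participants.
    """
    preset = PRESETS["trial-prompt"]
    oos_r, ood_r, ood_sd, feedback_r = [], [], [], []
    for p in range(n_participants):
        sub = derive_seed(seed, "participant", p)
        ds = preset.build(sub)
        enc = _encoder_for(preset, derive_seed(sub, "encoder"))
        emb = enc.encode(ds.prompt_set)
        oos_spec = SplitSpec("random", fraction=0.33, seed=derive_seed(sub, "split"))
        rep = run_evaluation(ds, oos_spec, embeddings=emb, seed=sub)
        oos_r.append(rep.metrics.r)
        rep = run_evaluation(ds, SplitSpec("quantile", fraction=0.33, region="top"),
                             embeddings=emb, seed=sub)
        ood_r.append(rep.metrics.r)
        ood_sd.append(rep.sd_score)
        feedback = generate_feedback_prompts(len(ds), seed=derive_seed(sub, "feedback"))
        ds_fb = StudyDataset(feedback, ds.behavior, seed=ds.seed)
        emb_fb = enc.encode(feedback)
        rep = run_evaluation(ds_fb, oos_spec, embeddings=emb_fb, seed=sub)
        feedback_r.append(rep.metrics.r)
    return {
        "n_participants": n_participants,
        "trial_oos_r": oos_r,
        "trial_ood_r": ood_r,
        "trial_ood_sd": ood_sd,
        "feedback_oos_r": feedback_r,
        "median": {
            "trial_oos_r": float(np.median(oos_r)),
            "trial_ood_r": float(np.median(ood_r)),
            "trial_ood_sd": float(np.median(ood_sd)),
            "feedback_oos_abs_r": float(np.median(np.abs(feedback_r))),
        },
    }


def horizon_battery(seed: int, n_oos_repeats: int = 3) -> dict:
    """Horizon-task audit: random OOS vs remaining-trials condition hold-out."""
    preset = PRESETS["horizon"]
    ds = preset.build(seed)
    enc = _encoder_for(preset, derive_seed(seed, "encoder"))
    emb = enc.encode(ds.prompt_set)
    model = EmbeddingLogisticRidge(
        **{k: v for k, v in preset.regression.items() if k != "lambda_grid"},
        random_state=derive_seed(seed, "model"),
    )
    y = ds.behavior.values
    baseline = float(max(y.mean(), 1.0 - y.mean()))
    oos_acc, oos_sd = [], []
    for i in range(n_oos_repeats):
        spec = SplitSpec("random", fraction=0.33, seed=derive_seed(seed, "oos", i))
        rep = run_evaluation(ds, spec, embeddings=emb, model=model, seed=seed)
        oos_acc.append(rep.metrics.accuracy)
        oos_sd.append(rep.sd_score)
    held = ("h6-r1", "h6-r2", "h6-r3", "h1-r1")
    rep_hold = run_evaluation(ds, SplitSpec("condition", held_out_labels=held),
                              embeddings=emb, model=model, seed=seed)
    return {
        "n_rows": len(ds),
        "majority_baseline": baseline,
        "oos_accuracy": oos_acc,
        "oos_sd": oos_sd,
        "median_oos_accuracy": float(np.median(oos_acc)),
        "median_oos_sd": float(np.median(oos_sd)),
        "holdout_accuracy": float(rep_hold.metrics.accuracy),
        "holdout_sd": float(rep_hold.sd_score),
    }
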