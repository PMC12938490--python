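"""Use-case presets: one fixed configuration per audited scenario.

Each preset bundles the dataset generator, encoder settings, regression
settings and the hold-out regimes that together reproduce one qualitative
phenomenon of embedding-based regression auditing. Docs, tests and the CLI
all draw on these same configurations, so there is exactly one authoritative
parameterization per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from ._utils import derive_seed
from .datasets import (
    StudyDataset,
    generate_autocorrelated_series,
    generate_condition_study,
    generate_feedback_prompts,
    generate_horizon_choices,
    generate_linear_target,
    generate_number_prompts,
    replicate_prompt_set,
    vshape_transform,
)
from .errors import ConfigError

__all__ = ["Preset", "PRESETS", "build_preset", "preset_names"]

# Encoder settings shared by the number-prompt scenarios: a 256-d embedding
# whose similarity range (half a concept unit) is strongly local relative to
# the 0-100 concept grid — adjacent numbers co-activate modestly, distant
# ones only through accidental shared basis centers — with a quarter of the
# coordinates carrying concept-independent distractors.
NUMBER_ENCODER = {
    "name": "synthetic",
    "dim": 256,
    "length_scale": 0.5,
    "distractor_fraction": 0.25,
    "noise_sd": 0.05,
}

# Trial-index prompts get a similarity range of one trial so that adjacent
# trials co-activate strongly — the regime in which trial prompts bind
# series autocorrelation.
TRIAL_ENCODER = dict(NUMBER_ENCODER, length_scale=1.0)

#: The four hold-out regimes of the number-prompt audit.
FOUR_REGIMES = (
    {"strategy": "random", "fraction": 0.33},
    {"strategy": "quantile", "region": "lowest", "fraction": 0.33},
    {"strategy": "quantile", "region": "middle", "fraction": 0.33},
    {"strategy": "quantile", "region": "top", "fraction": 0.33},
)


@dataclass
class Preset:
    name: str
    build: Callable[[int], StudyDataset]
    encoder: dict
    regression: dict
    regimes: tuple
    description: str = ""


def _usecase1_linear(seed: int) -> StudyDataset:
    # 101 number concepts, each rated 30 times with independent noise: the
    # aggregated-ratings reliability structure under which random hold-outs
    # reduce to predicting a stimulus from its own replicates.
    prompts = replicate_prompt_set(generate_number_prompts(0, 100, 1), 30)
    return generate_linear_target(prompts, slope=1.0, intercept=0.0, noise_sd=0.5,
                                  seed=derive_seed(seed, "usecase1", "target"))


def _usecase1_vshape(seed: int) -> StudyDataset:
    ds = _usecase1_linear(seed)
    return ds.with_behavior(vshape_transform(ds.behavior, pivot="median"),
                            vshape_pivot="median")


def _sleep_study(seed: int) -> StudyDataset:
    return generate_condition_study(
        ("none", "moderate", "strong"), (90.0, 70.0, 50.0),
        within_sd=5.0, n_per_condition=20,
        seed=derive_seed(seed, "sleep-study"),
    )


def _trial_series(seed: int) -> StudyDataset:
    return generate_autocorrelated_series(
        n_trials=150, ar_coefficient=0.8, noise_sd=1.0,
        seed=derive_seed(seed, "trial-series"),
    )


def _horizon(seed: int) -> StudyDataset:
    return generate_horizon_choices(
        n_games=500, horizon_lengths=(1, 6),
        first_choice_explore_gap=0.15, exploit_growth=0.1, base_p_best=0.3,
        seed=derive_seed(seed, "horizon"),
    )


PRESETS: dict[str, Preset] = {
    "usecase1-linear": Preset(
        name="usecase1-linear",
        build=_usecase1_linear,
        encoder=NUMBER_ENCODER,
        regression={"lambda_grid": "auto", "k_folds": 10},
        regimes=FOUR_REGIMES,
        description="Number prompts 0-100 with a noisy linear target: "
                    "interpolation succeeds, extrapolation reverses.",
    ),
    "usecase1-vshape": Preset(
        name="usecase1-vshape",
        build=_usecase1_vshape,
        encoder=NUMBER_ENCODER,
        regression={"lambda_grid": "auto", "k_folds": 10},
        regimes=FOUR_REGIMES,
        description="Same prompts with a V-shaped target: fit statistics "
                    "cannot distinguish the shapes.",
    ),
    "sleep-study": Preset(
        name="sleep-study",
        build=_sleep_study,
        encoder={"name": "synthetic", "dim": 128, "length_scale": 0.5,
                 "distractor_fraction": 0.25, "noise_sd": 0.05},
        regression={"lambda_grid": "auto", "k_folds": 10},
        regimes=(
            {"strategy": "random", "fraction": 0.33},
            {"strategy": "condition", "held_out_labels": ("moderate",)},
        ),
        description="Three-condition group study; holding out the middle "
                    "condition is an interpolable hold-out.",
    ),
    "trial-prompt": Preset(
        name="trial-prompt",
        build=_trial_series,
        encoder=TRIAL_ENCODER,
        regression={"lambda_grid": "auto", "k_folds": 10},
        regimes=(
            {"strategy": "random", "fraction": 0.33},
            {"strategy": "quantile", "region": "top", "fraction": 0.33},
        ),
        description="AR(1) trial series prompted as 'This is trial t': "
                    "trial-index embeddings bind autocorrelation.",
    ),
    "horizon": Preset(
        name="horizon",
        build=_horizon,
        encoder={"name": "synthetic", "dim": 256, "length_scale": 1.0,
                 "distractor_fraction": 0.25, "noise_sd": 0.05},
        regression={"lambda_grid": "auto", "k_folds": 5},
        regimes=(
            {"strategy": "random", "fraction": 0.33},
            {"strategy": "condition",
             "held_out_labels": ("h6-r1", "h6-r2", "h6-r3", "h1-r1")},
        ),
        description="Horizon-task choices; withholding the low remaining-"
                    "trials prompts forces concept extrapolation.",
    ),
}


def feedback_variant(dataset: StudyDataset, seed: int) -> StudyDataset:
    """Pair a trial-series dataset with feedback-style prompts.

    Keeps the behavioral series identical and swaps only the prompt set for
    concept-free feedback prompts, so a paired run isolates what the prompt
    template alone contributes.
    """
    prompts = generate_feedback_prompts(len(dataset), derive_seed(seed, "feedback"))
    truth = dict(dataset.truth or {})
    truth["prompt_method"] = "feedback"
    return StudyDataset(prompts, dataset.behavior, truth=truth, seed=dataset.seed)


def preset_names() -> list[str]:
    return sorted(PRESETS)


def build_preset(name: str, seed: int) -> tuple[StudyDataset, Preset]:
    """Instantiate a preset's dataset under a master seed."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; known presets: {preset_names()}")
    preset = PRESETS[name]
    return preset.build(seed), preset
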