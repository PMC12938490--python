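"""Synthetic prompt/behavior generators and their containers.

This module produces the study material every other stage consumes: ordered
prompt collections (:class:`PromptSet`), row-aligned behavioral targets
(:class:`BehaviorVector`), and provenance-carrying bundles of the two
(:class:`StudyDataset`).

The generators emulate the statistical structure of the behavioral settings the
audit framework is designed to probe:

* templated "number" prompts carrying a recognizable scalar concept
  (``"This is number 37"``), with linear or V-shaped concept→behavior mappings;
* multi-condition group studies (e.g. a three-arm sleep-deprivation design)
  where each participant carries an individual prompt;
* trial-wise autocorrelated series standing in for repeatedly measured neural
  activity, prompted as ``"This is trial t"``;
* horizon-task binary choices whose exploit probability rises as fewer trials
  remain, with a short-horizon exploitation offset on the first free choice.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
identical seed and parameters give bit-identical datasets.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import as_1d_float
from .errors import ParameterError, TemplateError, UsageError

__all__ = [
    "PromptSet",
    "BehaviorVector",
    "StudyDataset",
    "generate_number_prompts",
    "generate_linear_target",
    "vshape_transform",
    "generate_condition_study",
    "generate_autocorrelated_series",
    "generate_horizon_choices",
    "generate_feedback_prompts",
    "replicate_prompt_set",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PromptSet:
    """Ordered collection of prompts.

    Parameters
    ----------
    prompts
        One text string per row.
    concept
        Optional per-prompt real scalar: the value embedded in the template
        (the ``n`` of ``"This is number n"``). Required by the synthetic
        encoder; must be finite when present.
    condition
        Optional per-prompt categorical label.
    ids
        Stable, unique per-prompt identifiers. Auto-generated when omitted.
    """

    prompts: list[str]
    concept: Optional[np.ndarray] = None
    condition: Optional[list[str]] = None
    ids: Optional[list[str]] = None

    def __post_init__(self):
        self.prompts = [str(p) for p in self.prompts]
        n = len(self.prompts)
        if self.ids is None:
            self.ids = [f"prompt-{i:05d}" for i in range(n)]
        else:
            self.ids = [str(i) for i in self.ids]
        if len(self.ids) != n:
            raise UsageError("ids must have the same length as prompts")
        if len(set(self.ids)) != n:
            raise UsageError("prompt ids must be unique")
        if self.concept is not None:
            self.concept = as_1d_float(self.concept, "concept")
            if len(self.concept) != n:
                raise UsageError("concept must have the same length as prompts")
            if not np.all(np.isfinite(self.concept)):
                raise UsageError("concept values must all be finite")
        if self.condition is not None:
            self.condition = [str(c) for c in self.condition]
            if len(self.condition) != n:
                raise UsageError("condition must have the same length as prompts")

    def __len__(self) -> int:
        return len(self.prompts)

    def subset(self, idx: Sequence[int]) -> "PromptSet":
        idx = np.asarray(idx, dtype=int)
        return PromptSet(
            prompts=[self.prompts[i] for i in idx],
            concept=None if self.concept is None else self.concept[idx],
            condition=None if self.condition is None else [self.condition[i] for i in idx],
            ids=[self.ids[i] for i in idx],
        )


@dataclass
class BehaviorVector:
    """Per-prompt behavioral target.

    ``mode`` is ``"continuous"`` (real ratings/activations) or ``"binary"``
    ({0, 1} choices).
    """

    values: np.ndarray
    mode: str = "continuous"

    def __post_init__(self):
        self.values = as_1d_float(self.values, "values")
        if self.mode not in ("continuous", "binary"):
            raise UsageError(f"unknown behavior mode: {self.mode!r}")
        if not np.all(np.isfinite(self.values)):
            raise UsageError("behavior values must all be finite")
        if self.mode == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise UsageError("binary behavior must contain only 0/1 values")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, idx: Sequence[int]) -> "BehaviorVector":
        return BehaviorVector(self.values[np.asarray(idx, dtype=int)], self.mode)


@dataclass
class StudyDataset:
    """A prompt set with its row-aligned behavior and generating provenance.

    ``truth``, when present, records the generating parameters (slope,
    condition means, AR coefficient, ...) so parameter-recovery tests can
    compare estimates against them; together with ``seed`` it fully determines
    the generating distribution.
    """

    prompt_set: PromptSet
    behavior: BehaviorVector
    truth: Optional[dict] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.prompt_set) != len(self.behavior):
            raise UsageError("prompt_set and behavior must have the same length")

    def __len__(self) -> int:
        return len(self.prompt_set)

    def with_behavior(self, behavior: BehaviorVector, **truth_updates) -> "StudyDataset":
        truth = dict(self.truth or {})
        truth.update(truth_updates)
        return StudyDataset(self.prompt_set, behavior, truth=truth, seed=self.seed)

    # -- two-file bundle round trip (CSV table + JSON sidecar) --------------

    def to_frame(self) -> pd.DataFrame:
        ps = self.prompt_set
        data = {"id": ps.ids, "prompt": ps.prompts}
        data["concept"] = ps.concept if ps.concept is not None else np.nan
        data["condition"] = ps.condition if ps.condition is not None else ""
        data["target"] = self.behavior.values
        return pd.DataFrame(data)

    def save(self, prefix) -> None:
        """Write ``<prefix>.csv`` (rows) and ``<prefix>.json`` (truth/seed/mode)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        sidecar = {"mode": self.behavior.mode, "truth": self.truth, "seed": self.seed}
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix) -> "StudyDataset":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"), keep_default_na=False, na_values=[""])
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        concept = df["concept"].to_numpy(dtype=float)
        if np.all(np.isnan(concept)):
            concept = None
        condition = df["condition"].astype(str).tolist()
        if all(c in ("", "nan") for c in condition):
            condition = None
        ps = PromptSet(
            prompts=df["prompt"].tolist(),
            concept=concept,
            condition=condition,
            ids=df["id"].tolist(),
        )
        behavior = BehaviorVector(df["target"].to_numpy(dtype=float), sidecar["mode"])
        return cls(ps, behavior, truth=sidecar.get("truth"), seed=sidecar.get("seed"))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _check_template(template: str) -> None:
    fields = [f for _, f, _, _ in string.Formatter().parse(template) if f is not None]
    if len(fields) != 1:
        raise TemplateError(
            f"template must contain exactly one placeholder, found {len(fields)}: {template!r}"
        )


def generate_number_prompts(
    n_min: int,
    n_max: int,
    step: int = 1,
    template: str = "This is number {}",
) -> PromptSet:
    """Deterministic grid of templated prompts carrying a numeric concept.

    One prompt per grid value ``n_min, n_min+step, ..., <= n_max``; the concept
    field is set to the numeric value itself.
    """
    if n_min > n_max:
        raise ParameterError(f"n_min ({n_min}) must not exceed n_max ({n_max})")
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    _check_template(template)
    values = np.arange(n_min, n_max + 1, step)
    prompts = [template.format(v) for v in values]
    ids = [f"num-{v}" for v in values]
    return PromptSet(prompts=prompts, concept=values.astype(float), ids=ids)


def replicate_prompt_set(prompt_set: PromptSet, n_replicates: int) -> PromptSet:
    """Tile a prompt set: each prompt appears ``n_replicates`` times.

    Replicates share text, concept and condition but get distinct ids.
    Together with independent target noise this emulates repeated
    measurements of the same stimulus (data-reliability structure), the
    regime in which random out-of-sample validation reduces to predicting a
    stimulus from its own replicates.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    reps = range(n_replicates)
    return PromptSet(
        prompts=[p for p in prompt_set.prompts for _ in reps],
        concept=None if prompt_set.concept is None
        else np.repeat(prompt_set.concept, n_replicates),
        condition=None if prompt_set.condition is None
        else [c for c in prompt_set.condition for _ in reps],
        ids=[f"{i}-rep{r}" for i in prompt_set.ids for r in reps],
    )


def generate_linear_target(
    prompt_set: PromptSet,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> StudyDataset:
    """Inject a linear concept→behavior relationship with Gaussian noise."""
    if prompt_set.concept is None:
        raise UsageError("generate_linear_target requires a concept field")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = intercept + slope * prompt_set.concept + rng.normal(0.0, noise_sd, len(prompt_set))
    behavior = BehaviorVector(values, "continuous")
    truth = {"kind": "linear", "slope": slope, "intercept": intercept, "noise_sd": noise_sd}
    return StudyDataset(prompt_set, behavior, truth=truth, seed=seed)


def vshape_transform(behavior: BehaviorVector, pivot="median") -> BehaviorVector:
    """Fold a continuous target into a V about ``pivot``, rescaled to its range.

    ``out = a + b * |y - pivot|`` with (a, b) mapping the folded values back
    onto the original ``[min(y), max(y)]`` range. The output is a strictly
    increasing function of ``|y - pivot|``, so it destroys linear
    recoverability of the concept while preserving interpolability.
    """
    if behavior.mode != "continuous":
        raise UsageError("vshape_transform requires a continuous behavior vector")
    y = behavior.values
    p = float(np.median(y)) if isinstance(pivot, str) and pivot == "median" else float(pivot)
    v = np.abs(y - p)
    lo, hi = float(y.min()), float(y.max())
    vlo, vhi = float(v.min()), float(v.max())
    if vhi > vlo:
        out = lo + (v - vlo) * (hi - lo) / (vhi - vlo)
    else:
        # all points equidistant from the pivot: the fold is constant
        out = np.full_like(v, (lo + hi) / 2.0)
    return BehaviorVector(out, "continuous")


def generate_condition_study(
    condition_names: Sequence[str] = ("none", "moderate", "strong"),
    condition_means: Sequence[float] = (90.0, 70.0, 50.0),
    within_sd: float = 5.0,
    n_per_condition: int = 20,
    seed: int = 0,
) -> StudyDataset:
    """Multi-condition group study with individual prompts per participant.

    Each participant receives an individual prompt (a shuffled stimulus-order
    token appended to the condition description), so prompts are unique yet
    condition-similar. Targets are Gaussian around the condition mean. The
    concept scalar is the condition index, mirroring an ordered factor.
    """
    names = [str(n) for n in condition_names]
    means = as_1d_float(condition_means, "condition_means")
    if len(names) != len(means):
        raise UsageError("condition_names and condition_means must have equal length")
    if n_per_condition < 1:
        raise ParameterError("n_per_condition must be >= 1")
    if within_sd < 0:
        raise ParameterError("within_sd must be >= 0")
    rng = np.random.default_rng(seed)
    prompts, concept, condition, ids, values = [], [], [], [], []
    stimuli = list("abcdefghij")
    for ci, (name, mu) in enumerate(zip(names, means)):
        for j in range(n_per_condition):
            order = "".join(rng.permutation(stimuli))
            prompts.append(
                f"In the {name} condition, the participant saw items {order} before the test."
            )
            concept.append(float(ci))
            condition.append(name)
            ids.append(f"{name}-{j:03d}")
            values.append(mu + rng.normal(0.0, within_sd))
    ps = PromptSet(prompts=prompts, concept=np.array(concept), condition=condition, ids=ids)
    behavior = BehaviorVector(np.array(values), "continuous")
    truth = {
        "kind": "condition_study",
        "condition_names": names,
        "condition_means": means.tolist(),
        "within_sd": within_sd,
        "n_per_condition": n_per_condition,
    }
    return StudyDataset(ps, behavior, truth=truth, seed=seed)


def generate_autocorrelated_series(
    n_trials: int = 150,
    ar_coefficient: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
    template: str = "This is trial {}",
) -> StudyDataset:
    """Stationary AR(1) series prompted on the trial-index grid.

    Stands in for trial-wise neural activity: the only structure is that
    nearby trials have correlated values, which is exactly what a
    trial-index prompt can bind to. The series starts from its stationary
    distribution, ``x_1 ~ N(0, noise_sd^2 / (1 - phi^2))``.
    """
    if n_trials < 2:
        raise ParameterError("n_trials must be >= 2")
    if not (-1.0 < ar_coefficient < 1.0):
        raise UsageError(f"ar_coefficient must lie in (-1, 1), got {ar_coefficient}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    _check_template(template)
    rng = np.random.default_rng(seed)
    phi = float(ar_coefficient)
    x = np.empty(n_trials)
    stat_sd = noise_sd / np.sqrt(1.0 - phi**2) if noise_sd > 0 else 0.0
    x[0] = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
    eps = rng.normal(0.0, noise_sd, n_trials - 1)
    for t in range(1, n_trials):
        x[t] = phi * x[t - 1] + eps[t - 1]
    trials = np.arange(1, n_trials + 1)
    ps = PromptSet(
        prompts=[template.format(t) for t in trials],
        concept=trials.astype(float),
        ids=[f"trial-{t:04d}" for t in trials],
    )
    truth = {"kind": "ar1", "ar_coefficient": phi, "noise_sd": noise_sd}
    return StudyDataset(ps, BehaviorVector(x, "continuous"), truth=truth, seed=seed)


def generate_feedback_prompts(n_trials: int, seed: int = 0) -> PromptSet:
    """Feedback-style prompts carrying no trial-index concept.

    Each prompt states only which option was rewarded and by how much, with
    the reward amount drawn i.i.d. — the concept scalar (the amount) is
    unrelated to the trial order, so embeddings of these prompts cannot bind
    trial-wise autocorrelation.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    sides = rng.integers(0, 2, n_trials)
    amounts = rng.integers(1, 10, n_trials)
    prompts = [
        f"The {'left' if s == 0 else 'right'} option was rewarded with {a} points."
        for s, a in zip(sides, amounts)
    ]
    return PromptSet(
        prompts=prompts,
        concept=amounts.astype(float),
        ids=[f"fb-{t:04d}" for t in range(1, n_trials + 1)],
    )


def generate_horizon_choices(
    n_games: int = 500,
    horizon_lengths: Sequence[int] = (1, 6),
    first_choice_explore_gap: float = 0.15,
    exploit_growth: float = 0.1,
    base_p_best: float = 0.3,
    seed: int = 0,
) -> StudyDataset:
    """Simulated horizon-task choices: exploit probability grows with experience.

    Each game in horizon condition ``h`` contributes ``h`` choice rows with
    remaining-trials labels ``h, h-1, ..., 1``. The probability of choosing
    the best option is a linear trend in the number of choices already made
    plus an offset for the shortest horizon's first free choice::

        P(best | h, r) = base_p_best + exploit_growth * (h - r)
                         + first_choice_explore_gap * [h == min(horizon_lengths)]

    so on the first free choice the short horizon exploits more than the long
    one by exactly ``first_choice_explore_gap``, and within the long horizon
    exploitation increases as fewer trials remain — early long-horizon choices
    sit below chance, reflecting directed exploration of the lesser-known
    option. Prompts encode the prior samples of both options and how many
    trials are left; the concept scalar is the remaining-trials count.
    """
    if len(horizon_lengths) == 0:
        raise ParameterError("horizon_lengths must be nonempty")
    horizons = [int(h) for h in horizon_lengths]
    if any(h < 1 for h in horizons):
        raise ParameterError("horizon lengths must be >= 1")
    if n_games < 1:
        raise ParameterError("n_games must be >= 1")
    h_short = min(horizons)
    for h in horizons:
        for r in range(1, h + 1):
            p = base_p_best + exploit_growth * (h - r)
            if h == h_short:
                p += first_choice_explore_gap
            if not (0.0 < p < 1.0):
                raise ParameterError(
                    f"implied P(best) = {p:.3f} outside (0, 1) for horizon {h}, remaining {r}"
                )
    rng = np.random.default_rng(seed)
    prompts, concept, condition, ids, values = [], [], [], [], []
    for h in horizons:
        for g in range(n_games):
            lo, hi = sorted(rng.choice(np.arange(10, 91), size=2, replace=False))
            for r in range(h, 0, -1):
                p = base_p_best + exploit_growth * (h - r)
                if h == h_short:
                    p += first_choice_explore_gap
                prompts.append(
                    f"Option A showed rewards averaging {hi} points and option B "
                    f"averaged {lo} points. There are {r} trials left to play. "
                    "Choose an option."
                )
                concept.append(float(r))
                condition.append(f"h{h}-r{r}")
                ids.append(f"h{h}-g{g:04d}-r{r}")
                values.append(float(rng.random() < p))
    ps = PromptSet(prompts=prompts, concept=np.array(concept), condition=condition, ids=ids)
    behavior = BehaviorVector(np.array(values), "binary")
    truth = {
        "kind": "horizon",
        "n_games": n_games,
        "horizon_lengths": horizons,
        "first_choice_explore_gap": first_choice_explore_gap,
        "exploit_growth": exploit_growth,
        "base_p_best": base_p_best,
    }
    return StudyDataset(ps, behavior, truth=truth, seed=seed)
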