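"""Hold-out regimes: random OOS, target-quantile OOD, condition hold-outs.

Three strategies partition a dataset's rows into disjoint, exhaustive,
nonempty train/test sides:

* ``random`` — classic out-of-sample: a seeded random test fraction whose
  targets still span the training distribution (tests interpolation);
* ``quantile`` — out-of-distribution by construction: the test side is the
  lowest / middle / top fraction of the *target* values, so evaluation
  requires extrapolating (or bridging) in target space;
* ``condition`` — out-of-domain/condition: all rows with the held-out labels
  form the test side.

The train/test *exchange* used by the SD-score diagnostic is expressed as
swapping the sides of a :class:`SplitResult`, so the same machinery serves
fit-on-test reference models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._utils import as_1d_float
from .datasets import BehaviorVector, StudyDataset
from .errors import ConfigError, DegenerateDataError, ParameterError, UsageError

__all__ = [
    "SplitSpec",
    "SplitResult",
    "random_oos",
    "quantile_ood",
    "condition_holdout",
    "make_split",
    "round_half_away",
]

_REGIONS = ("lowest", "middle", "top")


def round_half_away(x: float) -> int:
    """Round with halves away from zero (documented rounding for fraction*n)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SplitSpec:
    """Declarative hold-out regime.

    Exactly the fields required by the strategy may be set:
    ``random`` uses ``fraction`` and ``seed``; ``quantile`` uses ``fraction``
    and ``region``; ``condition`` uses ``held_out_labels``.
    """

    strategy: str
    fraction: Optional[float] = None
    region: Optional[str] = None
    held_out_labels: Optional[tuple] = None
    seed: Optional[int] = None

    def __post_init__(self):
        errors = []
        if self.held_out_labels is not None:
            self.held_out_labels = tuple(str(l) for l in self.held_out_labels)
        if self.strategy == "random":
            if self.fraction is None:
                errors.append("random strategy requires 'fraction'")
            # seed may stay None in a declarative spec; it is then derived
            # from the master seed when the split is materialized
            if self.region is not None or self.held_out_labels is not None:
                errors.append("random strategy takes only 'fraction' and 'seed'")
        elif self.strategy == "quantile":
            if self.fraction is None:
                errors.append("quantile strategy requires 'fraction'")
            if self.region not in _REGIONS:
                errors.append(f"quantile strategy requires region in {_REGIONS}")
            if self.seed is not None or self.held_out_labels is not None:
                errors.append("quantile strategy takes only 'fraction' and 'region'")
        elif self.strategy == "condition":
            if not self.held_out_labels:
                errors.append("condition strategy requires nonempty 'held_out_labels'")
            if self.fraction is not None or self.region is not None or self.seed is not None:
                errors.append("condition strategy takes only 'held_out_labels'")
        else:
            errors.append(f"unknown strategy {self.strategy!r}")
        if self.fraction is not None and not (0.0 < self.fraction < 1.0):
            errors.append(f"fraction must lie in (0, 1), got {self.fraction}")
        if errors:
            raise ConfigError(errors)

    def label(self) -> str:
        if self.strategy == "random":
            return f"random-{self.fraction:g}"
        if self.strategy == "quantile":
            return f"{self.region}-{self.fraction:g}"
        return "holdout-" + ",".join(self.held_out_labels)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "fraction": self.fraction,
            "region": self.region,
            "held_out_labels": list(self.held_out_labels) if self.held_out_labels else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        d = {k: v for k, v in d.items() if v is not None}
        if "held_out_labels" in d:
            d["held_out_labels"] = tuple(d["held_out_labels"])
        return cls(**d)


@dataclass
class SplitResult:
    """Disjoint train/test index sets plus the spec that produced them."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    spec: SplitSpec
    target_summary: Optional[dict] = None

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if len(self.train_idx) == 0 or len(self.test_idx) == 0:
            raise DegenerateDataError("both split sides must be nonempty")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise UsageError("train and test indices overlap")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.test_idx)

    def exchange(self) -> "SplitResult":
        """Swap train and test sides (the SD-score exchange protocol)."""
        summary = None
        if self.target_summary is not None:
            summary = {"train": self.target_summary.get("test"),
                       "test": self.target_summary.get("train")}
        return SplitResult(self.test_idx.copy(), self.train_idx.copy(), self.spec, summary)

    def to_json(self, path=None) -> str:
        payload = {
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "spec": self.spec.to_dict(),
            "target_summary": self.target_summary,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SplitResult":
        source = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(source)
        return cls(
            np.asarray(payload["train_idx"], dtype=int),
            np.asarray(payload["test_idx"], dtype=int),
            SplitSpec.from_dict(payload["spec"]),
            payload.get("target_summary"),
        )


def _summary(y: Optional[np.ndarray], train_idx, test_idx) -> Optional[dict]:
    if y is None:
        return None

    def side(idx):
        vals = y[idx]
        return {"min": float(vals.min()), "max": float(vals.max()),
                "mean": float(vals.mean())}

    return {"train": side(train_idx), "test": side(test_idx)}


def random_oos(n: int, fraction: float, seed: int, y=None) -> SplitResult:
    """Random out-of-sample split: test size = round(fraction * n), seeded."""
    if n < 4:
        raise UsageError(f"random_oos requires n >= 4, got {n}")
    if not (0.0 < fraction < 1.0):
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    k = round_half_away(fraction * n)
    if k < 1 or k >= n:
        raise UsageError(f"degenerate test size {k} for n={n}, fraction={fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = np.sort(perm[:k])
    train = np.sort(perm[k:])
    yv = None if y is None else _coerce_target(y)
    spec = SplitSpec("random", fraction=fraction, seed=seed)
    return SplitResult(train, test, spec, _summary(yv, train, test))


def _coerce_target(y) -> np.ndarray:
    if isinstance(y, BehaviorVector):
        return y.values
    return as_1d_float(y, "y")


def quantile_ood(y, region: str, fraction: float) -> SplitResult:
    """Target-quantile OOD split: test = lowest / middle / top fraction of y.

    Rank-based with ties broken by stable row order; the middle band is
    centered on the median by rank (the low flank keeps the extra row when
    the remainder is odd). For ``top`` the minimum test target is >= the
    maximum train target, and symmetrically for ``lowest``.
    """
    yv = _coerce_target(y)
    if isinstance(y, BehaviorVector) and y.mode != "continuous":
        raise UsageError("quantile_ood requires a continuous target")
    if region not in _REGIONS:
        raise ParameterError(f"region must be one of {_REGIONS}, got {region!r}")
    if not (0.0 < fraction < 1.0):
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(yv)
    if yv.min() == yv.max():
        raise DegenerateDataError("all target values are equal; quantile split undefined")
    k = round_half_away(fraction * n)
    if k < 1 or k >= n:
        raise UsageError(f"degenerate test size {k} for n={n}, fraction={fraction}")
    order = np.argsort(yv, kind="stable")
    if region == "lowest":
        test = order[:k]
    elif region == "top":
        test = order[n - k:]
    else:
        start = (n - k) // 2
        test = order[start:start + k]
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    train = np.nonzero(mask)[0]
    test = np.sort(test)
    spec = SplitSpec("quantile", fraction=fraction, region=region)
    return SplitResult(train, test, spec, _summary(yv, train, test))


def condition_holdout(labels: Sequence[str], held_out, y=None) -> SplitResult:
    """Hold out all rows whose condition label is in ``held_out``."""
    labels = [str(l) for l in labels]
    held = {str(l) for l in (held_out if not isinstance(held_out, str) else [held_out])}
    if not held:
        raise UsageError("held_out must be nonempty")
    observed = set(labels)
    unknown = held - observed
    if unknown:
        raise UsageError(f"held-out labels not present in data: {sorted(unknown)}")
    if held >= observed:
        raise UsageError("held_out must be a proper subset of the observed labels")
    mask = np.array([l in held for l in labels])
    test = np.nonzero(mask)[0]
    train = np.nonzero(~mask)[0]
    yv = None if y is None else _coerce_target(y)
    spec = SplitSpec("condition", held_out_labels=tuple(sorted(held)))
    return SplitResult(train, test, spec, _summary(yv, train, test))


def make_split(spec: SplitSpec, dataset: StudyDataset) -> SplitResult:
    """Apply a declarative split spec to a study dataset."""
    if spec.strategy == "random":
        if spec.seed is None:
            raise UsageError("random split spec has no seed; derive one before use")
        return random_oos(len(dataset), spec.fraction, spec.seed, y=dataset.behavior)
    if spec.strategy == "quantile":
        return quantile_ood(dataset.behavior, spec.region, spec.fraction)
    if spec.strategy == "condition":
        if dataset.prompt_set.condition is None:
            raise UsageError("condition split requires condition labels on the dataset")
        return condition_holdout(
            dataset.prompt_set.condition, spec.held_out_labels, y=dataset.behavior
        )
    raise ConfigError(f"unknown split strategy {spec.strategy!r}")
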