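"""Run configuration: validation, defaults, and the effective-config echo.

A run configuration names the dataset source (a preset or a CSV bundle), the
encoder, the regression settings, the hold-out regimes and a master seed.
Validation resolves every default and collects *all* problems in one pass, so
a broken file reports every issue at once; the normalized ("effective")
configuration is echoed alongside the results, making any run replayable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .presets import PRESETS, preset_names
from .splits import SplitSpec

__all__ = ["RunConfig", "validate_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "dataset": {"preset": "usecase1-linear"},
    "encoder": None,  # None -> the preset's encoder settings
    "regression": None,  # None -> the preset's regression settings
    "splits": None,  # None -> the preset's regimes
    "distance": "l1",
    "ordinal_bins": 6,
    "seed": 0,
    "out_dir": "embaudit-out",
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


@dataclass
class RunConfig:
    """Normalized, fully-resolved run configuration."""

    dataset: dict
    encoder: dict | None
    regression: dict | None
    splits: list[SplitSpec] | None
    distance: str
    ordinal_bins: int
    seed: int
    out_dir: str

    def effective(self) -> dict:
        """The fully-explicit configuration as written next to results."""
        return {
            "dataset": self.dataset,
            "encoder": self.encoder,
            "regression": self.regression,
            "splits": [s.to_dict() for s in self.splits] if self.splits else None,
            "distance": self.distance,
            "ordinal_bins": self.ordinal_bins,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def _validate_dataset(src, errors) -> dict:
    if not isinstance(src, dict):
        errors.append("'dataset' must be a mapping with 'preset' or 'csv'")
        return {}
    src = dict(src)
    preset = src.get("preset")
    csv = src.get("csv")
    if preset is None and csv is None:
        errors.append("'dataset' needs either 'preset' or 'csv'")
    if preset is not None and preset not in PRESETS:
        errors.append(f"unknown preset {preset!r}; known presets: {preset_names()}")
    if csv is not None and not Path(str(csv)).with_suffix(".csv").exists():
        errors.append(f"dataset csv bundle not found: {csv}")
    return src


def validate_config(source) -> RunConfig:
    """Validate a config file/dict; raise ConfigError listing every problem.

    ``source`` may be a path to a YAML file, a YAML string, or a dict. An
    empty file yields the full default configuration.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(str(source))
        text = path.read_text() if path.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"configuration must be a mapping, got {type(raw).__name__}"])

    errors: list[str] = []
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    for key in unknown:
        errors.append(f"unknown configuration key: {key!r}")

    merged = {**DEFAULT_CONFIG, **{k: v for k, v in raw.items() if k in _KNOWN_KEYS}}

    dataset = _validate_dataset(merged["dataset"], errors)

    splits = None
    if merged["splits"] is not None:
        splits = []
        if not isinstance(merged["splits"], (list, tuple)):
            errors.append("'splits' must be a list of split specifications")
        else:
            for i, item in enumerate(merged["splits"]):
                try:
                    splits.append(SplitSpec.from_dict(dict(item)))
                except (ConfigError, TypeError) as exc:
                    errors.append(f"splits[{i}]: {exc}")

    if merged["distance"] not in ("l1", "l2"):
        errors.append(f"distance must be 'l1' or 'l2', got {merged['distance']!r}")
    try:
        ordinal_bins = int(merged["ordinal_bins"])
        if ordinal_bins < 2:
            errors.append("ordinal_bins must be >= 2")
    except (TypeError, ValueError):
        errors.append(f"ordinal_bins must be an integer, got {merged['ordinal_bins']!r}")
        ordinal_bins = 2
    try:
        seed = int(merged["seed"])
    except (TypeError, ValueError):
        errors.append(f"seed must be an integer, got {merged['seed']!r}")
        seed = 0
    for section in ("encoder", "regression"):
        if merged[section] is not None and not isinstance(merged[section], dict):
            errors.append(f"'{section}' must be a mapping")

    if errors:
        raise ConfigError(errors)

    return RunConfig(
        dataset=dataset,
        encoder=merged["encoder"],
        regression=merged["regression"],
        splits=splits,
        distance=merged["distance"],
        ordinal_bins=ordinal_bins,
        seed=seed,
        out_dir=str(merged["out_dir"]),
    )
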