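"""Extrapolation-failure diagnostics: SD score, log-SD consistency, ordinal adequacy.

The central diagnostic is the *SD score*, computed under a train/test
exchange protocol. A model fitted on the training side produces predictions
for the test side; a second model with the identical configuration is then
fitted on the test side itself, giving reference in-sample fitted values for
the very same rows. The SD score is the ratio

    sum of distances(predictions-from-train, test targets)
    -----------------------------------------------------
    sum of distances(fit-on-test,          test targets)

A score of 1 means the transferred weights describe the test data exactly as
well as weights estimated on it — model integrity. Scores well above 1 signal
extrapolation breakdown; scores below 1 (transferred predictions beating the
in-sample fit) warrant inspection. The score is scale-free: rescaling the
target and both prediction vectors by a common positive factor leaves it
unchanged. Across many well-specified splits, log(SD) should be centered on 0.

*Ordinal adequacy* checks whether predictions reproduce an a-priori ordering
of cluster means observed in the data; a *reversal* is an ordering satisfied
in the observed means whose strict inverse holds in the predicted means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from ._utils import as_1d_float, derive_seed
from .datasets import StudyDataset
from .encoders import EmbeddingMatrix, SyntheticEncoder, get_encoder
from .errors import (
    DegenerateDenominatorError,
    EmbauditError,
    ParameterError,
    UsageError,
)
from .regression import (
    EmbeddingLogisticRidge,
    EmbeddingRidge,
    ScoreBundle,
    predict as _predict,
    score as _score,
)
from .splits import SplitResult, SplitSpec, make_split

__all__ = [
    "sd_score",
    "log_sd_distribution",
    "LogSDSummary",
    "ordinal_adequacy",
    "OrdinalVerdict",
    "run_evaluation",
    "EvaluationReport",
    "repeated_random_oos",
    "summarize_reports",
]

#: Relative tolerance below which the SD denominator counts as degenerate.
DENOMINATOR_RTOL = 1e-10


def _distance(a: np.ndarray, b: np.ndarray, distance: str) -> float:
    d = a - b
    if distance == "l1":
        return float(np.abs(d).sum())
    if distance == "l2":
        return float(np.sqrt((d**2).sum()))
    raise ParameterError(f"distance must be 'l1' or 'l2', got {distance!r}")


def sd_score(test_targets, predictions_from_train, reference_fit_on_test,
             distance: str = "l1") -> float:
    """SD score: transferred-prediction error over in-sample reference error.

    ``distance='l1'`` sums absolute deviations (default); ``'l2'`` uses the
    Euclidean norm of the deviation vector. A near-zero denominator (the
    reference model fits the test side essentially perfectly) raises
    :class:`DegenerateDenominatorError` carrying both raw sums — the
    diagnostic is undefined there, not infinite.
    """
    y = as_1d_float(test_targets, "test_targets")
    pred = as_1d_float(predictions_from_train, "predictions_from_train")
    ref = as_1d_float(reference_fit_on_test, "reference_fit_on_test")
    if not (len(y) == len(pred) == len(ref)):
        raise UsageError("all three vectors must have equal length")
    if len(y) < 2:
        raise UsageError("sd_score requires at least 2 test rows")
    num = _distance(pred, y, distance)
    den = _distance(ref, y, distance)
    scale = max(1.0, float(np.abs(y).sum()))
    if den <= DENOMINATOR_RTOL * scale:
        raise DegenerateDenominatorError(
            "SD-score denominator is degenerate (near-perfect reference fit)",
            numerator=num, denominator=den,
        )
    return num / den


@dataclass
class LogSDSummary:
    """Summary of log SD scores across repeated evaluations."""

    mean: float
    sd: float
    n: int
    shapiro_p: Optional[float]
    band: float
    consistent: bool


def log_sd_distribution(scores: Sequence[float], band: float = 0.2) -> LogSDSummary:
    """Summarize log(SD) across runs; consistent models center on 0.

    ``consistent`` is True when the mean log score lies within ``±band`` of 0.
    A Shapiro–Wilk p-value is attached as a normality check when computable.
    """
    arr = as_1d_float(scores, "scores")
    if len(arr) < 2:
        raise UsageError("log_sd_distribution requires at least 2 scores")
    if np.any(arr <= 0):
        raise EmbauditError(
            "non-positive SD score encountered: upstream invariant violated"
        )
    logs = np.log(arr)
    shapiro_p = None
    if len(logs) >= 3 and np.std(logs) > 0:
        shapiro_p = float(stats.shapiro(logs).pvalue)
    mean = float(np.mean(logs))
    return LogSDSummary(
        mean=mean,
        sd=float(np.std(logs, ddof=1)),
        n=len(logs),
        shapiro_p=shapiro_p,
        band=band,
        consistent=bool(abs(mean) <= band),
    )


@dataclass
class OrdinalVerdict:
    """Per-assertion evaluation of an expected cluster-mean ordering.

    ``expected_ordering`` is a list of ``(i, j)`` pairs asserting
    ``mean(cluster i) > mean(cluster j)``. ``observed_holds`` / ``satisfied``
    record whether each assertion holds in the observed / predicted means;
    ``reversal`` is True only if some assertion holds in the observed means
    while its strict inverse holds in the predicted means.
    """

    cluster_ids: list
    observed_means: dict
    predicted_means: dict
    expected_ordering: list
    observed_holds: list
    satisfied: list
    reversal: bool

    def to_dict(self):
        return {
            "cluster_ids": list(self.cluster_ids),
            "observed_means": {str(k): v for k, v in self.observed_means.items()},
            "predicted_means": {str(k): v for k, v in self.predicted_means.items()},
            "expected_ordering": [list(p) for p in self.expected_ordering],
            "observed_holds": list(self.observed_holds),
            "satisfied": list(self.satisfied),
            "reversal": self.reversal,
        }


def ordinal_adequacy(observed, predicted, cluster_ids,
                     expected_ordering) -> OrdinalVerdict:
    """Compare observed vs predicted cluster-mean orderings."""
    obs = as_1d_float(observed.values if hasattr(observed, "values") else observed,
                      "observed")
    pred = as_1d_float(predicted, "predicted")
    clusters = list(cluster_ids)
    if not (len(obs) == len(pred) == len(clusters)):
        raise UsageError("observed, predicted and cluster_ids must have equal length")
    uniq = []
    for c in clusters:
        if c not in uniq:
            uniq.append(c)
    obs_means, pred_means = {}, {}
    carr = np.asarray(clusters, dtype=object)
    for c in uniq:
        mask = carr == c
        if not mask.any():
            raise UsageError(f"cluster {c!r} is empty")
        obs_means[c] = float(obs[mask].mean())
        pred_means[c] = float(pred[mask].mean())
    observed_holds, satisfied = [], []
    reversal = False
    for i, j in expected_ordering:
        if i not in obs_means or j not in obs_means:
            raise UsageError(f"expected ordering references unknown cluster: ({i!r}, {j!r})")
        o = obs_means[i] > obs_means[j]
        p = pred_means[i] > pred_means[j]
        observed_holds.append(bool(o))
        satisfied.append(bool(p))
        if o and pred_means[i] < pred_means[j]:
            reversal = True
    return OrdinalVerdict(
        cluster_ids=uniq,
        observed_means=obs_means,
        predicted_means=pred_means,
        expected_ordering=list(expected_ordering),
        observed_holds=observed_holds,
        satisfied=satisfied,
        reversal=reversal,
    )


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Everything one hold-out regime produced, with full provenance."""

    regime: SplitSpec
    test_idx: np.ndarray
    test_targets: np.ndarray
    predictions_from_train: np.ndarray
    reference_fit_on_test: np.ndarray
    metrics: ScoreBundle
    sd_score: float
    log_sd: float
    ordinal: OrdinalVerdict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "regime": self.regime.to_dict(),
            "test_idx": self.test_idx.tolist(),
            "test_targets": self.test_targets.tolist(),
            "predictions_from_train": self.predictions_from_train.tolist(),
            "reference_fit_on_test": self.reference_fit_on_test.tolist(),
            "metrics": self.metrics.to_dict(),
            "sd_score": self.sd_score,
            "log_sd": self.log_sd,
            "ordinal": self.ordinal.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _default_model(mode: str, seed: int):
    cls = EmbeddingLogisticRidge if mode == "binary" else EmbeddingRidge
    return cls(random_state=seed)


def _rank_bins(values: np.ndarray, n_bins: int) -> list:
    """Assign rows to n_bins rank-based clusters of the observed target."""
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=object)
    bounds = np.linspace(0, len(values), n_bins + 1).astype(int)
    for b in range(n_bins):
        labels[order[bounds[b]:bounds[b + 1]]] = f"bin{b + 1}"
    return labels.tolist()


def run_evaluation(
    dataset: StudyDataset,
    split,
    encoder=None,
    model=None,
    embeddings: Optional[EmbeddingMatrix] = None,
    distance: str = "l1",
    ordinal_bins: int = 6,
    seed: int = 0,
) -> EvaluationReport:
    """Execute the full audit protocol for one hold-out regime.

    encode → split → fit-on-train → predict-on-test → fit-on-test (exchange)
    → correlation/accuracy + SD score + ordinal verdict. The reference model
    uses the identical regression configuration as the main fit. The default
    ordinal check bins *all* rows into ``ordinal_bins`` rank bins of the
    observed target and compares the increasing order of observed bin means
    (asserted a priori) against the model's account of each row — in-sample
    fitted values on the training side, transferred predictions on the test
    side. A model whose extrapolated predictions collapse below the fitted
    values of adjacent training bins flags a reversal, mirroring a
    prediction-vs-fit cluster-mean comparison.

    ``embeddings`` may carry a precomputed matrix for the whole dataset to
    avoid re-encoding across regimes; it must be row-aligned.
    """
    mode = dataset.behavior.mode
    if embeddings is None:
        enc = get_encoder(encoder) if encoder is not None else SyntheticEncoder(
            seed=derive_seed(seed, "encoder")
        )
        embeddings = enc.encode(dataset.prompt_set)
    else:
        embeddings.check_aligned(dataset.prompt_set)
    if model is None:
        model = _default_model(mode, derive_seed(seed, "model"))
    result = split if isinstance(split, SplitResult) else make_split(split, dataset)
    y = dataset.behavior.values
    Xtr = embeddings.matrix[result.train_idx]
    Xte = embeddings.matrix[result.test_idx]
    ytr, yte = y[result.train_idx], y[result.test_idx]

    model_train = clone(model).fit(Xtr, ytr)
    predictions = _predict(model_train, Xte)
    model_test = clone(model).fit(Xte, yte)
    reference = model_test.fitted_values(Xte)

    metrics = _score(predictions, yte, mode)
    sd = sd_score(yte, predictions, reference, distance=distance)
    # Ordinal check across the whole target range: cluster-mean comparison of
    # the model's account of every row (in-sample fit on train rows, transferred
    # predictions on test rows) against the observed means, per rank bin of y.
    n_bins = min(ordinal_bins, len(y))
    full_pred = np.empty(len(y))
    full_pred[result.train_idx] = model_train.fitted_values(Xtr)
    full_pred[result.test_idx] = predictions
    clusters = _rank_bins(y, n_bins)
    uniq = [f"bin{b + 1}" for b in range(n_bins)]
    expected = [(uniq[i + 1], uniq[i]) for i in range(len(uniq) - 1)]
    verdict = ordinal_adequacy(y, full_pred, clusters, expected)
    provenance = {
        "encoder_id": embeddings.encoder_id,
        "distance": distance,
        "seed": seed,
        "lambda_train": model_train.lambda_,
        "lambda_test": model_test.lambda_,
        "model_params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in model.get_params().items()},
        "n_train": int(len(result.train_idx)),
        "n_test": int(len(result.test_idx)),
    }
    return EvaluationReport(
        regime=result.spec,
        test_idx=result.test_idx,
        test_targets=yte,
        predictions_from_train=np.asarray(predictions, dtype=float),
        reference_fit_on_test=np.asarray(reference, dtype=float),
        metrics=metrics,
        sd_score=sd,
        log_sd=float(np.log(sd)),
        ordinal=verdict,
        provenance=provenance,
    )


def repeated_random_oos(
    dataset: StudyDataset,
    n_repeats: int,
    fraction: float = 0.33,
    encoder=None,
    model=None,
    distance: str = "l1",
    seed: int = 0,
) -> list[EvaluationReport]:
    """Run the protocol across many seeded random OOS splits (shared encoding)."""
    enc = get_encoder(encoder) if encoder is not None else SyntheticEncoder(
        seed=derive_seed(seed, "encoder")
    )
    embeddings = enc.encode(dataset.prompt_set)
    reports = []
    for rep in range(n_repeats):
        spec = SplitSpec("random", fraction=fraction, seed=derive_seed(seed, "oos", rep))
        reports.append(
            run_evaluation(dataset, spec, model=model, embeddings=embeddings,
                           distance=distance, seed=seed)
        )
    return reports


def summarize_reports(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """One row per regime: the figure-style tabular summary."""
    rows = []
    for rep in reports:
        m = rep.metrics
        rows.append({
            "regime": rep.regime.label(),
            "n_train": rep.provenance["n_train"],
            "n_test": rep.provenance["n_test"],
            "r": m.r,
            "accuracy": m.accuracy,
            "deviance_r2": m.deviance_r2,
            "sd_score": rep.sd_score,
            "log_sd": rep.log_sd,
            "reversal": rep.ordinal.reversal,
            "lambda_train": rep.provenance["lambda_train"],
            "lambda_test": rep.provenance["lambda_test"],
        })
    return pd.DataFrame(rows)
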