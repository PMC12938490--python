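"""Prompt encoders: synthetic local-similarity embeddings and pluggable adapters.

The audit framework treats an encoder as a black box mapping a
:class:`~embaudit.datasets.PromptSet` to an :class:`EmbeddingMatrix`. The
workhorse here is :class:`SyntheticEncoder`, which emulates the one property
of final-layer language-model embeddings that embedding-based regression
exploits: *local similarity* — prompts carrying nearby concept values produce
nearby vectors, with similarity decaying smoothly with concept distance.

It is built from sparse localized random features of the concept scalar:
each signal coordinate is a sum of Gaussian bumps,
``f_j(c) = sum_k exp(-(c - mu_jk)^2 / (2 * length_scale^2))``, with several
random centers ``mu_jk`` per coordinate spread over the concept range. Two
rows therefore co-activate strongly when their concepts are within about one
``length_scale`` of each other and only weakly (through accidental shared
centers) otherwise — and, because every coordinate has bumps across the whole
range, no coordinate is dormant on any concept subset, mirroring how real
embedding coordinates vary across any prompt sample. A configurable fraction
of coordinates are concept-independent distractors (deterministic
pseudo-random functions of the prompt text), and i.i.d. Gaussian measurement
noise can be added on top. No pretrained weights are involved anywhere.

A real transformer adapter slot exists (`TransformerEncoder`) but raises a
:class:`~embaudit.errors.CapabilityError` when the optional dependency is
absent — never a silent fallback.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_2d_float
from .datasets import PromptSet
from .errors import AlignmentError, CapabilityError, ConfigError, ParameterError, UsageError

__all__ = [
    "EmbeddingMatrix",
    "SyntheticEncoder",
    "FileEncoder",
    "TransformerEncoder",
    "encode",
    "get_encoder",
    "save_embeddings",
    "load_embeddings",
]


@dataclass
class EmbeddingMatrix:
    """n_prompts x dim matrix of encoder activations, row-aligned to a PromptSet."""

    matrix: np.ndarray
    encoder_id: str
    row_ids: list[str]

    def __post_init__(self):
        self.matrix = as_2d_float(self.matrix, "matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise UsageError("embedding matrix contains non-finite entries")
        self.row_ids = [str(r) for r in self.row_ids]
        if len(self.row_ids) != self.matrix.shape[0]:
            raise AlignmentError("row_ids length does not match matrix row count")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx) -> "EmbeddingMatrix":
        idx = np.asarray(idx, dtype=int)
        return EmbeddingMatrix(
            self.matrix[idx], self.encoder_id, [self.row_ids[i] for i in idx]
        )

    def check_aligned(self, prompt_set: PromptSet) -> None:
        if self.row_ids != prompt_set.ids:
            raise AlignmentError("embedding rows are not aligned with the prompt set")


def _text_rng(text: str, seed: int) -> np.random.Generator:
    """Deterministic per-prompt generator keyed on the prompt text."""
    h = hashlib.blake2b(f"{seed}\x00{text}".encode(), digest_size=8)
    return np.random.default_rng(int.from_bytes(h.digest(), "little"))


class SyntheticEncoder(TransformerMixin, BaseEstimator):
    """Concept-smooth synthetic embedding encoder.

    Parameters
    ----------
    dim : int
        Embedding dimensionality (>= 2).
    length_scale : float
        Similarity range in concept units: rows whose concepts differ by much
        more than this are nearly orthogonal in the signal block.
    distractor_fraction : float in [0, 1)
        Fraction of coordinates that carry concept-independent values,
        derived deterministically from the prompt text.
    noise_sd : float
        Standard deviation of i.i.d. Gaussian noise added to every entry.
    n_centers : int
        Number of bump centers per signal coordinate.
    seed : int
        Seed for the random basis, the distractor keying and the noise.
    """

    def __init__(self, dim=256, length_scale=2.0, distractor_fraction=0.25,
                 noise_sd=0.05, n_centers=8, seed=0):
        self.dim = dim
        self.length_scale = length_scale
        self.distractor_fraction = distractor_fraction
        self.noise_sd = noise_sd
        self.n_centers = n_centers
        self.seed = seed

    @property
    def encoder_id(self) -> str:
        return (
            f"synthetic(dim={self.dim},ls={self.length_scale},"
            f"distractor={self.distractor_fraction},noise={self.noise_sd},seed={self.seed})"
        )

    def _validate(self):
        if self.dim < 2:
            raise ParameterError("dim must be >= 2")
        if self.length_scale <= 0:
            raise ParameterError("length_scale must be > 0")
        if not (0.0 <= self.distractor_fraction < 1.0):
            raise ParameterError("distractor_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_centers < 1:
            raise ParameterError("n_centers must be >= 1")

    def _signal_dim(self) -> int:
        return self.dim - int(round(self.distractor_fraction * self.dim))

    def transform(self, concept) -> np.ndarray:
        """Noiseless signal block for an array of concept values (no distractors).

        Bump centers are drawn (seeded) uniformly over the concept range
        padded by two length scales, so boundary concepts are covered as
        densely as interior ones.
        """
        self._validate()
        c = np.asarray(concept, dtype=float).reshape(-1, 1)
        m = self._signal_dim()
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xB0B]))
        lo = c.min() - 2.0 * self.length_scale
        hi = c.max() + 2.0 * self.length_scale
        centers = rng.uniform(lo, hi, (self.n_centers, m))
        out = np.zeros((c.shape[0], m))
        for k in range(self.n_centers):
            out += np.exp(-((c - centers[k][None, :]) ** 2)
                          / (2.0 * self.length_scale**2))
        return out

    def fit(self, X=None, y=None):  # stateless; present for pipeline compatibility
        self._validate()
        return self

    def encode(self, prompt_set: PromptSet) -> EmbeddingMatrix:
        self._validate()
        if prompt_set.concept is None:
            raise UsageError("SyntheticEncoder requires a concept field on the prompt set")
        n = len(prompt_set)
        m = self._signal_dim()
        signal = self.transform(prompt_set.concept)
        n_distract = self.dim - m
        mat = np.empty((n, self.dim))
        mat[:, :m] = signal
        if n_distract:
            for i, text in enumerate(prompt_set.prompts):
                mat[i, m:] = _text_rng(text, int(self.seed)).standard_normal(n_distract)
        if self.noise_sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xA0A]))
            mat += rng.normal(0.0, self.noise_sd, mat.shape)
        return EmbeddingMatrix(mat, self.encoder_id, list(prompt_set.ids))


class FileEncoder:
    """'Encoder' that loads precomputed embeddings from disk and checks alignment."""

    def __init__(self, path):
        self.path = Path(path)

    @property
    def encoder_id(self) -> str:
        return f"file({self.path.name})"

    def encode(self, prompt_set: PromptSet) -> EmbeddingMatrix:
        emb = load_embeddings(self.path)
        if emb.row_ids != prompt_set.ids:
            raise AlignmentError(
                f"embedding rows in {self.path} do not match the prompt set ids"
            )
        return EmbeddingMatrix(emb.matrix, self.encoder_id, emb.row_ids)


class TransformerEncoder:
    """Adapter for a real pretrained transformer encoder (optional capability).

    Pools the final-layer token states by mean pooling — a fixed, documented
    choice. Requires the ``transformers`` package; when it is unavailable the
    constructor raises a :class:`CapabilityError` rather than falling back.
    """

    def __init__(self, model_name: str = "distilbert-base-uncased"):
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "the 'transformers' package is required for TransformerEncoder "
                "but is not installed"
            ) from exc
        self.model_name = model_name

    @property
    def encoder_id(self) -> str:
        return f"transformer({self.model_name},mean-pool)"

    def encode(self, prompt_set: PromptSet) -> EmbeddingMatrix:
        from transformers import AutoModel, AutoTokenizer  # pragma: no cover
        import torch  # pragma: no cover

        tokenizer = AutoTokenizer.from_pretrained(self.model_name)  # pragma: no cover
        model = AutoModel.from_pretrained(self.model_name)  # pragma: no cover
        rows = []  # pragma: no cover
        with torch.no_grad():  # pragma: no cover
            for text in prompt_set.prompts:
                out = model(**tokenizer(text, return_tensors="pt"))
                rows.append(out.last_hidden_state.mean(dim=1).squeeze(0).numpy())
        return EmbeddingMatrix(np.vstack(rows), self.encoder_id, list(prompt_set.ids))  # pragma: no cover


_REGISTRY = {
    "synthetic": SyntheticEncoder,
    "file": FileEncoder,
    "transformer": TransformerEncoder,
}


def get_encoder(spec):
    """Resolve an encoder handle: an encoder object, a name, or a config dict."""
    if not isinstance(spec, (str, dict)) and hasattr(spec, "encode"):
        return spec
    if isinstance(spec, str):
        name, kwargs = spec, {}
    elif isinstance(spec, dict):
        kwargs = dict(spec)
        name = kwargs.pop("name", None)
    else:
        raise ConfigError(f"cannot interpret encoder spec: {spec!r}")
    if name not in _REGISTRY:
        raise ConfigError(
            f"unknown encoder {name!r}; known encoders: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)


def encode(prompt_set: PromptSet, encoder) -> EmbeddingMatrix:
    """Encode a prompt set with a registered encoder handle."""
    return get_encoder(encoder).encode(prompt_set)


# ---------------------------------------------------------------------------
# embedding I/O
# ---------------------------------------------------------------------------


def save_embeddings(emb: EmbeddingMatrix, path) -> None:
    """Write an embedding matrix to delimited text (.csv) or a compressed .npz."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, matrix=emb.matrix, row_ids=np.array(emb.row_ids),
            encoder_id=np.array(emb.encoder_id),
        )
    else:
        import pandas as pd

        df = pd.DataFrame(emb.matrix, columns=[f"e{i}" for i in range(emb.dim)])
        df.insert(0, "id", emb.row_ids)
        df.to_csv(path, index=False)


def load_embeddings(path) -> EmbeddingMatrix:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            return EmbeddingMatrix(
                data["matrix"],
                str(data["encoder_id"]),
                [str(r) for r in data["row_ids"]],
            )
    import pandas as pd

    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ConfigError(f"embedding file {path} lacks an 'id' column")
    ids = df["id"].astype(str).tolist()
    return EmbeddingMatrix(df.drop(columns=["id"]).to_numpy(dtype=float), f"file({path.name})", ids)
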