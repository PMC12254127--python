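"""Protein-language-model embedding of Cas9 variants and the TextCNN head.

A variant's protein sequence is turned into an L x D matrix of per-residue
embeddings (D = 1280 by default, the per-residue width of the ESM2-650M
checkpoint) and condensed by a multi-scale TextCNN: parallel convolutions
with kernel widths {5, 9, 13}, 128 ReLU filters per scale, global max
pooling per filter, a 384-wide concatenation, and a sigmoid fully
connected layer down to the 256-wide representation H_pt that the fusion
stage mixes with the guide representation.

Two embedder backends are provided.  The default ``StubEmbedder`` maps
each residue (optionally hashed with k residues of context) to a fixed
pseudo-random vector derived from a seeded digest, so the whole protein
path is deterministic and reproducible offline.  ``Esm2Embedder`` wraps a
real ESM2 checkpoint when the ``esm`` package is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import F32, Conv1d, Dense, Param, global_max_pool, global_max_pool_backward
from .variants import ProteinSequence

DEFAULT_EMBEDDING_WIDTH = 1280


class EmbedderBackend:
    """Interface: deterministic per-residue embedding of a protein sequence."""

    name: str
    output_width: int
    deterministic: bool = True

    def embed(self, residues: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class StubEmbedder(EmbedderBackend):
    """Deterministic pseudo-random per-residue embedding.

    Each residue context (the residue itself for ``context_k=0``, or the
    window of ``context_k`` neighbours on each side) is hashed together
    with the seed into a fixed D-vector.  Identical sequences always give
    identical matrices; with ``context_k=0`` two sequences differing at
    one residue differ in exactly that row.
    """

    def __init__(self, output_width: int = DEFAULT_EMBEDDING_WIDTH,
                 context_k: int = 0, seed: int = 0):
        self.name = f"stub-w{output_width}-k{context_k}-s{seed}"
        self.output_width = output_width
        self.context_k = context_k
        self.seed = seed
        self._memo: dict[str, np.ndarray] = {}

    def _vector(self, key: str) -> np.ndarray:
        vec = self._memo.get(key)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{self.output_width}:{key}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.output_width).astype(F32)
            self._memo[key] = vec
        return vec

    def embed(self, residues: str) -> np.ndarray:
        if not residues:
            raise ValueError("cannot embed an empty sequence")
        k = self.context_k
        rows = []
        for i in range(len(residues)):
            key = residues[max(0, i - k):i + k + 1] if k else residues[i]
            rows.append(self._vector(key))
        return np.stack(rows)


class Esm2Embedder(EmbedderBackend):
    """Real ESM2 backend (650M checkpoint, 1280-wide); requires ``esm``."""

    def __init__(self, model_name: str = "esm2_t33_650M_UR50D"):
        try:
            import esm  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the 'esm' package is not installed; use the default "
                "StubEmbedder backend for offline runs"
            ) from exc
        import esm as _esm

        self._model, alphabet = getattr(_esm.pretrained, model_name)()
        self._model.eval()
        self._converter = alphabet.get_batch_converter()
        self._layer = self._model.num_layers
        self.name = model_name
        self.output_width = self._model.embed_dim

    def embed(self, residues: str) -> np.ndarray:  # pragma: no cover - needs esm
        import torch

        _, _, toks = self._converter([("seq", residues)])
        with torch.no_grad():
            out = self._model(toks, repr_layers=[self._layer])
        rep = out["representations"][self._layer][0, 1:len(residues) + 1]
        return rep.numpy().astype(F32)


def _digest(residues: str) -> str:
    return hashlib.sha256(residues.encode()).hexdigest()[:32]


def embed_protein(seq: ProteinSequence, backend: EmbedderBackend,
                  cache_dir: str | Path | None = None) -> np.ndarray:
    """Embed a protein as an (L, D) float32 matrix, optionally disk-cached.

    The cache is keyed by (backend name, sequence digest); a JSON manifest
    records the backend name and width of each entry.
    """
    if not seq.residues:
        raise ValueError("cannot embed an empty sequence")
    if cache_dir is None:
        return backend.embed(seq.residues)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = f"{_digest(backend.name)[:8]}_{_digest(seq.residues)}"
    npy = cache_dir / f"{key}.npy"
    manifest_path = cache_dir / "manifest.json"
    if npy.exists():
        return np.load(npy)
    emb = backend.embed(seq.residues)
    np.save(npy, emb)
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[key] = {
        "backend": backend.name,
        "width": int(emb.shape[1]),
        "length": int(emb.shape[0]),
        "sequence_id": seq.id,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return emb


@dataclass(frozen=True)
class TextCnnSpec:
    """Configuration of the multi-scale protein convolution head."""

    kernel_sizes: tuple[int, ...] = (5, 9, 13)
    filters_per_scale: int = 128
    activation: str = "relu"

    def __post_init__(self) -> None:
        if list(self.kernel_sizes) != sorted(set(self.kernel_sizes)):
            raise ValueError("kernel_sizes must be strictly increasing")
        if self.filters_per_scale < 1:
            raise ValueError("filters_per_scale must be >= 1")


class TextCnnEncoder:
    """Multi-scale TextCNN: conv per scale -> global max pool -> sigmoid FC."""

    OUTPUT_WIDTH = 256

    def __init__(self, embedding_width: int, rng: np.random.Generator,
                 spec: TextCnnSpec = TextCnnSpec(), fc_activation: str = "sigmoid"):
        self.spec = spec
        self.embedding_width = embedding_width
        self.convs = [
            Conv1d(embedding_width, spec.filters_per_scale, k, spec.activation, rng)
            for k in spec.kernel_sizes
        ]
        self.concat_width = spec.filters_per_scale * len(spec.kernel_sizes)
        self.fc = Dense(self.concat_width, self.OUTPUT_WIDTH, fc_activation, rng)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for c in self.convs:
            out += c.params()
        return out + self.fc.params()

    def forward(self, emb: np.ndarray):
        """Condense an (L, D) or (1, L, D) embedding to a (1, 256) vector."""
        if emb.ndim == 2:
            emb = emb[None]
        if emb.shape[1] < max(self.spec.kernel_sizes):
            raise ValueError(
                f"sequence of length {emb.shape[1]} is shorter than the "
                f"largest kernel ({max(self.spec.kernel_sizes)})"
            )
        pooled, caches = [], []
        for conv in self.convs:
            fmap, cc = conv.forward(emb.astype(F32, copy=False), need_input_grad=False)
            pool, cp = global_max_pool(fmap)
            pooled.append(pool)
            caches.append((cc, cp))
        concat = np.concatenate(pooled, axis=1)
        out, cf = self.fc.forward(concat)
        return out, (caches, cf)

    def backward(self, cache, dout: np.ndarray) -> None:
        caches, cf = cache
        dconcat = self.fc.backward(cf, dout)
        f = self.spec.filters_per_scale
        for j, (conv, (cc, cp)) in enumerate(zip(self.convs, caches)):
            dpool = np.ascontiguousarray(dconcat[:, j * f:(j + 1) * f])
            dfmap = global_max_pool_backward(cp, dpool)
            conv.backward(cc, dfmap)
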