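"""Dynamic-weight fusion of the guide and protein branches, and training.

The full activity model runs the dual-path CNN over the one-hot guide and
the multi-scale TextCNN over the variant's per-residue protein embedding,
then mixes the two 256-wide representations with a learned per-sample
scalar gate::

    z = concat(H_RNA, H_pt)                  # 512
    w = sigmoid(W2 . relu(W1 . z + b1) + b2) # scalar in (0, 1)
    H_fusion = w * H_RNA + (1 - w) * H_pt    # convex combination

A two-layer head with a final sigmoid maps ``H_fusion`` to the predicted
activity on a [0, 1] scale.  Training minimizes MSE with Adam under a
cosine-annealing warm-restart schedule; activities are min-max scaled to
[0, 1] per training set (the sigmoid head forces a bounded target) and
the scaler is stored with the model.  Cross-variant training simply pools
records from all variants, shuffling them together into every batch.
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .nn import Adam, Dense, F32, Param, cosine_annealing_lr
from .protein_encoder import TextCnnEncoder, TextCnnSpec
from .sgrna_encoder import DualPathEncoder, SgRnaRecord, encode_batch


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class TrainingConfig:
    """Optimization settings; the defaults are the tuned configuration."""

    learning_rate: float = 0.0001
    batch_size: int = 256
    epochs: int = 100
    optimizer: str = "adam"
    loss: str = "mse"
    scheduler: str = "cosine_annealing"
    scheduler_cycle: int = 5
    seed: int = 0


@dataclass(frozen=True)
class GridSpace:
    """Hyperparameter grid searched exhaustively (Cartesian product)."""

    learning_rates: tuple[float, ...] = (0.0001, 0.0005, 0.001, 0.005)
    batch_sizes: tuple[int, ...] = (64, 128, 256, 512)
    epoch_counts: tuple[int, ...] = (50, 100, 200)

    def configs(self, base: TrainingConfig | None = None) -> list[TrainingConfig]:
        base = base or TrainingConfig()
        out = []
        for lr, bs, ep in itertools.product(
            self.learning_rates, self.batch_sizes, self.epoch_counts
        ):
            cfg = copy.deepcopy(base)
            cfg.learning_rate, cfg.batch_size, cfg.epochs = lr, bs, ep
            out.append(cfg)
        return out


@dataclass
class ActivityScaler:
    """Per-dataset min-max scaling of activities onto [0, 1]."""

    minimum: float = 0.0
    maximum: float = 1.0

    @classmethod
    def fit(cls, values: np.ndarray) -> "ActivityScaler":
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi <= lo:
            hi = lo + 1.0  # constant targets: map to 0, invert to the constant
        return cls(lo, hi)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=F32) - F32(self.minimum)) / F32(
            self.maximum - self.minimum
        )

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=np.float64) * (
            self.maximum - self.minimum
        ) + self.minimum


class DynamicWeightFusion:
    """Per-sample scalar gate mixing the two branch representations."""

    HIDDEN = 128

    def __init__(self, width: int, rng: np.random.Generator):
        self.width = width
        self.fc1 = Dense(2 * width, self.HIDDEN, "relu", rng)
        self.fc2 = Dense(self.HIDDEN, 1, "sigmoid", rng)
        # start neutral: w = 0.5 for every sample until the data moves it
        self.fc2.W.value[...] = 0.0

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, h_rna: np.ndarray, h_pt: np.ndarray):
        if h_rna.shape != h_pt.shape:
            raise ValueError(
                f"branch width mismatch: {h_rna.shape} vs {h_pt.shape}"
            )
        z = np.concatenate([h_rna, h_pt], axis=1)
        hidden, c1 = self.fc1.forward(z)
        w, c2 = self.fc2.forward(hidden)  # (n, 1), sigmoid-bounded
        fused = w * h_rna + (1.0 - w) * h_pt
        return fused, w, (c1, c2, h_rna, h_pt, w)

    def backward(self, cache, dfused: np.ndarray):
        c1, c2, h_rna, h_pt, w = cache
        dw = np.sum(dfused * (h_rna - h_pt), axis=1, keepdims=True)
        dh_rna = dfused * w
        dh_pt = dfused * (1.0 - w)
        dhidden = self.fc2.backward(c2, dw)
        dz = self.fc1.backward(c1, dhidden)
        dh_rna += dz[:, :self.width]
        dh_pt += dz[:, self.width:]
        return dh_rna, dh_pt


def fuse(h_rna: np.ndarray, h_pt: np.ndarray,
         gate: DynamicWeightFusion) -> tuple[np.ndarray, np.ndarray]:
    """Functional fusion: returns (H_fusion, w) for (n, width) branch inputs."""
    fused, w, _ = gate.forward(h_rna, h_pt)
    return fused, w


class CasActivityModel:
    """Dual-input sgRNA activity model: guide CNN + protein TextCNN + gate."""

    REPR_WIDTH = 256
    HEAD_HIDDEN = 128

    def __init__(self, embedding_width: int, seed: int = 0,
                 conv_activation: str = "sigmoid",
                 textcnn_spec: TextCnnSpec = TextCnnSpec()):
        self.embedding_width = embedding_width
        self.seed = seed
        self.conv_activation = conv_activation
        rng = np.random.default_rng(seed)
        self.rna_encoder = DualPathEncoder(rng, activation=conv_activation)
        self.protein_encoder = TextCnnEncoder(embedding_width, rng, spec=textcnn_spec)
        self.fusion = DynamicWeightFusion(self.REPR_WIDTH, rng)
        self.head1 = Dense(self.REPR_WIDTH, self.HEAD_HIDDEN, "relu", rng)
        self.head2 = Dense(self.HEAD_HIDDEN, 1, "sigmoid", rng)
        self.variant_embeddings: dict[str, np.ndarray] = {}
        self.scaler = ActivityScaler()

    def params(self) -> list[Param]:
        return (
            self.rna_encoder.params()
            + self.protein_encoder.params()
            + self.fusion.params()
            + self.head1.params()
            + self.head2.params()
        )

    def set_variant_embeddings(self, embeddings: Mapping[str, np.ndarray]) -> None:
        if not embeddings:
            raise ValueError("variant embedding map is empty")
        for name, emb in embeddings.items():
            if emb.ndim != 2 or emb.shape[1] != self.embedding_width:
                raise ValueError(
                    f"embedding for {name!r} has shape {emb.shape}; expected "
                    f"(L, {self.embedding_width})"
                )
        self.variant_embeddings = {
            k: np.asarray(v, dtype=F32) for k, v in embeddings.items()
        }

    def _variant_index(self, names: Sequence[str]):
        unique = sorted(set(names))
        missing = [n for n in unique if n not in self.variant_embeddings]
        if missing:
            raise KeyError(f"no protein embedding for variant(s) {missing}")
        lookup = {n: i for i, n in enumerate(unique)}
        idx = np.array([lookup[n] for n in names])
        return unique, idx

    def forward(self, x: np.ndarray, variant_names: Sequence[str]):
        """Predict scaled activities for a (n, 59, 5) batch; returns (yhat, cache)."""
        unique, idx = self._variant_index(variant_names)
        h_rna, c_rna = self.rna_encoder.forward(x)
        pt_outs, pt_caches = [], []
        for name in unique:
            h, c = self.protein_encoder.forward(self.variant_embeddings[name])
            pt_outs.append(h[0])
            pt_caches.append(c)
        h_pt = np.stack(pt_outs)[idx]
        fused, w, c_fuse = self.fusion.forward(h_rna, h_pt)
        hidden, c_h1 = self.head1.forward(fused)
        out, c_h2 = self.head2.forward(hidden)
        yhat = out[:, 0]
        cache = (c_rna, pt_caches, idx, len(unique), c_fuse, c_h1, c_h2)
        return yhat, cache

    def backward(self, cache, dyhat: np.ndarray) -> None:
        c_rna, pt_caches, idx, n_unique, c_fuse, c_h1, c_h2 = cache
        dhidden = self.head2.backward(c_h2, dyhat[:, None].astype(F32))
        dfused = self.head1.backward(c_h1, dhidden)
        dh_rna, dh_pt = self.fusion.backward(c_fuse, dfused)
        self.rna_encoder.backward(c_rna, dh_rna)
        for u in range(n_unique):
            mask = idx == u
            if mask.any():
                g = dh_pt[mask].sum(axis=0, keepdims=True)
                self.protein_encoder.backward(pt_caches[u], g)

    def predict_scaled(self, records: Sequence[SgRnaRecord],
                       batch_size: int = 512) -> np.ndarray:
        """Predicted activities on the model's internal [0, 1] scale."""
        out = []
        for i in range(0, len(records), batch_size):
            chunk = records[i:i + batch_size]
            x = encode_batch(chunk)
            yhat, _ = self.forward(x, [r.variant_name for r in chunk])
            out.append(yhat)
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, records: Sequence[SgRnaRecord],
                batch_size: int = 512) -> np.ndarray:
        """Predicted activities on the original activity scale."""
        return self.scaler.inverse(self.predict_scaled(records, batch_size))

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a checkpoint: parameter archive + JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for name, emb in self.variant_embeddings.items():
            arrays[f"emb::{name}"] = emb
        np.savez(path / "weights.npz", **arrays)
        sidecar = {
            "embedding_width": self.embedding_width,
            "seed": self.seed,
            "conv_activation": self.conv_activation,
            "textcnn_kernel_sizes": list(self.protein_encoder.spec.kernel_sizes),
            "textcnn_filters": self.protein_encoder.spec.filters_per_scale,
            "scaler": asdict(self.scaler),
            "variants": sorted(self.variant_embeddings),
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CasActivityModel":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text())
        model = cls(
            embedding_width=sidecar["embedding_width"],
            seed=sidecar["seed"],
            conv_activation=sidecar["conv_activation"],
            textcnn_spec=TextCnnSpec(
                kernel_sizes=tuple(sidecar["textcnn_kernel_sizes"]),
                filters_per_scale=sidecar["textcnn_filters"],
            ),
        )
        data = np.load(path / "weights.npz")
        embeddings = {
            k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("emb::")
        }
        if embeddings:
            model.set_variant_embeddings(embeddings)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
        model.scaler = ActivityScaler(**sidecar["scaler"])
        return model


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    import warnings

    with warnings.catch_warnings():
        # constant predictions in early epochs have undefined rank
        # correlation; score them 0 rather than warning every epoch
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def train(train_records: Sequence[SgRnaRecord],
          variant_embeddings: Mapping[str, np.ndarray],
          cfg: TrainingConfig | None = None,
          val_records: Sequence[SgRnaRecord] | None = None,
          model: CasActivityModel | None = None) -> tuple[CasActivityModel, dict]:
    """Train the activity model with Adam + MSE under cosine annealing.

    Records from all variants are pooled and shuffled into every batch.
    When a validation split is given, the checkpoint with the best
    validation Spearman is restored at the end; the returned history holds
    per-epoch train loss, validation loss/Spearman and the schedule.
    """
    cfg = cfg or TrainingConfig()
    if not train_records:
        raise ValueError("training set is empty")
    if not variant_embeddings:
        raise ValueError("variant embedding map is empty")
    widths = {e.shape[1] for e in variant_embeddings.values()}
    if len(widths) != 1:
        raise ValueError(f"inconsistent embedding widths {sorted(widths)}")
    if model is None:
        model = CasActivityModel(embedding_width=widths.pop(), seed=cfg.seed)
    model.set_variant_embeddings(variant_embeddings)

    y_raw = np.array([r.activity for r in train_records])
    model.scaler = ActivityScaler.fit(y_raw)
    y = model.scaler.transform(y_raw)
    x = encode_batch(train_records)
    names = np.array([r.variant_name for r in train_records])
    if val_records is not None:
        y_val = model.scaler.transform(
            np.array([r.activity for r in val_records])
        )

    opt = Adam(model.params(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    history: dict = {"train_loss": [], "val_loss": [], "val_spearman": [], "lr": []}
    best = (-np.inf, None, -1)

    n = len(train_records)
    for epoch in range(cfg.epochs):
        lr = cosine_annealing_lr(epoch, cfg.learning_rate, cfg.scheduler_cycle)
        history["lr"].append(lr)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = x[sel], y[sel]
            yhat, cache = model.forward(xb, list(names[sel]))
            err = yhat - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch offset {start} "
                    f"(lr={lr:.2e}); try a smaller learning rate"
                )
            epoch_loss += loss * len(sel)
            opt.zero_grad()
            model.backward(cache, 2.0 * err / len(sel))
            opt.step(lr=lr)
        history["train_loss"].append(epoch_loss / n)

        if val_records is not None:
            pred = model.predict_scaled(val_records)
            history["val_loss"].append(float(np.mean((pred - y_val) ** 2)))
            rho = _spearman(pred, y_val)
            history["val_spearman"].append(rho)
            if rho > best[0]:
                best = (rho, [p.value.copy() for p in model.params()], epoch)

    if best[1] is not None:
        for p, v in zip(model.params(), best[1]):
            p.value[...] = v
        history["best_epoch"] = best[2]
        history["best_val_spearman"] = best[0]
    return model, history


def grid_search(space: GridSpace,
                train_records: Sequence[SgRnaRecord],
                val_records: Sequence[SgRnaRecord],
                variant_embeddings: Mapping[str, np.ndarray],
                base_cfg: TrainingConfig | None = None) -> tuple[TrainingConfig, list[dict]]:
    """Exhaustive grid search maximizing validation Spearman.

    Returns the best config and the full leaderboard (one dict per config,
    sorted best first).  A diverging configuration scores -inf rather than
    aborting the search.
    """
    if not val_records:
        raise ValueError("grid search requires a non-empty validation split")
    leaderboard = []
    for cfg in space.configs(base_cfg):
        try:
            model, _ = train(train_records, variant_embeddings, cfg,
                             val_records=val_records)
            rho = _spearman(model.predict_scaled(val_records),
                            np.array([r.activity for r in val_records]))
        except TrainingDivergedError as exc:
            rho = -np.inf
            leaderboard.append({**asdict(cfg), "val_spearman": rho,
                                "error": str(exc)})
            continue
        leaderboard.append({**asdict(cfg), "val_spearman": rho})
    leaderboard.sort(key=lambda d: d["val_spearman"], reverse=True)
    best = leaderboard[0]
    best_cfg = copy.deepcopy(base_cfg or TrainingConfig())
    best_cfg.learning_rate = best["learning_rate"]
    best_cfg.batch_size = best["batch_size"]
    best_cfg.epochs = best["epochs"]
    return best_cfg, leaderboard
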