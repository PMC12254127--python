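"""Spearman metric, 7:1:2 splitting, and the deployment-scenario protocols.

The primary metric is the Spearman rank correlation between predicted and
measured activities; with average-tie ranking it reduces exactly to the
classical closed form ``rho = 1 - 6*sum(d_i^2)/(n*(n^2-1))`` on tie-free
data.  Datasets are split 7:1:2 into train/validation/test with a
deterministic floor-then-largest-remainder allocation.  Three deployment
scenarios are modelled on the split variant datasets:

* ``well_established`` — train and test on the large variant datasets only;
* ``newly_identified`` — train on every dataset's training split, test on
  the small variants' test splits (a few labelled guides exist for the
  new variant);
* ``newly_discovered`` — train on the large variants' training splits
  only and test on the *same* small-variant test splits (zero-shot: no
  guide from the new variant is seen in training).

"Small" means a dataset total below a size threshold (default 1500).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fusion_model import TrainingConfig, train
from .sgrna_encoder import SgRnaRecord

#: Dataset totals strictly below this count as "small" (newly identified).
DEFAULT_SIZE_THRESHOLD = 1500

SCENARIOS = ("well_established", "newly_identified", "newly_discovered")


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman rank correlation (average ties) and the sample count."""

    rho: float
    n: int


def spearman(pred: Sequence[float], truth: Sequence[float]) -> SpearmanResult:
    """Spearman correlation of two equal-length score vectors.

    Ranks use the average-tie convention, so the result equals the
    closed-form ``1 - 6*sum(d^2)/(n*(n^2-1))`` whenever no ties occur.
    Constant input has undefined rank correlation and is an error.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    n = pred.size
    if n < 2:
        raise ValueError("Spearman requires at least 2 observations")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("Spearman is undefined for constant input")
    rho = float(stats.spearmanr(pred, truth).statistic)
    return SpearmanResult(rho=rho, n=n)


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Floor-then-largest-remainder apportionment of n items."""
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def split_712(dataset: Sequence[SgRnaRecord], seed: int,
              fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
              ) -> tuple[list[SgRnaRecord], list[SgRnaRecord], list[SgRnaRecord]]:
    """Random 7:1:2 train/validation/test split, reproducible under ``seed``."""
    n = len(dataset)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train, n_val, n_test = _allocate(n, fractions)
    order = np.random.default_rng(seed).permutation(n)
    train_ix = order[:n_train]
    val_ix = order[n_train:n_train + n_val]
    test_ix = order[n_train + n_val:]
    assert len(test_ix) == n_test
    return ([dataset[i] for i in train_ix],
            [dataset[i] for i in val_ix],
            [dataset[i] for i in test_ix])


@dataclass
class ScenarioSplit:
    """Record-level partition realizing one deployment scenario."""

    scenario: str
    train: list[SgRnaRecord]
    val: list[SgRnaRecord]
    test: list[SgRnaRecord]
    small_datasets: list[str]
    large_datasets: list[str]
    seed: int


def classify_datasets(datasets: Mapping[str, Sequence[SgRnaRecord]],
                      size_threshold: int = DEFAULT_SIZE_THRESHOLD
                      ) -> tuple[list[str], list[str]]:
    """Partition dataset names into (small, large) by total record count."""
    small = sorted(n for n, recs in datasets.items() if len(recs) < size_threshold)
    large = sorted(n for n, recs in datasets.items() if len(recs) >= size_threshold)
    return small, large


def build_scenario(datasets: Mapping[str, Sequence[SgRnaRecord]],
                   scenario: str,
                   size_threshold: int = DEFAULT_SIZE_THRESHOLD,
                   seed: int = 0) -> ScenarioSplit:
    """Assemble the train/val/test partition for one deployment scenario.

    Each dataset is first split 7:1:2 with a seed derived from the run
    seed and the dataset name, so the small-variant test memberships are
    identical between the newly_identified and newly_discovered scenarios.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    small, large = classify_datasets(datasets, size_threshold)
    splits = {
        name: split_712(list(recs), seed=_dataset_seed(seed, name))
        for name, recs in datasets.items()
    }
    if scenario == "well_established":
        use_train, use_test = large, large
    elif scenario == "newly_identified":
        use_train, use_test = sorted(datasets), small
    else:  # newly_discovered: zero training data from the small variants
        use_train, use_test = large, small
    if not use_train or not use_test:
        raise ValueError(
            f"scenario {scenario!r} has no qualifying datasets "
            f"(small={small}, large={large})"
        )
    out = ScenarioSplit(scenario=scenario, train=[], val=[], test=[],
                        small_datasets=small, large_datasets=large, seed=seed)
    for name in use_train:
        tr, va, _ = splits[name]
        out.train.extend(tr)
        out.val.extend(va)
    for name in use_test:
        out.test.extend(splits[name][2])
    return out


def _dataset_seed(seed: int, name: str) -> int:
    import hashlib

    digest = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


def run_protocol(strategy: str,
                 datasets: Mapping[str, Sequence[SgRnaRecord]],
                 variant_embeddings: Mapping[str, np.ndarray],
                 cfg: TrainingConfig | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Variant-specific vs cross-variant training over a dataset collection.

    ``variant_specific`` trains one model per dataset on its own training
    split; ``cross_variant`` pools every training split into a single
    model.  Both are evaluated on each dataset's test split.  Returns a
    tidy table (dataset, variant, strategy, n_test, spearman).
    """
    if strategy not in ("variant_specific", "cross_variant"):
        raise ValueError(f"unknown strategy {strategy!r}")
    cfg = cfg or TrainingConfig()
    splits = {
        name: split_712(list(recs), seed=_dataset_seed(seed, name))
        for name, recs in datasets.items()
    }
    rows = []
    if strategy == "cross_variant":
        pooled_train = [r for name in sorted(splits) for r in splits[name][0]]
        pooled_val = [r for name in sorted(splits) for r in splits[name][1]]
        model, _ = train(pooled_train, variant_embeddings, cfg,
                         val_records=pooled_val)
        models = {name: model for name in splits}
    else:
        models = {}
        for name in sorted(splits):
            tr, va, _ = splits[name]
            embs = {v: variant_embeddings[v]
                    for v in {r.variant_name for r in tr}}
            models[name], _ = train(tr, embs, cfg, val_records=va)
    for name in sorted(splits):
        test = splits[name][2]
        pred = models[name].predict_scaled(test)
        res = spearman(pred, [r.activity for r in test])
        rows.append({
            "dataset": name,
            "variant": test[0].variant_name if test else "",
            "strategy": strategy,
            "n_test": res.n,
            "spearman": res.rho,
        })
    return pd.DataFrame(rows)
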