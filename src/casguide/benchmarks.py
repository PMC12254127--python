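"""Desk-scale benchmark conditions for end-to-end model evaluation.

Real multi-variant activity screens run to tens of thousands of guides per
variant; the benchmarks here are the package's fixed desk-scale stand-in:
four toy Cas9-like variants on a 240-aa synthetic parent, 128-wide stub
protein embeddings, and the generator's default planted structure (GC
trend, four-position motif, spread per-variant shifts, latent noise 0.3).
Two regimes are defined:

* the *recovery* benchmark — 500 guides per variant, a pooled 7:1:2 split,
  one cross-variant model; measures how much of the planted signal the
  model recovers on held-out guides;
* the *small-variant* benchmark — three variants keep 500 guides, the
  fourth is subsampled to 150; cross-variant pooling is compared with a
  variant-specific model on the small variant's test split (the regime in
  which pooling demonstrably helps).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from .fusion_model import TrainingConfig
from .protein_encoder import StubEmbedder
from .sgrna_encoder import SgRnaRecord
from .simulate import SimConfig, generate_dataset, make_parent
from .variants import VariantDefinition, apply_mutations, parse_mutation

BENCHMARK_VARIANTS = ("varA", "varB", "varC", "varD")
_VARIANT_TOKENS = {
    "varA": (),
    "varB": ("A10C", "L50W"),
    "varC": ("A10G",),
    "varD": ("L50F", "K100R", "A150V"),
}
PARENT_LENGTH = 240
EMBEDDING_WIDTH = 128
GUIDES_PER_VARIANT = 500
SMALL_VARIANT = "varD"
SMALL_VARIANT_GUIDES = 150  # 7:1:2 split leaves a 30-guide test set

#: Optimization settings for the desk-scale benchmarks (smaller data and a
#: bounded CPU budget call for a larger step and fewer epochs than the
#: full-scale defaults of TrainingConfig).
DESK_TRAINING = dict(learning_rate=0.0003, batch_size=128, epochs=30)


def desk_training_config(seed: int = 0) -> TrainingConfig:
    return TrainingConfig(seed=seed, **DESK_TRAINING)


def benchmark_definitions() -> dict[str, VariantDefinition]:
    return {
        n: VariantDefinition(n, tuple(parse_mutation(t) for t in toks))
        for n, toks in _VARIANT_TOKENS.items()
    }


def benchmark_embeddings(seed: int, width: int = EMBEDDING_WIDTH
                         ) -> dict[str, np.ndarray]:
    """Stub-embedded proteins of the four benchmark variants."""
    defs = benchmark_definitions()
    parent = make_parent(length=PARENT_LENGTH, registry=defs, seed=seed)
    backend = StubEmbedder(output_width=width, seed=seed)
    return {
        name: backend.embed(apply_mutations(parent, d).residues)
        for name, d in defs.items()
    }


def recovery_benchmark(seed: int):
    """500 guides for each of the four variants, default planted structure."""
    cfg = SimConfig(seed=seed, n_guides=GUIDES_PER_VARIANT,
                    variant_names=BENCHMARK_VARIANTS)
    return generate_dataset(cfg)


def small_variant_benchmark(seed: int) -> dict[str, list[SgRnaRecord]]:
    """Per-variant datasets with the small variant subsampled to 150 guides."""
    records, _ = recovery_benchmark(seed)
    datasets: dict[str, list[SgRnaRecord]] = {}
    for r in records:
        datasets.setdefault(r.variant_name, []).append(r)
    rng = np.random.default_rng(seed + 1)
    small = datasets[SMALL_VARIANT]
    keep = rng.choice(len(small), size=SMALL_VARIANT_GUIDES, replace=False)
    datasets[SMALL_VARIANT] = [small[i] for i in sorted(keep)]
    return datasets
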