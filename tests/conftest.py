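"""Shared fixtures: small synthetic proteins, variant sets, and guide data."""

from __future__ import annotations

import numpy as np
import pytest

from casguide.fusion_model import CasActivityModel
from casguide.protein_encoder import StubEmbedder
from casguide.simulate import SimConfig, generate_dataset, make_parent
from casguide.variants import (VariantDefinition, apply_mutations,
                               builtin_registry, parse_mutation)


@pytest.fixture(scope="session")
def parent_1368():
    """Synthetic 1368-aa parent carrying the correct reference residues."""
    return make_parent(length=1368, seed=7)


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


def small_variant_defs() -> dict[str, VariantDefinition]:
    """Four toy variants on a short parent, for fast training tests."""
    tokens = {
        "varA": (),
        "varB": ("A10C", "L50W"),
        "varC": ("A10G",),
        "varD": ("L50F", "K100R", "A150V"),
    }
    return {
        n: VariantDefinition(n, tuple(parse_mutation(t) for t in toks))
        for n, toks in tokens.items()
    }


@pytest.fixture(scope="session")
def small_proteins():
    """Embedded toy variant proteins (240 aa, 64-wide stub embeddings)."""
    defs = small_variant_defs()
    parent = make_parent(length=240, registry=defs, seed=5)
    emb = StubEmbedder(output_width=64, seed=0)
    return {
        name: emb.embed(apply_mutations(parent, d).residues)
        for name, d in defs.items()
    }


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small 2-variant dataset with planted signal (120 records)."""
    cfg = SimConfig(seed=21, n_guides=60, variant_names=("varA", "varB"))
    records, truth = generate_dataset(cfg)
    return records, truth


@pytest.fixture()
def tiny_model(small_proteins):
    model = CasActivityModel(embedding_width=64, seed=0)
    model.set_variant_embeddings(small_proteins)
    return model
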