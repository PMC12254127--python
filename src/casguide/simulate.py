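"""Seeded synthetic multi-variant guide-activity data with planted signal.

Real multi-variant activity screens are large and external; this module
generates stand-in datasets whose structure every other module can
recover: guide sequences are uniform random 20-nt protospacers with an
NGG PAM and a constant 36-nt scaffold, and the activity of guide *i*
assayed with variant *v* is

    activity_i = logistic( beta_gc * (GC_i - 0.5)
                           + sum_m effect_m * [nt at pos_m == favored_m]
                           + gamma_v + eps_i ),    eps ~ N(0, noise_sd)

so activities live in (0, 1) with a GC trend, a planted positional motif,
an additive per-variant shift, and bounded noise.  The noiseless latent
and activity are stored as ground truth next to every dataset.  Parental
proteins are random sequences constrained to carry the correct reference
residue at every registered mutation position, so all built-in variants
apply cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .sgrna_encoder import (PAM_LENGTH, PROTOSPACER_LENGTH, SCAFFOLD_LENGTH,
                            SgRnaRecord, write_guides)
from .variants import (ProteinSequence, VariantDefinition, apply_mutations,
                       builtin_registry, write_fasta)

#: Constant structural scaffold shared by every generated guide (36 nt).
SCAFFOLD = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCT"
assert len(SCAFFOLD) == SCAFFOLD_LENGTH

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NTS = "ACGT"


@dataclass(frozen=True)
class PlantedMotif:
    """One planted positional preference on the protospacer (0-based)."""

    position: int
    nucleotide: str
    effect: float

    def __post_init__(self) -> None:
        if not 0 <= self.position < PROTOSPACER_LENGTH:
            raise ValueError("motif position must lie on the protospacer")
        if self.nucleotide not in _NTS:
            raise ValueError(f"invalid motif nucleotide {self.nucleotide!r}")
        if not np.isfinite(self.effect):
            raise ValueError("motif effect must be finite")


#: Study-condition defaults: a GC trend, a four-position motif, four
#: variants with spread additive shifts, and moderate latent noise.
DEFAULT_MOTIF = (
    PlantedMotif(2, "G", 0.8),
    PlantedMotif(6, "G", 0.8),
    PlantedMotif(11, "C", 0.8),
    PlantedMotif(17, "A", -0.8),
)


@dataclass
class SimConfig:
    """Generator settings; the seed is mandatory and fully determines output."""

    seed: int
    n_guides: int = 500
    variant_names: tuple[str, ...] | None = None  # None -> built-in registry
    motif: tuple[PlantedMotif, ...] = DEFAULT_MOTIF
    gc_effect: float = 4.0
    variant_effects: dict[str, float] | None = None  # None -> evenly spread
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_guides < 1:
            raise ValueError("n_guides must be >= 1")
        if not np.isfinite(self.gc_effect):
            raise ValueError("gc_effect must be finite")
        positions = [m.position for m in self.motif]
        if len(positions) != len(set(positions)):
            raise ValueError("planted motif positions must be distinct")

    def resolved_variants(self) -> list[str]:
        if self.variant_names is not None:
            return list(self.variant_names)
        return sorted(builtin_registry())

    def resolved_effects(self) -> dict[str, float]:
        names = self.resolved_variants()
        if self.variant_effects is not None:
            missing = set(names) - set(self.variant_effects)
            if missing:
                raise ValueError(f"variant_effects missing {sorted(missing)}")
            return dict(self.variant_effects)
        spread = np.linspace(-1.0, 1.0, len(names)) if len(names) > 1 else [0.0]
        return {n: float(g) for n, g in zip(names, spread)}


@dataclass
class GroundTruth:
    """Noiseless structure stored alongside a generated dataset."""

    latent: np.ndarray            # noiseless linear predictor per record
    noiseless_activity: np.ndarray
    gc_content: np.ndarray
    motif: tuple[PlantedMotif, ...]
    variant_effects: dict[str, float]
    config: SimConfig

    def to_json(self) -> str:
        return json.dumps({
            "latent": self.latent.tolist(),
            "noiseless_activity": self.noiseless_activity.tolist(),
            "gc_content": self.gc_content.tolist(),
            "motif": [{"position": m.position, "nucleotide": m.nucleotide,
                       "effect": m.effect} for m in self.motif],
            "variant_effects": self.variant_effects,
            "seed": self.config.seed,
            "n_guides": self.config.n_guides,
            "gc_effect": self.config.gc_effect,
            "noise_sd": self.config.noise_sd,
        })


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_parent(length: int = 1368,
                registry: Mapping[str, VariantDefinition] | None = None,
                seed: int = 0, name: str = "synthetic-parent") -> ProteinSequence:
    """Random parental protein compatible with every registered variant.

    The residue at each registered mutation position is pinned to that
    mutation's reference amino acid; conflicting reference residues at a
    shared position across variants are an error (the built-in registry
    has none).
    """
    registry = builtin_registry() if registry is None else registry
    pinned: dict[int, str] = {}
    for defn in registry.values():
        for mut in defn.mutations:
            prev = pinned.get(mut.position)
            if prev is not None and prev != mut.ref_aa:
                raise ValueError(
                    f"conflicting reference residues at position "
                    f"{mut.position}: {prev} vs {mut.ref_aa}"
                )
            pinned[mut.position] = mut.ref_aa
    if pinned and max(pinned) > length:
        raise ValueError(
            f"parent length {length} is shorter than the largest mutation "
            f"position {max(pinned)}"
        )
    rng = np.random.default_rng(seed)
    residues = rng.choice(list(_AA20), size=length)
    for pos, aa in pinned.items():
        residues[pos - 1] = aa
    return ProteinSequence(id=name, residues="".join(residues))


def generate_dataset(cfg: SimConfig) -> tuple[list[SgRnaRecord], GroundTruth]:
    """Generate ``n_guides`` records per variant with planted structure."""
    rng = np.random.default_rng(cfg.seed)
    names = cfg.resolved_variants()
    effects = cfg.resolved_effects()
    records: list[SgRnaRecord] = []
    latents, noiseless, gcs = [], [], []
    for name in names:
        gamma = effects[name]
        for _ in range(cfg.n_guides):
            proto = "".join(rng.choice(list(_NTS), size=PROTOSPACER_LENGTH))
            pam = rng.choice(list(_NTS)) + "GG"
            seq = proto + pam + SCAFFOLD
            gc = (proto.count("G") + proto.count("C")) / PROTOSPACER_LENGTH
            lp = cfg.gc_effect * (gc - 0.5) + gamma
            for m in cfg.motif:
                if proto[m.position] == m.nucleotide:
                    lp += m.effect
            eps = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            activity = float(_logistic(np.array(lp + eps)))
            records.append(SgRnaRecord(seq, activity, name))
            latents.append(lp)
            noiseless.append(float(_logistic(np.array(lp))))
            gcs.append(gc)
    truth = GroundTruth(
        latent=np.array(latents),
        noiseless_activity=np.array(noiseless),
        gc_content=np.array(gcs),
        motif=cfg.motif,
        variant_effects=effects,
        config=cfg,
    )
    return records, truth


def write_dataset(records: Sequence[SgRnaRecord], truth: GroundTruth,
                  out_dir: str | Path,
                  parent: ProteinSequence | None = None,
                  registry: Mapping[str, VariantDefinition] | None = None) -> None:
    """Write per-variant CSVs, ground truth JSON, and optional FASTAs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_variant: dict[str, list[SgRnaRecord]] = {}
    for r in records:
        by_variant.setdefault(r.variant_name, []).append(r)
    for name, recs in sorted(by_variant.items()):
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
        write_guides(recs, out_dir / f"guides_{safe}.csv")
    (out_dir / "ground_truth.json").write_text(truth.to_json())
    if parent is not None:
        sequences = [parent]
        if registry:
            sequences += [apply_mutations(parent, d)
                          for d in registry.values()]
        write_fasta(sequences, out_dir / "proteins.fasta")
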