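"""Cas9 variant construction from point-mutation specifications.

Engineered Cas9 variants (SpCas9-HF1, eSpCas9(1.1), HypaCas9, SniperCas9,
evoCas9, xCas9) differ from wild-type *S. pyogenes* Cas9 by a handful of
amino-acid substitutions written in the standard ``R661A`` notation
(arginine at residue 661 replaced by alanine, 1-based coordinates).  This
module parses that notation, applies mutation lists to a parental protein
template, diffs sequences back into mutation lists, and ships the built-in
registry of the seven variants used throughout the package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationError(ValueError):
    """Malformed mutation token or inapplicable mutation."""


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single amino-acid substitution, 1-based on the protein."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise MutationError(
                f"unknown amino-acid letter in {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise MutationError(
                f"degenerate substitution {self.ref_aa}{self.position}{self.alt_aa}: "
                "reference and alternate residues are equal"
            )

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class VariantDefinition:
    """A named Cas9 variant as an ordered list of substitutions.

    An empty mutation list denotes the wild type.
    """

    name: str
    mutations: tuple[MutationSpec, ...] = ()

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise MutationError(
                f"variant {self.name!r} has duplicate mutation positions"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def parse_mutation(token: str) -> MutationSpec:
    """Parse a ``<ref><position><alt>`` token such as ``"R661A"``.

    Letters are case-insensitive and normalized to upper case.
    """
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise MutationError(f"malformed mutation token {token!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    try:
        return MutationSpec(ref, pos, alt)
    except MutationError as exc:
        raise MutationError(f"invalid mutation token {token!r}: {exc}") from exc


def apply_mutations(parent: ProteinSequence, defn: VariantDefinition) -> ProteinSequence:
    """Apply a variant's substitutions to the parental template.

    Every mutation's reference residue must match the parent at its position;
    a mismatch signals that the wrong parental template is in use and is a
    hard error.
    """
    residues = list(parent.residues)
    for mut in defn.mutations:
        if mut.position > len(residues):
            raise MutationError(
                f"{mut} out of range for parent {parent.id!r} "
                f"of length {len(residues)}"
            )
        found = residues[mut.position - 1]
        if found != mut.ref_aa:
            raise MutationError(
                f"reference mismatch applying {mut} to {parent.id!r}: "
                f"parent has {found!r} at position {mut.position} "
                "(wrong parental template?)"
            )
        residues[mut.position - 1] = mut.alt_aa
    return ProteinSequence(id=defn.name, residues="".join(residues))


def diff_sequences(a: ProteinSequence, b: ProteinSequence) -> list[MutationSpec]:
    """Minimal per-position substitution list transforming ``a`` into ``b``."""
    if len(a) != len(b):
        raise ValueError(
            f"cannot diff sequences of unequal length ({len(a)} vs {len(b)})"
        )
    return [
        MutationSpec(ra, i + 1, rb)
        for i, (ra, rb) in enumerate(zip(a.residues, b.residues))
        if ra != rb
    ]


# Published mutation lists of the seven SpCas9 variants, relative to the
# wild-type S. pyogenes Cas9 (1368 aa).
_REGISTRY_TOKENS: dict[str, tuple[str, ...]] = {
    "WT-SpCas9": (),
    "SpCas9-HF1": ("N497A", "R661A", "Q695A", "Q926A"),
    "eSpCas9(1.1)": ("K848A", "K1003A", "R1060A"),
    "HypaCas9": ("N692A", "M694A", "Q695A", "H698A"),
    "SniperCas9": ("F539S", "M763I", "K890N"),
    "evoCas9": ("M495V", "Y515N", "K526E", "R661Q"),
    "xCas9": ("A262T", "R324L", "S409I", "E480K", "E543D", "M694I", "E1219V"),
}

#: Expected length of all SpCas9 variant proteins.
CAS9_LENGTH = 1368


def builtin_registry() -> dict[str, VariantDefinition]:
    """The seven built-in SpCas9 variants keyed by name."""
    return {
        name: VariantDefinition(name, tuple(parse_mutation(t) for t in tokens))
        for name, tokens in _REGISTRY_TOKENS.items()
    }


def load_variant_definitions(path: str | Path) -> dict[str, VariantDefinition]:
    """Load variant definitions from a JSON or YAML mapping name -> token list."""
    path = Path(path)
    text = path.read_text()
    raw: Mapping[str, Iterable[str]]
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping of variant name -> mutation list")
    return {
        str(name): VariantDefinition(
            str(name), tuple(parse_mutation(t) for t in (tokens or ()))
        )
        for name, tokens in raw.items()
    }


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file."""
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write protein sequences to a FASTA file."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
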