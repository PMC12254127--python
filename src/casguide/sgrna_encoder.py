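"""sgRNA records, one-hot encoding, and the dual-path CNN guide encoder.

Each guide is a 59-nt record: a 20-nt protospacer, a 3-nt PAM (NGG for
SpCas9) and a constant 36-nt scaffold, together with its measured editing
activity and the Cas9 variant it was assayed with.  Guides are one-hot
encoded over the five-letter alphabet (A, C, G, T, N) and passed through a
two-branch convolutional encoder: a single convolution and a stack of
three convolutions (all kernel 5, padding 2, 64 filters, sigmoid), whose
59x64 outputs are concatenated, flattened (7552 values), pushed through a
2048-unit fully connected layer and linearly projected to a 256-wide
representation H_RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .nn import F32, Conv1d, Dense, Param

SGRNA_LENGTH = 59
PROTOSPACER_LENGTH = 20
PAM_LENGTH = 3
SCAFFOLD_LENGTH = 36

#: Channel order of the one-hot encoding; frozen for reproducibility.
ALPHABET = "ACGTN"
_CHANNEL_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SgRnaRecord:
    """One 59-nt guide with its activity score and variant label."""

    sequence: str
    activity: float
    variant_name: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if seq != self.sequence:
            object.__setattr__(self, "sequence", seq)
        if len(seq) != SGRNA_LENGTH:
            raise ValueError(
                f"sgRNA sequence must be {SGRNA_LENGTH} nt, got {len(seq)}"
            )
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid symbols in sgRNA sequence: {sorted(bad)}")
        if not np.isfinite(self.activity):
            raise ValueError("activity must be finite")

    @property
    def protospacer(self) -> str:
        return self.sequence[:PROTOSPACER_LENGTH]

    @property
    def pam(self) -> str:
        return self.sequence[PROTOSPACER_LENGTH:PROTOSPACER_LENGTH + PAM_LENGTH]

    @property
    def scaffold(self) -> str:
        return self.sequence[PROTOSPACER_LENGTH + PAM_LENGTH:]


def normalize_sequence(seq: str) -> str:
    """Upper-case and map RNA 'U' to DNA 'T'."""
    return seq.strip().upper().replace("U", "T")


def one_hot_encode(record: SgRnaRecord | str) -> np.ndarray:
    """One-hot encode a guide as a 59x5 binary matrix (channels A,C,G,T,N)."""
    seq = record.sequence if isinstance(record, SgRnaRecord) else normalize_sequence(record)
    if len(seq) != SGRNA_LENGTH:
        raise ValueError(f"expected a {SGRNA_LENGTH}-nt sequence, got {len(seq)}")
    mat = np.zeros((SGRNA_LENGTH, len(ALPHABET)), dtype=F32)
    for i, c in enumerate(seq):
        try:
            mat[i, _CHANNEL_INDEX[c]] = 1.0
        except KeyError:
            raise ValueError(f"invalid symbol {c!r} at position {i + 1}") from None
    return mat


def encode_batch(records: Sequence[SgRnaRecord]) -> np.ndarray:
    """Stack one-hot matrices into a (n, 59, 5) array."""
    return np.stack([one_hot_encode(r) for r in records])


def read_guides(path: str | Path, *, strict_length: bool = True,
                sep: str | None = None) -> list[SgRnaRecord]:
    """Read an sgRNA table (CSV/TSV with columns sequence, activity, variant).

    With ``strict_length=False``, foreign-dialect sequences are padded with
    'N' or truncated to 59 nt (a warning is emitted per adjustment).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    missing = {"sequence", "activity", "variant"} - set(cols)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        seq = normalize_sequence(str(row[cols["sequence"]]))
        if len(seq) != SGRNA_LENGTH and not strict_length:
            import warnings

            warnings.warn(
                f"adjusting sequence of length {len(seq)} to {SGRNA_LENGTH} nt"
            )
            seq = seq[:SGRNA_LENGTH].ljust(SGRNA_LENGTH, "N")
        records.append(
            SgRnaRecord(seq, float(row[cols["activity"]]), str(row[cols["variant"]]))
        )
    return records


def write_guides(records: Iterable[SgRnaRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "activity": [r.activity for r in records],
            "variant": [r.variant_name for r in records],
        }
    ).to_csv(path, index=False)


class DualPathEncoder:
    """Two-branch CNN producing the 256-wide guide representation H_RNA.

    Branch 1 is a single convolution; branch 2 stacks three convolutions.
    All use kernel 5, padding 2 and 64 filters with sigmoid activation
    (switchable to ReLU for ablation), preserving the 59-position length.
    """

    CONV_CHANNELS = 64
    KERNEL_SIZE = 5
    FC_HIDDEN = 2048
    OUTPUT_WIDTH = 256

    def __init__(self, rng: np.random.Generator, activation: str = "sigmoid"):
        k, ch = self.KERNEL_SIZE, self.CONV_CHANNELS
        n_in = len(ALPHABET)
        self.single = Conv1d(n_in, ch, k, activation, rng)
        self.stack = [
            Conv1d(n_in, ch, k, activation, rng),
            Conv1d(ch, ch, k, activation, rng),
            Conv1d(ch, ch, k, activation, rng),
        ]
        flat = SGRNA_LENGTH * 2 * ch
        self.fc_hidden = Dense(flat, self.FC_HIDDEN, activation, rng)
        self.fc_out = Dense(self.FC_HIDDEN, self.OUTPUT_WIDTH, "linear", rng)

    def params(self) -> list[Param]:
        out = self.single.params()
        for c in self.stack:
            out += c.params()
        return out + self.fc_hidden.params() + self.fc_out.params()

    def forward(self, x: np.ndarray):
        """Encode a (batch, 59, 5) one-hot tensor to (batch, 256)."""
        if x.ndim != 3 or x.shape[1:] != (SGRNA_LENGTH, len(ALPHABET)):
            raise ValueError(
                f"expected input of shape (n, {SGRNA_LENGTH}, {len(ALPHABET)}), "
                f"got {x.shape}"
            )
        a, ca = self.single.forward(x, need_input_grad=False)
        z, c0 = self.stack[0].forward(x, need_input_grad=False)
        z, c1 = self.stack[1].forward(z)
        b, c2 = self.stack[2].forward(z)
        concat = np.concatenate([a, b], axis=2)
        flat = concat.reshape(x.shape[0], -1)
        h, cf = self.fc_hidden.forward(flat)
        out, co = self.fc_out.forward(h)
        return out, (ca, c0, c1, c2, co, cf, x.shape[0])

    def backward(self, cache, dout: np.ndarray) -> None:
        ca, c0, c1, c2, co, cf, n = cache
        dh = self.fc_out.backward(co, dout)
        dflat = self.fc_hidden.backward(cf, dh)
        dconcat = dflat.reshape(n, SGRNA_LENGTH, 2 * self.CONV_CHANNELS)
        da = dconcat[:, :, :self.CONV_CHANNELS]
        db = np.ascontiguousarray(dconcat[:, :, self.CONV_CHANNELS:])
        self.single.backward(ca, np.ascontiguousarray(da))
        dz = self.stack[2].backward(c2, db)
        dz = self.stack[1].backward(c1, dz)
        self.stack[0].backward(c0, dz)

    def branch_outputs(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return the two 59x64 branch feature maps (for inspection/tests)."""
        a, _ = self.single.forward(x, need_input_grad=False)
        z, _ = self.stack[0].forward(x, need_input_grad=False)
        z, _ = self.stack[1].forward(z)
        b, _ = self.stack[2].forward(z)
        return a, b
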