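"""Handcrafted sgRNA sequence descriptor: 175 named features per guide.

The descriptor covers the feature families known to correlate with guide
efficacy: GC content, mono-/di-/tri-nucleotide composition, melting
temperature (nearest-neighbor thermodynamics), and position-specific
nucleotide indicators.  Composition features are raw counts on the 20-nt
protospacer (a frequency switch is provided); positional indicators are
1-based from the protospacer 5' end and extend one position into the PAM
(the variable N of NGG), giving 21 covered positions.

Breakdown (sums to 175):

====================================  =====
mono-nucleotide counts                    4
dinucleotide counts                      16
trinucleotide counts                     64
GC content                                1
melting temperatures                      6
position-specific indicators (4 x 21)    84
====================================  =====

The six Tm features are: the full 20-nt protospacer, its three segments
(positions 1-5, 6-13, 14-20), the 23-nt protospacer+PAM context, and a
GC-corrected empirical estimate (Marmur-Doty).  Nearest-neighbor Tm uses
the unified DNA stack parameter set (SantaLucia 1998) with the default
strand and salt concentrations recorded in :class:`TmParams`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sgrna_encoder import PROTOSPACER_LENGTH, SgRnaRecord

NUCLEOTIDES = "ACGT"

#: Gas constant in cal/(mol*K).
R_GAS = 1.987

# Unified nearest-neighbor DNA stack parameters (SantaLucia 1998):
# dinucleotide -> (delta_H kcal/mol, delta_S cal/(mol*K)).
_UNIFIED_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)   # per terminal G or C
_INIT_AT = (2.3, 4.1)    # per terminal A or T


@dataclass(frozen=True)
class TmParams:
    """Nearest-neighbor thermodynamic parameters and solution conditions.

    ``dnac1``/``dnac2`` are strand concentrations in nM; ``na_mM`` is the
    monovalent cation concentration in mM (entropy salt correction
    0.368 * (N-1) * ln[Na+]).
    """

    nn_stacks: dict = field(default_factory=lambda: dict(_UNIFIED_NN))
    init_gc: tuple[float, float] = _INIT_GC
    init_at: tuple[float, float] = _INIT_AT
    dnac1: float = 25.0
    dnac2: float = 25.0
    na_mM: float = 50.0

    def __post_init__(self) -> None:
        missing = {a + b for a in NUCLEOTIDES for b in NUCLEOTIDES} - set(self.nn_stacks)
        if missing:
            raise ValueError(f"nn_stacks missing dinucleotides: {sorted(missing)}")


DEFAULT_TM_PARAMS = TmParams()


def melting_temperature(seq: str, params: TmParams = DEFAULT_TM_PARAMS) -> float:
    """Duplex melting temperature in degrees Celsius, nearest-neighbor method.

    Tm = 1000 * dH / (dS + R * ln(C_T/x)) - 273.15, with stack enthalpies and
    entropies summed over adjacent dinucleotides, terminal initiation terms,
    and the SantaLucia entropic salt correction.  The effective strand factor
    is C_T/x = dnac1 - dnac2/2 for non-self-complementary duplexes.
    """
    seq = seq.strip().upper().replace("U", "T")
    if len(seq) < 2:
        raise ValueError("Tm requires a sequence of length >= 2")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"invalid symbols for Tm: {sorted(bad)}")
    d_h, d_s = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        dh, ds = params.init_gc if end in "GC" else params.init_at
        d_h += dh
        d_s += ds
    for i in range(len(seq) - 1):
        dh, ds = params.nn_stacks[seq[i:i + 2]]
        d_h += dh
        d_s += ds
    d_s += 0.368 * (len(seq) - 1) * math.log(params.na_mM / 1000.0)
    k = (params.dnac1 - params.dnac2 / 2.0) * 1e-9
    return (1000.0 * d_h) / (d_s + R_GAS * math.log(k)) - 273.15


def melting_temperature_gc(seq: str) -> float:
    """Empirical GC-corrected Tm estimate (Marmur-Doty): 64.9 + 41*(GC-16.4)/N."""
    seq = seq.strip().upper()
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


_DINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]
_TRINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]
#: Covered positions for the positional indicators: protospacer 1-20 plus
#: the variable PAM 'N' position (21).
N_POSITIONS = PROTOSPACER_LENGTH + 1

FEATURE_VERSION = "1"


def feature_names() -> list[str]:
    """The 175 stable feature labels, in extraction order."""
    names = [f"count_{n}" for n in NUCLEOTIDES]
    names += [f"di_{d}" for d in _DINUCLEOTIDES]
    names += [f"tri_{t}" for t in _TRINUCLEOTIDES]
    names += ["gc_content"]
    names += ["tm_protospacer", "tm_seg_1_5", "tm_seg_6_13", "tm_seg_14_20",
              "tm_protospacer_pam", "tm_gc_empirical"]
    for pos in range(1, N_POSITIONS + 1):
        names += [f"pos_{pos}_{n}" for n in NUCLEOTIDES]
    return names


_FEATURE_NAMES = feature_names()
assert len(_FEATURE_NAMES) == 175


def extract_features(record: SgRnaRecord, *, frequencies: bool = False,
                     tm_params: TmParams = DEFAULT_TM_PARAMS,
                     on_n: str = "error") -> np.ndarray:
    """Compute the 175-feature descriptor of one guide.

    Composition and positional features use the 20-nt protospacer (plus
    the PAM N position for indicators).  ``on_n`` controls handling of an
    'N' in the analysed region: ``"error"`` (default) raises, ``"zero"``
    zero-fills the affected features with a warning.  ``frequencies=True``
    divides each k-mer count by its number of windows.
    """
    proto = record.protospacer
    region = proto + record.pam[0]
    if "N" in region:
        if on_n == "error":
            raise ValueError(
                "protospacer/PAM-N region contains 'N'; pass on_n='zero' to "
                "zero-fill features instead"
            )
        warnings.warn("'N' in protospacer region; affected features zero-filled")

    values: list[float] = []
    for n in NUCLEOTIDES:
        values.append(proto.count(n))
    for d in _DINUCLEOTIDES:
        values.append(_count_kmer(proto, d))
    for t in _TRINUCLEOTIDES:
        values.append(_count_kmer(proto, t))
    if frequencies:
        ln = len(proto)
        for i in range(4):
            values[i] /= ln
        for i in range(4, 20):
            values[i] /= ln - 1
        for i in range(20, 84):
            values[i] /= ln - 2
    values.append((proto.count("G") + proto.count("C")) / len(proto))

    for sub in (proto, proto[0:5], proto[5:13], proto[13:20],
                proto + record.pam):
        values.append(0.0 if "N" in sub else melting_temperature(sub, tm_params))
    values.append(0.0 if "N" in proto else melting_temperature_gc(proto))

    for i in range(N_POSITIONS):
        base = region[i]
        for n in NUCLEOTIDES:
            values.append(1.0 if base == n else 0.0)

    vec = np.asarray(values, dtype=np.float64)
    assert vec.shape == (175,)
    return vec


def _count_kmer(seq: str, kmer: str) -> int:
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] == kmer)


def feature_table(records, **kwargs):
    """Extract features for many guides into a pandas DataFrame."""
    import pandas as pd

    rows = [extract_features(r, **kwargs) for r in records]
    return pd.DataFrame(rows, columns=_FEATURE_NAMES)
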