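"""The 175-feature guide descriptor and nearest-neighbor melting temperature."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casguide.features import (DEFAULT_TM_PARAMS, R_GAS, TmParams,
                               extract_features, feature_names,
                               melting_temperature, melting_temperature_gc)
from casguide.sgrna_encoder import SgRnaRecord

SCAFFOLD36 = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCT"


def _record(proto, pam="AGG", activity=0.5):
    return SgRnaRecord(proto + pam + SCAFFOLD36, activity, "wt")


def test_feature_names_are_175_unique_and_stable():
    names = feature_names()
    assert len(names) == 175
    assert len(set(names)) == 175
    assert names == feature_names()


def test_all_g_protospacer():
    vec = extract_features(_record("G" * 20))
    names = feature_names()
    get = dict(zip(names, vec))
    assert get["gc_content"] == 1.0
    assert [get[f"count_{n}"] for n in "ACGT"] == [0, 0, 20, 0]
    assert get["di_GG"] == 19
    assert get["tri_GGG"] == 18


@settings(max_examples=40, deadline=None)
@given(st.text(alphabet="ACGT", min_size=20, max_size=20))
def test_kmer_sum_identities(proto):
    """Mono/di/tri counts sum to 20/19/18; matches a brute-force recount."""
    vec = extract_features(_record(proto))
    names = feature_names()
    get = dict(zip(names, vec))
    assert sum(get[f"count_{n}"] for n in "ACGT") == 20
    di = [n for n in names if n.startswith("di_")]
    tri = [n for n in names if n.startswith("tri_")]
    assert sum(get[d] for d in di) == 19
    assert sum(get[t] for t in tri) == 18
    # brute-force oracle for a couple of k-mers
    for kmer in ("AC", "GGA"):
        expected = sum(1 for i in range(21 - len(kmer))
                       if proto[i:i + len(kmer)] == kmer)
        key = ("di_" if len(kmer) == 2 else "tri_") + kmer
        assert get[key] == expected
    assert get["gc_content"] == pytest.approx(
        (proto.count("G") + proto.count("C")) / 20)


def test_positional_indicators_one_hot():
    proto = "ACGTACGTACGTACGTACGT"
    vec = extract_features(_record(proto, pam="TGG"))
    get = dict(zip(feature_names(), vec))
    for pos in range(1, 22):
        active = [n for n in "ACGT" if get[f"pos_{pos}_{n}"] == 1.0]
        assert len(active) == 1
        expected = proto[pos - 1] if pos <= 20 else "T"
        assert active[0] == expected


def test_n_in_protospacer_errors_by_default():
    rec = _record("N" + "A" * 19)
    with pytest.raises(ValueError, match="'N'"):
        extract_features(rec)
    with pytest.warns(UserWarning):
        vec = extract_features(rec, on_n="zero")
    assert vec.shape == (175,)


def test_frequencies_switch():
    vec = extract_features(_record("G" * 20), frequencies=True)
    get = dict(zip(feature_names(), vec))
    assert get["count_G"] == 1.0
    assert get["di_GG"] == 1.0


def test_tm_gc_rich_exceeds_at_rich():
    assert melting_temperature("GCGCGCGCGC") > melting_temperature("ATATATATAT")


def test_tm_duplex_symmetry():
    """A duplex and its reverse complement denature at the same temperature."""
    seq = "ATGCGTACGTTAGCCATGAA"
    rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
    assert melting_temperature(seq) == pytest.approx(melting_temperature(rc),
                                                     abs=1e-9)


def test_tm_rejects_bad_input():
    with pytest.raises(ValueError):
        melting_temperature("A")
    with pytest.raises(ValueError):
        melting_temperature("ACGX")


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet="ACGT", min_size=20, max_size=20))
def test_tm_matches_independent_summation(seq):
    """Independent table-lookup oracle of the same unified parameter set."""
    p = DEFAULT_TM_PARAMS
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        ih, is_ = (0.1, -2.8) if end in "GC" else (2.3, 4.1)
        dh += ih
        ds += is_
    for a, b in zip(seq, seq[1:]):
        sh, ss = p.nn_stacks[a + b]
        dh += sh
        ds += ss
    ds += 0.368 * 19 * math.log(p.na_mM / 1000)
    k = (p.dnac1 - p.dnac2 / 2) * 1e-9
    expected = 1000 * dh / (ds + R_GAS * math.log(k)) - 273.15
    assert melting_temperature(seq) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("seq", [
    "ACGTACGTACGTACGTACGT", "GGGGGCCCCCGGGGGCCCCC", "ATTATAATTATATTAATATT",
    "GATTACAGATTACAGATTAC",
])
def test_tm_matches_biopython_nearest_neighbor(seq):
    """Cross-check against an independent nearest-neighbor implementation
    (Biopython, same published unified parameter set and conditions)."""
    from Bio.SeqUtils import MeltingTemp as mt

    p = DEFAULT_TM_PARAMS
    expected = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, dnac1=p.dnac1, dnac2=p.dnac2,
                        Na=p.na_mM, saltcorr=5)
    assert melting_temperature(seq) == pytest.approx(expected, abs=0.05)


def test_tm_params_require_all_stacks():
    with pytest.raises(ValueError, match="missing"):
        TmParams(nn_stacks={"AA": (-7.9, -22.2)})


def test_tm_gc_empirical_monotone_in_gc():
    assert melting_temperature_gc("G" * 20) > melting_temperature_gc("A" * 20)
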