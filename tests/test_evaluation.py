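"""Spearman metric, 7:1:2 splitting, and scenario construction."""

import itertools

import numpy as np
import pytest

from casguide.evaluation import (_allocate, build_scenario, classify_datasets,
                                 spearman, split_712)
from casguide.simulate import SimConfig, generate_dataset


def closed_form_rho(pred, truth):
    """Classical closed form 1 - 6*sum(d^2)/(n*(n^2-1)), tie-free data."""
    n = len(pred)
    rank = lambda v: {x: i + 1 for i, x in enumerate(sorted(v))}
    rp, rt = rank(pred), rank(truth)
    d2 = sum((rp[a] - rt[b]) ** 2 for a, b in zip(pred, truth))
    return 1 - 6 * d2 / (n * (n ** 2 - 1))


def test_spearman_perfect_and_reversed():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)


def test_spearman_worked_example():
    res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res.rho == pytest.approx(0.8, abs=1e-12)
    assert res.n == 5


def test_spearman_errors():
    with pytest.raises(ValueError, match="length"):
        spearman([1, 2], [1, 2, 3])
    with pytest.raises(ValueError, match="at least 2"):
        spearman([1], [1])
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1], [1, 2, 3])


def test_spearman_matches_closed_form_exhaustively():
    """Agreement with the closed form to 1e-12 over all permutations, n<=6."""
    for n in range(2, 7):
        base = list(range(1, n + 1))
        for perm in itertools.permutations(base):
            assert spearman(base, list(perm)).rho == pytest.approx(
                closed_form_rho(base, list(perm)), abs=1e-12)


def test_spearman_monotone_transform_invariance():
    rng = np.random.default_rng(0)
    a, b = rng.random(50), rng.random(50)
    base = spearman(a, b).rho
    assert spearman(np.exp(5 * a), b).rho == pytest.approx(base, abs=1e-12)
    assert spearman(a, b ** 3 + 7).rho == pytest.approx(base, abs=1e-12)


def test_allocate_is_exact_and_exhaustive():
    for n in (10, 97, 1000, 5546):
        sizes = _allocate(n, (0.7, 0.1, 0.2))
        assert sum(sizes) == n
    assert _allocate(1000, (0.7, 0.1, 0.2)) == [700, 100, 200]
    # frozen from the floor-then-largest-remainder rule itself
    assert _allocate(5546, (0.7, 0.1, 0.2)) == [3882, 555, 1109]


def test_split_712_sizes_disjoint_reproducible():
    cfg = SimConfig(seed=2, n_guides=500, variant_names=("v1", "v2"))
    records, _ = generate_dataset(cfg)
    tr, va, te = split_712(records, seed=9)
    assert (len(tr), len(va), len(te)) == (700, 100, 200)
    ids = lambda part: {id(r) for r in part}
    assert not (ids(tr) & ids(te)) and not (ids(tr) & ids(va))
    tr2, va2, te2 = split_712(records, seed=9)
    assert [r.sequence for r in tr] == [r.sequence for r in tr2]
    assert [r.sequence for r in te] == [r.sequence for r in te2]


def test_split_712_too_few_records():
    cfg = SimConfig(seed=1, n_guides=5, variant_names=("v",))
    records, _ = generate_dataset(cfg)
    with pytest.raises(ValueError, match="at least 10"):
        split_712(records[:5], seed=0)


def _collection(seed=4):
    """Two large and two small synthetic variant datasets."""
    datasets = {}
    for name, n in (("bigA", 300), ("bigB", 280), ("smallC", 40), ("smallD", 60)):
        cfg = SimConfig(seed=seed + sum(map(ord, name)), n_guides=n,
                        variant_names=(name,))
        datasets[name], _ = generate_dataset(cfg)
    return datasets


def test_classify_datasets_by_threshold():
    small, large = classify_datasets(_collection(), size_threshold=100)
    assert small == ["smallC", "smallD"]
    assert large == ["bigA", "bigB"]


def test_newly_discovered_excludes_small_variants():
    datasets = _collection()
    split = build_scenario(datasets, "newly_discovered", size_threshold=100,
                           seed=1)
    small_seqs = {r.sequence for n in ("smallC", "smallD") for r in datasets[n]}
    assert not any(r.sequence in small_seqs for r in split.train)
    assert split.test  # tested on the small variants


def test_identified_and_discovered_share_test_sets():
    datasets = _collection()
    a = build_scenario(datasets, "newly_identified", size_threshold=100, seed=3)
    b = build_scenario(datasets, "newly_discovered", size_threshold=100, seed=3)
    key = lambda split: sorted((r.sequence, r.variant_name) for r in split.test)
    assert key(a) == key(b)
    # but the identified scenario trains on small-variant records too
    assert len(a.train) > len(b.train)


def test_well_established_uses_large_only():
    datasets = _collection()
    split = build_scenario(datasets, "well_established", size_threshold=100,
                           seed=0)
    variants = {r.variant_name for r in split.train} | {
        r.variant_name for r in split.test}
    assert variants == {"bigA", "bigB"}


def test_scenario_train_test_disjoint():
    datasets = _collection()
    for scenario in ("well_established", "newly_identified", "newly_discovered"):
        split = build_scenario(datasets, scenario, size_threshold=100, seed=5)
        train_keys = {(r.sequence, r.variant_name) for r in split.train}
        test_keys = {(r.sequence, r.variant_name) for r in split.test}
        assert not (train_keys & test_keys)


def test_scenario_without_qualifying_datasets():
    datasets = {k: v for k, v in _collection().items() if k.startswith("big")}
    with pytest.raises(ValueError, match="no qualifying"):
        build_scenario(datasets, "newly_identified", size_threshold=100)
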