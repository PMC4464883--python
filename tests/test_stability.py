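import json
from fractions import Fraction

import numpy as np
import pytest

from boostsel.learners import linear
from boostsel.stability import (
    SelectionFrequencies,
    StabSelResult,
    SubsampleScheme,
    draw_subsamples,
    rethreshold,
    selection_frequencies,
    stability_paths,
    stable_set,
    stabsel,
)

# -- subsampling ------------------------------------------------------------


def test_cp_even_split_covers_everything():
    sets = draw_subsamples(10, SubsampleScheme("complementary_pairs", 1, 3))
    assert len(sets) == 2
    a, b = map(set, sets)
    assert len(a) == len(b) == 5
    assert a.isdisjoint(b)
    assert a | b == set(range(10))


def test_cp_odd_n_leaves_one_out():
    sets = draw_subsamples(11, SubsampleScheme("complementary_pairs", 1, 3))
    a, b = map(set, sets)
    assert len(a) == len(b) == 5
    assert a.isdisjoint(b)
    assert len(a | b) == 10


def test_mb_sizes():
    sets = draw_subsamples(21, SubsampleScheme("mb", 7, 0))
    assert len(sets) == 7
    assert all(len(s) == 10 for s in sets)


def test_subsample_determinism():
    s1 = draw_subsamples(30, SubsampleScheme("complementary_pairs", 5, 42))
    s2 = draw_subsamples(30, SubsampleScheme("complementary_pairs", 5, 42))
    for a, b in zip(s1, s2):
        np.testing.assert_array_equal(a, b)


def test_subsample_n_too_small():
    with pytest.raises(ValueError):
        draw_subsamples(1, SubsampleScheme())


def test_scheme_validation():
    with pytest.raises(ValueError):
        SubsampleScheme("bootstrap", 10, 0)
    with pytest.raises(ValueError):
        SubsampleScheme("mb", 0, 0)


# -- frequencies and stable set --------------------------------------------


def test_selection_frequencies_hand_count():
    sets = [{"1", "2"}, {"1"}, {"1", "3"}, {"1"}]
    freqs = selection_frequencies(sets, ["1", "2", "3", "4"])
    assert freqs["1"] == 1.0
    assert freqs["2"] == 0.25
    assert freqs["3"] == 0.25
    assert freqs["4"] == 0.0
    assert freqs.n_fits == 4


def test_selection_frequencies_unknown_id():
    with pytest.raises(ValueError, match="outside universe"):
        selection_frequencies([{"zzz"}], ["a", "b"])


def test_selection_frequencies_empty():
    with pytest.raises(ValueError):
        selection_frequencies([], ["a"])


def test_frequencies_on_grid():
    sets = [{"a"}, {"a", "b"}, {"b"}, {"a"}, {"a", "b"}, {"b"}]
    freqs = selection_frequencies(sets, ["a", "b", "c"])
    for frac in freqs.as_fractions().values():
        assert isinstance(frac, Fraction)
        assert frac.denominator in (1, 2, 3, 6)  # divisors of n_fits


def test_stable_set_inclusive_threshold():
    freqs = SelectionFrequencies({"1": 1.0, "2": 0.97, "3": 0.5}, 100)
    assert stable_set(freqs, 0.87) == {"1", "2"}
    assert stable_set(freqs, 1.0) == {"1"}
    assert stable_set(SelectionFrequencies({"x": 0.87}, 100), 0.87) == {"x"}


def test_stable_set_threshold_validation():
    freqs = SelectionFrequencies({"1": 1.0}, 10)
    with pytest.raises(ValueError):
        stable_set(freqs, 0.5)
    with pytest.raises(ValueError):
        stable_set(freqs, 1.1)


# -- stabsel ----------------------------------------------------------------


def _signal_data(seed=0, n=100, p=10, k=1, coef=3.0):
    gen = np.random.default_rng(seed)
    X = gen.standard_normal((n, p))
    y = coef * X[:, :k].sum(axis=1) + gen.standard_normal(n)
    return X, y


def test_stabsel_requires_exactly_two_parameters():
    X, y = _signal_data()
    learners = [linear(j) for j in range(10)]
    with pytest.raises(ValueError, match="exactly two"):
        stabsel(X, y, "gaussian", learners, q=2)
    with pytest.raises(ValueError, match="exactly two"):
        stabsel(X, y, "gaussian", learners, q=2, pi_thr=0.8, pfer_max=1.0)


def test_stabsel_case_study_resolution():
    # 57 learners, q=10, PFER<=1, B=50 -> unimodal cutoff 0.87
    gen = np.random.default_rng(5)
    X = gen.standard_normal((40, 57))
    y = gen.standard_normal(40)
    res = stabsel(
        X, y, "gaussian", [linear(j) for j in range(57)],
        q=10, pfer_max=1.0, assumption="unimodal",
        scheme=SubsampleScheme("complementary_pairs", 50, 7),
    )
    assert res.pi_thr == pytest.approx(0.87)
    assert res.realized_bound == pytest.approx(0.9632, abs=1e-4)
    assert res.frequencies.n_fits == 100


def test_stabsel_frequencies_sum_to_q():
    # every fit selects exactly q distinct learners -> sum of freqs == q
    X, y = _signal_data(seed=2, k=2)
    res = stabsel(
        X, y, "gaussian", [linear(j) for j in range(10)],
        q=3, pi_thr=0.9, scheme=SubsampleScheme("complementary_pairs", 20, 1),
    )
    assert sum(res.frequencies.freqs.values()) == pytest.approx(3.0)
    for f in res.frequencies.freqs.values():
        assert round(f * 40) == pytest.approx(f * 40)  # on the 1/(2B) grid


def test_stabsel_pure_noise_usually_empty():
    empty = 0
    for seed in range(20):
        gen = np.random.default_rng(100 + seed)
        X = gen.standard_normal((100, 50))
        y = gen.standard_normal(100)
        res = stabsel(
            X, y, "gaussian", [linear(j) for j in range(50)],
            q=2, pi_thr=0.9,
            scheme=SubsampleScheme("complementary_pairs", 25, seed),
        )
        empty += not res.stable
    assert empty >= 18


def test_stabsel_near_duplicate_signals_symmetric():
    gen = np.random.default_rng(9)
    n = 150
    x1 = gen.standard_normal(n)
    x2 = x1 + 0.05 * gen.standard_normal(n)  # near-duplicate
    X = np.column_stack([x1, x2, gen.standard_normal((n, 8))])
    y = x1 + x2 + 0.5 * gen.standard_normal(n)
    res = stabsel(
        X, y, "gaussian", [linear(j) for j in range(10)],
        q=3, pi_thr=0.9, scheme=SubsampleScheme("complementary_pairs", 50, 4),
    )
    assert abs(res.frequencies["x0"] - res.frequencies["x1"]) < 0.15


def test_stabsel_error_control_all_noise():
    # expected stable count in the all-noise setting stays below the bound
    pfer_max = 1.5
    counts = []
    for seed in range(50):
        gen = np.random.default_rng(3000 + seed)
        X = gen.standard_normal((60, 20))
        y = gen.standard_normal(60)
        res = stabsel(
            X, y, "gaussian", [linear(j) for j in range(20)],
            q=2, pfer_max=pfer_max, assumption="unimodal",
            scheme=SubsampleScheme("complementary_pairs", 25, seed),
        )
        counts.append(len(res.stable))
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert mean <= pfer_max + 1.645 * se


def test_stabsel_signal_dominance():
    X, y = _signal_data(seed=11, n=120, p=12, k=3, coef=2.0)
    res = stabsel(
        X, y, "gaussian", [linear(j) for j in range(12)],
        q=4, pi_thr=0.9, scheme=SubsampleScheme("complementary_pairs", 30, 2),
    )
    freqs = res.frequencies.freqs
    signal = np.mean([freqs[f"x{j}"] for j in range(3)])
    noise = np.mean([freqs[f"x{j}"] for j in range(3, 12)])
    assert signal > noise


def test_stabsel_determinism():
    X, y = _signal_data(seed=3)
    learners = [linear(j) for j in range(10)]
    kw = dict(q=2, pi_thr=0.8,
              scheme=SubsampleScheme("complementary_pairs", 10, 77))
    r1 = stabsel(X, y, "gaussian", learners, **kw)
    r2 = stabsel(X, y, "gaussian", learners, **kw)
    assert r1.frequencies.freqs == r2.frequencies.freqs
    assert r1.stable == r2.stable


def test_stabsel_unattainable_pfer_warns():
    X, y = _signal_data(seed=4, p=10)
    with pytest.warns(UserWarning, match="not attainable"):
        res = stabsel(
            X, y, "gaussian", [linear(j) for j in range(10)],
            q=8, pfer_max=0.5, assumption="none",
            scheme=SubsampleScheme("complementary_pairs", 10, 0),
        )
    assert res.pi_thr == 1.0
    assert not res.attainable


# -- rethreshold and serialization -----------------------------------------


def test_rethreshold_matches_direct_run():
    X, y = _signal_data(seed=6, k=2)
    learners = [linear(j) for j in range(10)]
    scheme = SubsampleScheme("complementary_pairs", 25, 5)
    base = stabsel(X, y, "gaussian", learners, q=3, pfer_max=1.0,
                   assumption="unimodal", scheme=scheme)
    direct = stabsel(X, y, "gaussian", learners, q=3, pfer_max=2.0,
                     assumption="r_concave", scheme=scheme)
    rt = rethreshold(base, pfer_max=2.0, assumption="r_concave")
    assert rt.stable == direct.stable
    assert rt.pi_thr == pytest.approx(direct.pi_thr)
    assert rt.frequencies.freqs == base.frequencies.freqs


def test_result_json_roundtrip(tmp_path):
    X, y = _signal_data(seed=8)
    res = stabsel(
        X, y, "gaussian", [linear(j) for j in range(10)],
        q=2, pi_thr=0.8, scheme=SubsampleScheme("complementary_pairs", 10, 1),
    )
    path = tmp_path / "res.json"
    res.to_json(path)
    loaded = StabSelResult.from_dict(json.loads(path.read_text()))
    assert loaded.stable == res.stable
    assert loaded.frequencies.freqs == res.frequencies.freqs
    assert loaded.q == res.q


# -- stability paths --------------------------------------------------------


def test_stability_paths_monotone_and_plateau():
    gen = np.random.default_rng(12)
    X = gen.standard_normal((100, 10))
    y = 3.0 * X[:, 0] + gen.standard_normal(100)
    ids, paths = stability_paths(
        X, y, "gaussian", [linear(j) for j in range(10)],
        scheme=SubsampleScheme("complementary_pairs", 15, 2), max_m=40,
    )
    assert paths.shape == (10, 40)
    assert np.all(np.diff(paths, axis=1) >= 0)
    assert paths[ids.index("x0"), -1] == 1.0  # strong signal saturates
    assert np.all(paths >= 0) and np.all(paths <= 1)


def test_stability_paths_validation():
    gen = np.random.default_rng(1)
    X = gen.standard_normal((20, 2))
    y = gen.standard_normal(20)
    with pytest.raises(ValueError):
        stability_paths(X, y, "gaussian", [linear(0), linear(1)], max_m=0)
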