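"""Count tables, rarefaction, classes, methylation summaries, ordination."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from epiamplicon import (
    EpialleleCountTable,
    all_epialleles,
    build_count_table,
    class_distribution,
    distance_matrix,
    group_separation,
    mean_methylation,
    ordinate,
    per_cpg_methylation,
    rarefy,
)
from epiamplicon.calling import ReadCall


def table_from_counts(counts: dict[str, dict[str, int]], k: int):
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.reindex(sorted(df.columns), axis=1)
    meta = pd.DataFrame(index=df.index)
    return EpialleleCountTable(counts=df, meta=meta, k=k)


def calls(sample, alleles):
    return [ReadCall(sample, a, 0, 1.0) for a in alleles]


def test_build_count_table_basic(spec7):
    # a 2-CpG toy: three reads collapse to two epiallele columns
    from epiamplicon import make_amplicon_spec

    spec2 = make_amplicon_spec(2, 60, [0, 10], seed=3)
    table = build_count_table({"s1": calls("s1", ["00", "00", "11"])}, spec2)
    assert table.counts.loc["s1"].to_dict() == {"00": 2, "11": 1}
    assert table.row_sums().loc["s1"] == 3


def test_column_space_cardinality(spec7):
    table = build_count_table({"s1": calls("s1", ["0000000"])}, spec7)
    dense = table.dense()
    assert dense.shape[1] == 128
    assert list(dense.columns) == all_epialleles(7)
    assert len(all_epialleles(8)) == 256


def test_zero_retained_sample_dropped(spec7):
    with pytest.warns(UserWarning, match="no retained reads"):
        table = build_count_table(
            {"good": calls("good", ["0000000"]),
             "empty": [ReadCall("empty", None, 7, 0.0)]},
            spec7,
        )
    assert table.sample_ids == ["good"]


def test_rarefy_exact_depth_and_identity():
    t = table_from_counts({"s1": {"00": 100}}, k=2)
    r = rarefy(t, depth=10, seed=0)
    assert r.counts.loc["s1", "00"] == 10
    # row sum already at depth: row unchanged
    t2 = table_from_counts({"s1": {"00": 7, "11": 3}}, k=2)
    r2 = rarefy(t2, depth=10, seed=0)
    assert r2.counts.loc["s1"].to_dict() == {"00": 7, "11": 3}


def test_rarefy_drops_shallow_samples():
    t = table_from_counts({"deep": {"00": 100}, "shallow": {"11": 5}}, k=2)
    r = rarefy(t, depth=50, seed=1)
    assert r.sample_ids == ["deep"]
    with pytest.raises(ValueError):
        rarefy(t, depth=0, seed=1)


def test_rarefy_hypergeometric_expectation():
    # subsampling 1000 of 5000+5000 reads: mean count of one epiallele
    # follows the hypergeometric mean 500 within 3 s.e. over 200 seeds
    t = table_from_counts({"s": {"01": 5000, "10": 5000}}, k=2)
    draws = np.array(
        [rarefy(t, depth=1000, seed=s).counts.loc["s", "01"]
         for s in range(200)]
    )
    assert (draws.sum() + (1000 * 200 - draws.sum())) == 200 * 1000
    var = 1000 * 0.5 * 0.5 * (10000 - 1000) / (10000 - 1)
    se_mean = np.sqrt(var / 200)
    assert abs(draws.mean() - 500) <= 3 * se_mean


def test_class_distribution_cases():
    t = table_from_counts({"s": {"0000000": 10}}, k=7)
    d = class_distribution(t)
    assert d.shape[1] == 8  # classes 0-Meth .. 7-Meth
    assert d.loc["s", "0-Meth"] == 1.0
    # uniform over all 128 epialleles: class c proportion = C(7,c)/128
    uniform = table_from_counts({"u": {a: 1 for a in all_epialleles(7)}}, k=7)
    du = class_distribution(uniform)
    for c in range(8):
        assert du.loc["u", f"{c}-Meth"] == pytest.approx(comb(7, c) / 128)
    assert du.sum(axis=1).loc["u"] == pytest.approx(1.0, abs=1e-9)


def test_methylation_summaries():
    t = table_from_counts({"s": {"1111111": 4}}, k=7)
    assert mean_methylation(t).loc["s"] == 1.0
    mix = table_from_counts({"s": {"1000000": 50, "0000000": 50}}, k=7)
    per = per_cpg_methylation(mix)
    assert per.loc["s", "0"] == pytest.approx(0.5)
    assert (per.loc["s"].values[1:] == 0).all()
    assert mean_methylation(mix).loc["s"] == pytest.approx(0.5 / 7)


def test_mean_equals_per_cpg_average_random(rng):
    # exact identity on arbitrary tables
    for _ in range(20):
        k = int(rng.integers(2, 8))
        alleles = ["".join(rng.choice(list("01"), size=k)) for _ in range(6)]
        counts = {
            f"s{i}": {
                a: int(c)
                for a, c in zip(alleles, rng.integers(1, 100, len(alleles)))
            }
            for i in range(4)
        }
        t = table_from_counts(counts, k=k)
        mm = mean_methylation(t)
        pc = per_cpg_methylation(t)
        assert np.allclose(mm.values, pc.values.mean(axis=1), atol=1e-12)


def test_distance_metric_properties(rng):
    # equal row sums (the rarefied regime, where Bray-Curtis reduces to
    # L1/(2N) and is a true metric)
    counts = {
        f"s{i}": {
            a: int(c) + 1
            for a, c in zip(
                ["00", "01", "10", "11"],
                rng.multinomial(196, rng.dirichlet(np.ones(4))),
            )
        }
        for i in range(5)
    }
    t = table_from_counts(counts, k=2)
    for metric in ("braycurtis", "euclidean"):
        d = distance_matrix(t, metric=metric).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = d.shape[0]
        for i, j, l in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, l] + d[l, j] + 1e-12


def test_identical_samples_distance_zero_and_degenerate_ordination():
    t = table_from_counts(
        {"a": {"01": 10, "10": 5}, "b": {"01": 10, "10": 5},
         "c": {"01": 10, "10": 5}},
        k=2,
    )
    assert distance_matrix(t).values.max() == 0
    res = ordinate(t)
    assert np.allclose(res.coordinates.values, 0)
    assert np.allclose(res.proportion_explained, 0)


def test_collinear_samples_single_axis():
    # frequencies along a one-parameter family: first axis carries ~all
    # the variance
    t = table_from_counts(
        {"a": {"00": 90, "11": 10}, "b": {"00": 50, "11": 50},
         "c": {"00": 10, "11": 90}},
        k=2,
    )
    res = ordinate(t, metric="euclidean", method="pca")
    assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
    res2 = ordinate(t, metric="braycurtis", method="pcoa")
    assert res2.proportion_explained[0] > 0.95


def test_ordination_contract():
    t = table_from_counts(
        {f"s{i}": {"00": 10 + i, "01": 20 - i, "11": 5 + 2 * i}
         for i in range(6)},
        k=2,
    )
    res = ordinate(t)
    pe = res.proportion_explained
    assert (np.diff(pe) <= 1e-12).all() and pe.sum() <= 1 + 1e-9
    # axis sign: largest-magnitude coordinate is positive
    for j in range(res.coordinates.shape[1]):
        col = res.coordinates.values[:, j]
        if np.abs(col).max() > 0:
            assert col[np.argmax(np.abs(col))] > 0
    with pytest.raises(ValueError):
        ordinate(table_from_counts({"a": {"00": 1}, "b": {"11": 1}}, k=2))


def test_conversion_bias_correction_round_trip(rng):
    # pushing a known mixture through the per-site miscall process and
    # inverting it recovers the mixture exactly (noise-free case)
    import pandas as pd

    from epiamplicon import (
        all_epialleles,
        conversion_transition_matrix,
        correct_conversion_bias,
    )

    k = 5
    probs = rng.dirichlet(np.ones(2 ** k) * 0.2)
    T = conversion_transition_matrix(k, failure_rate=0.02,
                                     inappropriate_rate=0.005)
    assert np.allclose(T.sum(axis=0), 1.0)  # columns are distributions
    observed = pd.Series(T @ probs, index=all_epialleles(k))
    recovered = correct_conversion_bias(observed, 0.02, 0.005)
    assert np.allclose(recovered.values, probs, atol=1e-10)
    # zero rates: the identity
    ident = correct_conversion_bias(
        pd.Series(probs, index=all_epialleles(k)), 0.0
    )
    assert np.allclose(ident.values, probs, atol=1e-12)


def test_disjoint_support_groups_separate(rng):
    # equal mean methylation, disjoint epiallele support: groups split
    # cleanly on the first two axes
    g1 = ["1100000", "0011000"]
    g2 = ["0000110", "1000001"]
    counts = {}
    groups = {}
    for i in range(4):
        n = rng.multinomial(500, [0.5, 0.5])
        counts[f"a{i}"] = dict(zip(g1, (int(n[0]) + 1, int(n[1]) + 1)))
        groups[f"a{i}"] = "A"
        m = rng.multinomial(500, [0.5, 0.5])
        counts[f"b{i}"] = dict(zip(g2, (int(m[0]) + 1, int(m[1]) + 1)))
        groups[f"b{i}"] = "B"
    t = table_from_counts(counts, k=7)
    mm = mean_methylation(t)
    assert np.allclose(mm.values, 2 / 7, atol=0.01)
    res = ordinate(t)
    sep = group_separation(res, pd.Series(groups))
    assert sep["between_centroids"] > sep["max_within"]
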