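"""ANOVA, pairwise t tests, Pearson correlation and heatmaps vs textbook
formula oracles."""

import numpy as np
import pandas as pd
import pytest

from epiamplicon import (
    anova_oneway,
    class_expression_heatmap,
    epiallele_expression_heatmap,
    methylation_expression_correlation,
    pairwise_t_tests,
)

from test_tables import table_from_counts


# --- independent textbook-formula implementations -------------------------

def anova_f_oracle(groups):
    arrays = [np.asarray(g, float) for g in groups]
    n = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def welch_t_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    return (x.mean() - y.mean()) / np.sqrt(vx + vy)


def pooled_t_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    sp2 = (
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())


# --------------------------------------------------------------------------

def test_anova_trivial_cases():
    res = anova_oneway({"a": [0.0, 1.0], "b": [1.0, 0.0]})
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    degenerate = anova_oneway({"a": [0.0, 0.0], "b": [1.0, 1.0]})
    assert degenerate.statistic == np.inf and degenerate.p_value == 0.0
    assert degenerate.note != ""


def test_anova_hand_computed_table():
    # 3 groups x 3 values, worked by the between/within mean-square formula
    groups = {"P1": [1.0, 2.0, 3.0], "P15": [2.0, 3.0, 4.0],
              "P60": [6.0, 7.0, 8.0]}
    res = anova_oneway(groups)
    assert res.statistic == pytest.approx(
        anova_f_oracle(groups.values()), abs=1e-10
    )
    # by hand: group means 2, 3, 7, grand mean 4; SSB = 3*(4+1+9) = 42,
    # MSB = 21; SSW = 6 over 6 df, MSW = 1; F = 21
    assert res.statistic == pytest.approx(21.0, abs=1e-10)


def test_statistics_match_oracles_random(rng):
    for _ in range(100):
        sizes = rng.integers(3, 9, size=3)
        groups = {
            f"g{i}": list(rng.normal(rng.uniform(-1, 1), 1.0, size=s))
            for i, s in enumerate(sizes)
        }
        res = anova_oneway(groups)
        assert res.statistic == pytest.approx(
            anova_f_oracle(groups.values()), abs=1e-10
        )
        pts = pairwise_t_tests(groups)
        assert len(pts) == 3
        for t in pts:
            x, y = groups[t.groups[0]], groups[t.groups[1]]
            assert t.statistic == pytest.approx(welch_t_oracle(x, y),
                                                abs=1e-10)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        corr = methylation_expression_correlation(
            pd.Series(x, index=range(8)), pd.Series(y, index=range(8))
        )
        assert corr.statistic == pytest.approx(pearson_oracle(x, y),
                                               abs=1e-10)


def test_two_group_f_equals_t_squared(rng):
    for _ in range(50):
        groups = {
            "a": list(rng.normal(0, 1, size=5)),
            "b": list(rng.normal(0.5, 1, size=7)),
        }
        f = anova_oneway(groups)
        (t,) = pairwise_t_tests(groups, equal_var=True)
        assert f.statistic == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert f.p_value == pytest.approx(t.p_value, abs=1e-10)


def test_identical_groups_t():
    (t,) = pairwise_t_tests({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert t.statistic == pytest.approx(0.0, abs=1e-12)
    assert t.p_value == pytest.approx(1.0)


def test_holm_correction_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    groups = {f"g{i}": list(rng.normal(i * 0.3, 1, size=6)) for i in range(4)}
    raw = pairwise_t_tests(groups, correction="none")
    adj = pairwise_t_tests(groups, correction="holm")
    expected = multipletests([r.p_value for r in raw], method="holm")[1]
    assert np.allclose([a.p_value for a in adj], expected, atol=1e-12)


def test_correlation_edge_cases():
    x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    res = methylation_expression_correlation(x, -x)
    assert res.statistic == pytest.approx(-1.0)
    const = methylation_expression_correlation(
        x, pd.Series(1.0, index=list("abcd"))
    )
    assert np.isnan(const.statistic) and "constant" in const.note
    with pytest.raises(ValueError):
        methylation_expression_correlation(x.iloc[:2], x.iloc[:2])


def _heatmap_fixture():
    # expression strictly decreasing in mean methylation; class-0 tracks it
    counts = {}
    tissues = {}
    expr = {}
    for i, p in enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]):
        n1 = int(1000 * p)
        counts[f"s{i}"] = {"1111111": n1, "0000000": 1000 - n1}
        tissues[f"s{i}"] = "brain"
        expr[f"s{i}"] = 1.0 - 0.9 * p
    t = table_from_counts(counts, k=7)
    return t, pd.Series(expr), pd.Series(tissues)


def test_class_heatmap_sign_pattern():
    t, expr, tissues = _heatmap_fixture()
    hm = class_expression_heatmap(t, expr, tissues=tissues)
    assert hm.r.loc["0-Meth", "brain"] > 0.99
    assert hm.r.loc["7-Meth", "brain"] < -0.99
    assert (hm.r.abs().fillna(0) <= 1 + 1e-9).all().all()


def test_epiallele_heatmap_floor_and_signs():
    t, expr, tissues = _heatmap_fixture()
    hm = epiallele_expression_heatmap(t, expr, tissues=tissues,
                                      min_mean_freq=0.01)
    assert hm.r.loc["0000000", "brain"] > 0.99
    assert hm.r.loc["1111111", "brain"] < -0.99
    assert "1111111" in hm.r.index and len(hm.excluded) == 0
    # floor above both frequencies excludes everything -> error
    with pytest.raises(ValueError):
        epiallele_expression_heatmap(t, expr, tissues=tissues,
                                     min_mean_freq=0.99)


def test_heatmap_invariant_to_expression_rescaling():
    t, expr, tissues = _heatmap_fixture()
    a = class_expression_heatmap(t, expr, tissues=tissues)
    b = class_expression_heatmap(t, expr * 13.7, tissues=tissues)
    assert np.allclose(
        a.r.values.astype(float), b.r.values.astype(float), atol=1e-12,
        equal_nan=True,
    )


def test_heatmap_requires_three_samples():
    counts = {"s0": {"11": 5, "00": 5}, "s1": {"11": 8, "00": 2}}
    t = table_from_counts(counts, k=2)
    expr = pd.Series({"s0": 1.0, "s1": 0.5})
    tissues = pd.Series({"s0": "brain", "s1": "brain"})
    with pytest.raises(ValueError):
        class_expression_heatmap(t, expr, tissues=tissues)
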