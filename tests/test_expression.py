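"""Quantile normalisation and two-group differential expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from methex.expression import (
    differential_expression,
    label_swap_check,
    quantile_normalize,
    upper_quartile_normalize,
)

# ---------------------------------------------------------------------------
# independent oracle: sort-average quantile normalisation with explicit ties


def brute_force_quantile_normalize(values: np.ndarray) -> np.ndarray:
    n, m = values.shape
    ref = np.mean(np.sort(values, axis=0), axis=1)
    out = np.zeros_like(values, dtype=float)
    for j in range(m):
        col = values[:, j]
        order = sorted(range(n), key=lambda i: col[i])
        rank_of = {}
        for rank, i in enumerate(order):
            rank_of[i] = rank
        for i in range(n):
            ties = [k for k in range(n) if col[k] == col[i]]
            out[i, j] = np.mean([ref[rank_of[k]] for k in ties])
    return out


def _t_test_oracle(case, ctrl):
    """Equal-variance two-sample t by the textbook formula."""
    n1, n2 = len(case), len(ctrl)
    sp2 = ((n1 - 1) * np.var(case, ddof=1) + (n2 - 1) * np.var(ctrl, ddof=1)) / (n1 + n2 - 2)
    t = (np.mean(case) - np.mean(ctrl)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


def _bh_oracle(p):
    """Step-up Benjamini-Hochberg by explicit enumeration."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


GROUPS = {f"c{i}": "ctrl" for i in range(1, 4)} | {f"u{i}": "uc" for i in range(1, 4)}
COLS = list(GROUPS)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=[f"f{i}" for i in range(len(values))], columns=COLS[: values.shape[1]])


# ---------------------------------------------------------------------------


def test_quantile_normalize_toy():
    df = pd.DataFrame([[1, 2], [3, 4], [5, 6], [7, 8]], columns=["a", "b"], dtype=float)
    out = quantile_normalize(df)
    expected = [1.5, 3.5, 5.5, 7.5]
    assert list(out["a"]) == expected
    assert list(out["b"]) == expected


def test_quantile_normalize_fixed_points():
    same = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    pd.testing.assert_frame_equal(quantile_normalize(same), same)
    single = pd.DataFrame({"a": [5.0, 2.0, 9.0]})
    pd.testing.assert_frame_equal(quantile_normalize(single), single)


def test_quantile_normalize_rejects_missing():
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


@given(
    arrays(
        np.float64,
        (7, 3),
        elements=st.integers(min_value=-5, max_value=5).map(float),
    )
)
@settings(max_examples=60, derandomize=True)
def test_quantile_normalize_matches_brute_force(values):
    """Integer-valued inputs force plenty of ties; the oracle handles them
    explicitly, the implementation must agree."""
    df = pd.DataFrame(values, columns=["a", "b", "c"])
    out = quantile_normalize(df).to_numpy()
    np.testing.assert_allclose(out, brute_force_quantile_normalize(values), atol=1e-12)


def test_quantile_normalize_invariants(rng):
    df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    out = quantile_normalize(df)
    sums = out.sum(axis=0)
    assert np.ptp(sums.to_numpy()) < 1e-9 * abs(sums.mean())
    pd.testing.assert_frame_equal(quantile_normalize(out), out)  # idempotent


def test_upper_quartile_alternative(rng):
    df = pd.DataFrame(rng.uniform(1, 100, size=(40, 3)), columns=list("abc"))
    out = upper_quartile_normalize(df)
    q = out.quantile(0.75)
    assert np.ptp(q.to_numpy()) < 1e-9 * q.mean()


def test_de_null_feature_and_planted_feature():
    values = np.array(
        [
            [5.0, 5.1, 4.9, 5.0, 5.1, 4.9],  # identical across groups
            [5.0, 5.1, 4.9, 7.0, 7.1, 6.9],  # planted log2fc = 2, sd ~ 0.1
        ]
    )
    res = differential_expression(_matrix(values), GROUPS).set_index("feature_id")
    assert res.loc["f0", "log2fc"] == pytest.approx(0.0)
    assert not res.loc["f0", "is_de"]
    assert res.loc["f1", "is_de"]
    assert res.loc["f1", "direction"] == "up"
    t, p = _t_test_oracle(values[1, 3:], values[1, :3])
    assert res.loc["f1", "t_stat"] == pytest.approx(t)
    assert res.loc["f1", "p"] == pytest.approx(p)


def test_de_boundary_log2fc_exactly_one_is_not_de():
    # tight variance so FDR passes; the effect sits exactly on the cut
    values = np.array([[5 - 0.25, 5.0, 5 + 0.25, 6 - 0.25, 6.0, 6 + 0.25]])
    res = differential_expression(_matrix(values), GROUPS)
    assert res.loc[0, "log2fc"] == 1.0
    assert res.loc[0, "fdr"] < 0.05
    assert not res.loc[0, "is_de"]


def test_de_zero_variance_conventions():
    values = np.array(
        [
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],  # equal means -> p = 1
            [5.0, 5.0, 5.0, 8.0, 8.0, 8.0],  # different means -> p = 0
        ]
    )
    res = differential_expression(_matrix(values), GROUPS).set_index("feature_id")
    assert res.loc["f0", "p"] == 1.0
    assert res.loc["f0", "t_stat"] == 0.0
    assert res.loc["f1", "p"] == 0.0


def test_de_requires_two_samples_per_group():
    df = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["c1", "c2", "u1"])
    with pytest.raises(ValueError):
        differential_expression(df, {"c1": "ctrl", "c2": "ctrl", "u1": "uc"})


def test_de_linear_input_is_logged(rng):
    lin = pd.DataFrame(rng.uniform(0, 1000, size=(20, 6)), columns=COLS)
    res = differential_expression(lin, GROUPS, is_log2=False)
    logged = np.log2(lin + 1)
    expect = logged[COLS[3:]].mean(axis=1) - logged[COLS[:3]].mean(axis=1)
    got = res.set_index("feature_id")["log2fc"]
    np.testing.assert_allclose(got[expect.index].to_numpy(), expect.to_numpy())


def test_de_fdr_matches_bh_oracle_and_sorted(rng):
    df = pd.DataFrame(rng.normal(8, 1, size=(100, 6)), columns=COLS)
    res = differential_expression(df, GROUPS)
    adj = _bh_oracle(res["p"].to_numpy())
    np.testing.assert_allclose(res["fdr"].to_numpy(), adj, atol=1e-12)
    assert (res["fdr"].to_numpy()[:-1] <= res["fdr"].to_numpy()[1:] + 1e-15).all()
    assert res["fdr"].between(0, 1).all()


def test_label_swap_antisymmetry(rng):
    df = pd.DataFrame(rng.normal(8, 1, size=(60, 6)), columns=COLS)
    report = label_swap_check(df, GROUPS)
    assert report["ok"], report
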