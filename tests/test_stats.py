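import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from prososcreen import (
    FEATURE_NAMES,
    KSResult,
    group_significance,
    ks_two_sample,
    rank_features,
    ranking_frame,
    synth_feature_cohort,
)
from prososcreen.stats import _ks_int_statistic


def brute_force_p(x, y):
    """Enumerate all C(n+m, n) label assignments of the pooled sample."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    c_obs = _ks_int_statistic(np.asarray(x), np.asarray(y))
    idx = list(range(n + m))
    hits = total = 0
    for comb in itertools.combinations(idx, n):
        rest = [i for i in idx if i not in set(comb)]
        if _ks_int_statistic(pooled[list(comb)], pooled[rest]) >= c_obs:
            hits += 1
        total += 1
    return hits / total


def test_identical_samples():
    r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.D == 0.0 and r.p_value == 1.0 and not r.h


def test_disjoint_samples_exact_p():
    x = np.linspace(0, 1, 10)
    y = np.linspace(10, 11, 10)
    r = ks_two_sample(x, y, method="exact")
    assert r.D == 1.0
    assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)


def test_exact_matches_brute_force_small_samples():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        x = rng.normal(0, 1, n)
        y = rng.normal(rng.uniform(-1, 1), 1, m)
        r = ks_two_sample(x, y, method="exact")
        assert r.p_value == pytest.approx(brute_force_p(x, y), abs=1e-12)


def test_exact_cross_checked_against_scipy():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        r = ks_two_sample(x, y, method="exact")
        sc = sps.ks_2samp(x, y, method="exact")
        assert r.D == pytest.approx(sc.statistic)
        assert r.p_value == pytest.approx(sc.pvalue, rel=1e-9)


def test_asymptotic_branch():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 60), rng.normal(0.4, 1, 70)
    r = ks_two_sample(x, y)  # auto -> asymptotic at this size
    assert r.method == "asymptotic"
    # independent evaluation of the same Smirnov limiting distribution
    lam = r.D * np.sqrt(60 * 70 / 130)
    assert r.p_value == pytest.approx(sps.kstwobign.sf(lam), rel=1e-6)


def test_asymptotic_p_decreases_in_D():
    from prososcreen.stats import _asymptotic_survival

    ps = [_asymptotic_survival(d, 10, 10) for d in np.linspace(0.05, 1.0, 20)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert all(0.0 <= p <= 1.0 for p in ps)


@given(
    data=st.lists(st.integers(-500, 500), min_size=2, max_size=8, unique=True),
    data2=st.lists(st.integers(-500, 500), min_size=2, max_size=8, unique=True),
    scale=st.floats(0.1, 3.0),
    shift=st.floats(-2, 2),
)
def test_D_invariant_under_monotone_transform(data, data2, scale, shift):
    # 0.01-granular values keep distinctness through the affine transform
    x, y = np.array(data) / 100.0, np.array(data2) / 100.0
    d1 = ks_two_sample(x, y).D
    d2 = ks_two_sample(scale * x + shift, scale * y + shift).D
    assert d1 == pytest.approx(d2)


def test_empty_sample_errors():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


def test_rank_identical_groups_all_null():
    df = synth_feature_cohort()
    half = pd.concat([df[df.label == "MD"]] * 2, ignore_index=True)
    half["label"] = ["MD"] * 10 + ["non-MD"] * 10
    ranked = rank_features(half)
    for r in ranked:
        assert r.result.D == 0.0 and r.result.p_value == 1.0 and not r.result.h


def test_rank_order_and_tie_break():
    rng = np.random.default_rng(0)
    n = 10
    df = pd.DataFrame({
        "subject_id": [str(i) for i in range(2 * n)],
        "label": ["MD"] * n + ["non-MD"] * n,
        "A": np.r_[rng.normal(0, 1, n), rng.normal(3, 1, n)],
        "B": rng.normal(0, 1, 2 * n),
        "C": np.r_[rng.normal(0, 1, n), rng.normal(3, 1, n)],
    })
    ranked = rank_features(df, features=["A", "B", "C"])
    assert ranked[0].rank == 1
    assert ranked[-1].name == "B"
    ps = [r.result.p_value for r in ranked]
    assert ps == sorted(ps)
    # exact tie between A and C breaks by canonical order
    if ps[0] == ps[1]:
        assert [ranked[0].name, ranked[1].name] == ["A", "C"]


def test_shifted_feature_ranks_first():
    """A 1.5-pooled-SD shift in SDF puts it at rank 1 with h=1 (n=m=50)."""
    rng = np.random.default_rng(2024)
    wins = 0
    reps = 100
    for _ in range(reps):
        n = 50
        data = {"subject_id": [str(i) for i in range(2 * n)],
                "label": ["MD"] * n + ["non-MD"] * n}
        for name in FEATURE_NAMES:
            if name == "SDF":
                data[name] = np.r_[rng.normal(1.5, 1, n), rng.normal(0, 1, n)]
            else:
                data[name] = rng.normal(0, 1, 2 * n)
        ranked = rank_features(pd.DataFrame(data))
        if ranked[0].name == "SDF" and ranked[0].result.h:
            wins += 1
    assert wins >= 95


def test_significance_tier_boundaries():
    def res(p):
        return KSResult(D=0.5, p_value=p, h=p < 0.05, n=10, m=10, method="exact")

    from prososcreen.stats import RankedFeature, _tier

    ranked = [
        RankedFeature("A", res(0.049), 1, _tier(0.049)),
        RankedFeature("B", res(0.05), 2, _tier(0.05)),
        RankedFeature("C", res(0.499), 3, _tier(0.499)),
        RankedFeature("D", res(0.5), 4, _tier(0.5)),  # boundary -> NSIG
        RankedFeature("E", res(0.9), 5, _tier(0.9)),
    ]
    groups = group_significance(ranked)
    assert groups.SIG == ("A",)
    assert groups.PSIG == ("B", "C")
    assert groups.NSIG == ("D", "E")


def test_ranking_frame_columns():
    df = synth_feature_cohort()
    rep = ranking_frame(rank_features(df))
    assert list(rep.columns) == ["feature", "D", "p", "h", "rank", "tier"]
    assert len(rep) == 12
    assert sorted(rep["rank"]) == list(range(1, 13))
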