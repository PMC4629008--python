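"""Two-sample Kolmogorov-Smirnov feature ranking and significance tiers.

The KS statistic D is the supremum distance between the two empirical
CDFs, evaluated at every pooled sample point (both one-sided sups, so ties
are handled).  Small samples get an exact p-value by integer lattice-path
counting over all C(n+m, n) orderings; larger ones use the classical
Smirnov asymptotic series.  Features are ranked ascending by p, and
partitioned into three discrimination tiers:

* SIG  : p < 0.05   (significant)
* PSIG : 0.05 <= p < 0.5  (possibly significant)
* NSIG : p >= 0.5   (nonsignificant)
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "KSResult",
    "RankedFeature",
    "SignificanceGroups",
    "ks_two_sample",
    "rank_features",
    "group_significance",
    "ranking_frame",
]

EXACT_LIMIT = 30  # auto -> exact enumeration when n + m <= this


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    h: bool
    n: int
    m: int
    method: str


@dataclass(frozen=True)
class RankedFeature:
    name: str
    result: KSResult
    rank: int
    tier: str


@dataclass(frozen=True)
class SignificanceGroups:
    SIG: tuple
    PSIG: tuple
    NSIG: tuple

    def combos(self) -> dict:
        """The seven tier combinations used for group-wise classification."""
        g = {"SIG": self.SIG, "PSIG": self.PSIG, "NSIG": self.NSIG}
        out = {}
        names = ["SIG", "PSIG", "NSIG", "SIG-PSIG", "SIG-NSIG", "PSIG-NSIG",
                 "SIG-PSIG-NSIG"]
        for name in names:
            feats: List[str] = []
            for part in name.split("-"):
                feats.extend(g[part])
            out[name] = tuple(feats)
        return out


def _ks_int_statistic(x: np.ndarray, y: np.ndarray) -> int:
    """sup |F_x - F_y| scaled by n*m, as an exact integer."""
    n, m = x.size, y.size
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    i = np.searchsorted(xs, pooled, side="right")
    j = np.searchsorted(ys, pooled, side="right")
    return int(np.max(np.abs(i * m - j * n)))


def _exact_survival(n: int, m: int, c: int) -> float:
    """P(D* >= c/(n*m)) under the null by lattice-path counting.

    Counts monotone paths (0,0)->(n,m) that keep |i*m - j*n| < c at every
    lattice point; the complement over C(n+m, n) equally likely orderings
    is the exact two-sided p-value (continuous / tie-free null).
    """
    if c <= 0:
        return 1.0
    grid = [[0] * (m + 1) for _ in range(n + 1)]
    grid[0][0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * m - j * n) >= c:
                continue
            acc = 0
            if i > 0:
                acc += grid[i - 1][j]
            if j > 0:
                acc += grid[i][j - 1]
            grid[i][j] = acc
    total = math.comb(n + m, n)
    return (total - grid[n][m]) / total


def _asymptotic_survival(d: float, n: int, m: int) -> float:
    """Smirnov limiting distribution: 2*sum (-1)^(k-1) exp(-2 k^2 lam^2)."""
    lam = d * math.sqrt(n * m / (n + m))
    if lam <= 0:
        return 1.0
    s = 0.0
    for k in range(1, 1000):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        s += term
        if abs(term) < 1e-12:
            break
    return float(min(1.0, max(0.0, s)))


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    alpha: float = 0.05,
) -> KSResult:
    """Two-sample KS test.

    ``method`` is ``"exact"`` (lattice-path enumeration, feasible for
    n + m <= ~30), ``"asymptotic"``, or ``"auto"`` (exact when
    n + m <= 30).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    n, m = int(x.size), int(y.size)
    c = _ks_int_statistic(x, y)
    d = c / (n * m)
    if method == "auto":
        method = "exact" if n + m <= EXACT_LIMIT else "asymptotic"
    if method == "exact":
        p = _exact_survival(n, m, c)
    elif method == "asymptotic":
        p = _asymptotic_survival(d, n, m)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return KSResult(D=d, p_value=float(p), h=bool(p < alpha), n=n, m=m, method=method)


def _tier(p: float) -> str:
    if p < 0.05:
        return "SIG"
    if p < 0.5:
        return "PSIG"
    return "NSIG"


def rank_features(
    table: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    label_col: str = "label",
    positive_label: str = "MD",
    alpha: float = 0.05,
    method: str = "auto",
) -> List[RankedFeature]:
    """Per-feature KS test between the two label groups, ranked by p.

    Rank 1 is the smallest p; ties break by position in the canonical
    feature order.  ``h`` is True iff p < alpha.
    """
    features = list(features) if features is not None else [
        f for f in FEATURE_NAMES if f in table.columns
    ]
    labels = table[label_col]
    pos = table[labels == positive_label]
    neg = table[labels != positive_label]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per group")
    results = []
    for order, name in enumerate(features):
        res = ks_two_sample(
            pos[name].to_numpy(), neg[name].to_numpy(), method=method, alpha=alpha
        )
        results.append((res.p_value, order, name, res))
    results.sort(key=lambda t: (t[0], t[1]))
    return [
        RankedFeature(name=name, result=res, rank=i + 1, tier=_tier(res.p_value))
        for i, (_, _, name, res) in enumerate(results)
    ]


def group_significance(ranked: Sequence[RankedFeature]) -> SignificanceGroups:
    """Partition ranked features into the SIG / PSIG / NSIG tiers."""
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    sig = tuple(r.name for r in ranked if r.tier == "SIG")
    psig = tuple(r.name for r in ranked if r.tier == "PSIG")
    nsig = tuple(r.name for r in ranked if r.tier == "NSIG")
    return SignificanceGroups(SIG=sig, PSIG=psig, NSIG=nsig)


def ranking_frame(ranked: Sequence[RankedFeature]) -> pd.DataFrame:
    """Report table: feature, D, p, h, rank, tier."""
    return pd.DataFrame(
        [
            {
                "feature": r.name,
                "D": r.result.D,
                "p": r.result.p_value,
                "h": int(r.result.h),
                "rank": r.rank,
                "tier": r.tier,
            }
            for r in ranked
        ]
    )
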