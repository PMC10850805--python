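"""Statistical kernels shared by the pipeline.

Each kernel is small, self-contained, and checkable against a brute-force
or closed-form oracle:

* :func:`welch_t` / :func:`student_t` — two-sample t tests, two-sided.
* :func:`mann_whitney` — U statistic with exact enumeration for small
  samples and a tie-corrected normal approximation otherwise.
* :func:`welch_anova` — heteroscedastic one-way F test.
* :func:`dunnett_adjust` — many-to-one comparisons against a control with
  a seeded Monte-Carlo family-wise adjustment.
* :func:`holm_sidak` — step-down Šidák multiple-testing adjustment.
* :func:`cohens_d` — pooled-SD standardized mean difference.
* :func:`pearson_corr` — Pearson r with a t-distribution p-value.

All p-values are two-sided.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ConfigError

__all__ = [
    "TestResult",
    "AdjustedPValues",
    "welch_t",
    "student_t",
    "mann_whitney",
    "welch_anova",
    "dunnett_adjust",
    "holm_sidak",
    "cohens_d",
    "pearson_corr",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and not self.df > 0:
            raise ValueError(f"df {self.df} must be positive")


@dataclass(frozen=True)
class AdjustedPValues:
    """Raw and multiplicity-adjusted p-values, in input order."""

    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    procedure: str


def _as_group(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < min_n:
        raise InsufficientDataError(
            f"group {name!r} has {arr.size} non-missing values; need >= {min_n}"
        )
    return arr


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    Uses the Satterthwaite degrees-of-freedom approximation.
    """
    x, y = _as_group(a, "a"), _as_group(b, "b")
    va, vb = x.var(ddof=1), y.var(ddof=1)
    na, nb = x.size, y.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if x.mean() == y.mean():
            raise DegenerateDataError("both groups constant with equal means")
        return TestResult(math.inf * np.sign(x.mean() - y.mean()), 0.0, "welch_t", df=na + nb - 2)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    # denom can underflow to 0 for near-constant groups
    df = se2**2 / denom if denom > 0 else float(na + nb - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), "welch_t", df=float(df))


def student_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance (Student) two-sample t test, two-sided."""
    x, y = _as_group(a, "a"), _as_group(b, "b")
    na, nb = x.size, y.size
    df = na + nb - 2
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            raise DegenerateDataError("both groups constant with equal means")
        return TestResult(math.inf * np.sign(x.mean() - y.mean()), 0.0, "student_t", df=df)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), "student_t", df=float(df))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group *a*: count of pairs with a_i > b_j, ties counted 1/2."""
    gt = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


@functools.lru_cache(maxsize=64)
def _exact_mw_distribution(n1: int, n2: int) -> tuple[int, ...]:
    """Null U counts by full enumeration of rank combinations.

    Feasible for n1, n2 <= 8 (C(16, 8) = 12870 labelings); cached per shape.
    """
    offset = n1 * (n1 + 1) // 2
    counts = [0] * (n1 * n2 + 1)
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        counts[sum(combo) - offset] += 1
    return tuple(counts)


def _exact_mw_p(u: float, n1: int, n2: int) -> float:
    counts = _exact_mw_distribution(n1, n2)
    total = sum(counts)
    n_le = sum(c for k, c in enumerate(counts) if k <= u)
    n_ge = sum(c for k, c in enumerate(counts) if k >= u)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def mann_whitney(a: Sequence[float], b: Sequence[float], mode: str = "auto") -> TestResult:
    """Mann–Whitney U test, two-sided.

    ``U`` counts pairs where an *a* observation exceeds a *b* observation
    (ties contribute 1/2), matching the common convention in which two
    stochastically identical samples give ``U = n1*n2/2``.

    mode:
        ``auto``   — exact enumeration when both groups have <= 8
                     observations and there are no ties; otherwise the
                     tie-corrected normal approximation.
        ``exact``  — force enumeration; refuses ties (falls back to
                     normal with a warning).
        ``normal`` — force the normal approximation.
    """
    if mode not in {"auto", "exact", "normal"}:
        raise ConfigError(f"unknown mann_whitney mode {mode!r}")
    x, y = _as_group(a, "a", min_n=1), _as_group(b, "b", min_n=1)
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    want_exact = mode == "exact" or (mode == "auto" and n1 <= 8 and n2 <= 8)
    if want_exact and has_ties:
        if mode == "exact":
            warnings.warn("ties present; exact Mann-Whitney falls back to normal approximation")
        want_exact = False

    if want_exact:
        return TestResult(u, _exact_mw_p(u, n1, n2), "mann_whitney_exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0.0:
        return TestResult(u, 1.0, "mann_whitney_normal")
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(u, float(p), "mann_whitney_normal")


def welch_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA (two-sided p from the F tail).

    Groups with fewer than 2 members or zero variance are dropped with a
    warning; at least 2 eligible groups are required.  With exactly two
    groups the statistic equals the square of :func:`welch_t`'s t.
    """
    cleaned: list[np.ndarray] = []
    for i, g in enumerate(groups):
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2 or arr.var(ddof=1) == 0.0:
            warnings.warn(f"welch_anova: dropping ineligible group {i} (n={arr.size})")
            continue
        cleaned.append(arr)
    k = len(cleaned)
    if k < 2:
        raise InsufficientDataError("welch_anova needs >= 2 groups with n >= 2 and nonzero variance")

    n = np.array([g.size for g in cleaned], dtype=float)
    m = np.array([g.mean() for g in cleaned])
    v = np.array([g.var(ddof=1) for g in cleaned])
    w = n / v
    w_sum = w.sum()
    mw = (w * m).sum() / w_sum
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1.0 - w / w_sum) ** 2 / (n - 1)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(float(f), min(p, 1.0), "welch_anova", df=float(df2))


def dunnett_adjust(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> AdjustedPValues:
    """Dunnett many-to-one comparisons against a control group.

    Raw p-values come from per-comparison Welch t tests.  The family-wise
    adjustment is evaluated by seeded Monte Carlo under the classical
    equal-variance Dunnett model: adjusted_i = P(max_j |T_j| >= |t_i|),
    where the T_j are the correlated null comparison statistics sharing a
    pooled variance estimate.  Adjusted values are clipped to be >= raw.

    With a single comparison the adjustment is the identity.
    """
    if not 0 <= control_index < len(groups):
        raise ConfigError(f"control_index {control_index} out of range")
    arrays = [_as_group(g, f"group {i}") for i, g in enumerate(groups)]
    control = arrays[control_index]
    if control.size < 2:
        raise InsufficientDataError("control group needs >= 2 observations")
    others = [(i, g) for i, g in enumerate(arrays) if i != control_index]
    if not others:
        raise ConfigError("dunnett_adjust needs at least one non-control group")

    raw = [welch_t(g, control).p_value for _, g in others]

    k = len(others)
    if k == 1:
        return AdjustedPValues(tuple(raw), tuple(raw), "dunnett")

    nu = sum(g.size - 1 for g in arrays)
    n0 = control.size
    ns = np.array([g.size for _, g in others], dtype=float)
    # observed statistics under the classical pooled-variance Dunnett model,
    # matching the Monte-Carlo null exactly
    sp2 = sum((g.size - 1) * g.var(ddof=1) for g in arrays) / nu
    if sp2 == 0.0:
        raise DegenerateDataError("pooled variance is zero")
    t_obs = [
        abs(g.mean() - control.mean()) / math.sqrt(sp2 * (1.0 / g.size + 1.0 / n0))
        for _, g in others
    ]

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc) / math.sqrt(n0)
    zi = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
    s = np.sqrt(rng.chisquare(nu, n_mc) / nu)
    t_null = np.abs(zi - z0[:, None]) / (s[:, None] * np.sqrt(1.0 / ns + 1.0 / n0))
    max_t = t_null.max(axis=1)
    adjusted = [
        min(1.0, max(p_raw, float((max_t >= t).mean())))
        for p_raw, t in zip(raw, t_obs)
    ]
    return AdjustedPValues(tuple(raw), tuple(adjusted), "dunnett")


def holm_sidak(raw: Sequence[float]) -> AdjustedPValues:
    """Step-down Šidák adjustment.

    Sort ascending; adjusted_(i) = max_{j<=i} (1 - (1 - p_(j))^(m-j+1)),
    clipped to 1 and mapped back to input order.
    """
    p = np.asarray(raw, dtype=float)
    if p.size == 0:
        return AdjustedPValues((), (), "holm_sidak")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        k = m - i
        # k == 1 simplifies to the raw p; the max() guards against float
        # rounding pushing the Sidak step below the raw value
        step = p[idx] if k == 1 else max(p[idx], 1.0 - (1.0 - p[idx]) ** k)
        running = max(running, step)
        adj_sorted[i] = min(1.0, running)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustedPValues(tuple(p.tolist()), tuple(adjusted.tolist()), "holm_sidak")


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d = (mean(a) - mean(b)) / pooled SD, with (n-1)-weighted pooling."""
    x, y = _as_group(a, "a"), _as_group(b, "b")
    na, nb = x.size, y.size
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise DegenerateDataError("pooled SD is zero; Cohen's d undefined")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with a two-sided p from t = r*sqrt((n-2)/(1-r^2)).

    Returns ``(r, p, n)`` over the pairwise-complete observations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise InsufficientDataError(f"pearson_corr needs >= 3 paired values, got {n}")
    if xa.var() == 0.0 or ya.var() == 0.0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # exact linear relation up to float error
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(min(1.0, 2.0 * stats.t.sf(abs(t), n - 2)))
    return r, p, n
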