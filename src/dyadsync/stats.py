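"""Group-level inference: t tests, one-way ANOVA with partial eta squared,
Benjamini-Hochberg FDR, and Pearson correlation.

All tests use the classical (equal-variance) formulas so that degrees of
freedom match conventional reports (e.g. df = N - k for a one-way ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "TTestResult",
    "AnovaResult",
    "FDRReport",
    "CorrelationResult",
    "one_sample_t",
    "paired_t",
    "independent_t",
    "one_way_anova",
    "eta_p2_from_f",
    "bh_fdr",
    "pearson_r",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    tail: str

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "tail": self.tail}


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    group_means: tuple[float, ...]
    posthoc: dict = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict:
        return {
            "f": self.f,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "eta_p2": self.eta_p2,
            "group_means": list(self.group_means),
            "posthoc": self.posthoc,
        }


@dataclass(frozen=True)
class FDRReport:
    raw_p: dict
    adjusted_p: dict
    passed: frozenset
    q_threshold: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def _clean(values: Iterable[float], min_n: int, what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValidationError(f"{what}: need at least {min_n} values")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what}: values must be finite")
    return arr


def _tail_p(t: float, df: int, tail: str) -> float:
    if tail == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if tail == "one":
        # one-tailed for the positive-direction alternative
        return float(sps.t.sf(t, df))
    raise ValidationError(f"unknown tail {tail!r}")


def one_sample_t(values: Iterable[float], mu0: float = 0.0, tail: str = "one") -> TTestResult:
    """One-sample t test of ``mean(values) = mu0``.

    The default tail is one-sided for the alternative ``mean > mu0`` (the
    direction used for the synchronization contrast).
    """
    x = _clean(values, 2, "one_sample_t")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("one_sample_t: zero variance")
    n = x.size
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    return TTestResult(t=float(t), df=n - 1, p=_tail_p(t, n - 1, tail), tail=tail)


def paired_t(a: Iterable[float], b: Iterable[float], tail: str = "two") -> TTestResult:
    x = _clean(a, 2, "paired_t")
    y = _clean(b, 2, "paired_t")
    if x.size != y.size:
        raise ValidationError("paired_t: length mismatch")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValidationError("paired_t: zero-variance differences")
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    return TTestResult(t=float(t), df=d.size - 1, p=_tail_p(t, d.size - 1, tail), tail=tail)


def independent_t(a: Iterable[float], b: Iterable[float], tail: str = "two") -> TTestResult:
    """Classical pooled-variance two-sample t test."""
    x = _clean(a, 2, "independent_t")
    y = _clean(b, 2, "independent_t")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ValidationError("independent_t: zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TTestResult(t=float(t), df=df, p=_tail_p(t, df, tail), tail=tail)


def eta_p2_from_f(f: float, df1: int, df2: int) -> float:
    """Partial eta squared implied by a one-way ANOVA F statistic:
    ``eta_p2 = df1*F / (df1*F + df2)``."""
    if f < 0 or df1 <= 0 or df2 <= 0:
        raise ValidationError("invalid F/df for effect size")
    return df1 * f / (df1 * f + df2)


def one_way_anova(
    groups: Sequence[Iterable[float]],
    labels: Sequence[str] | None = None,
    posthoc: bool = True,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with partial eta squared and (optional)
    Tukey HSD post hoc pairwise comparisons."""
    if len(groups) < 2:
        raise ValidationError("one_way_anova: need at least 2 groups")
    gs = [_clean(g, 2, "one_way_anova group") for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(gs))]
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1 = len(gs) - 1
    df2 = n_total - len(gs)
    if ss_within == 0:
        raise ValidationError("one_way_anova: zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    pairwise: dict = {}
    if posthoc:
        tukey = sps.tukey_hsd(*gs)
        pairwise = {
            f"{labels[i]}-{labels[j]}": float(tukey.pvalue[i, j])
            for i in range(len(gs))
            for j in range(i + 1, len(gs))
        }
    return AnovaResult(
        f=float(f),
        df1=df1,
        df2=df2,
        p=p,
        eta_p2=eta_p2_from_f(f, df1, df2),
        group_means=tuple(float(g.mean()) for g in gs),
        posthoc=pairwise,
    )


def bh_fdr(p_values: Mapping, q: float = 0.05) -> FDRReport:
    """Benjamini-Hochberg step-up procedure over a keyed family of p values.

    Returns the set of keys passing at level ``q`` and monotone adjusted
    p values.
    """
    if not p_values:
        raise ValidationError("bh_fdr: empty input")
    keys = list(p_values.keys())
    p = np.array([p_values[k] for k in keys], dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("bh_fdr: p values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    # step-up rule: largest k with p_(k) <= k/m * q; all smaller ranks pass
    below = ranked <= np.arange(1, m + 1) / m * q
    passed_keys: set = set()
    if np.any(below):
        k_max = int(np.max(np.nonzero(below)[0]))
        passed_keys = {keys[order[i]] for i in range(k_max + 1)}
    return FDRReport(
        raw_p={k: float(v) for k, v in zip(keys, p)},
        adjusted_p={k: float(v) for k, v in zip(keys, adjusted)},
        passed=frozenset(passed_keys),
        q_threshold=q,
    )


def pearson_r(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Pearson correlation with a two-tailed t-based p value."""
    xa = _clean(x, 3, "pearson_r")
    ya = _clean(y, 3, "pearson_r")
    if xa.size != ya.size:
        raise ValidationError("pearson_r: length mismatch")
    if xa.std() == 0 or ya.std() == 0:
        raise ValidationError("pearson_r: constant input")
    n = xa.size
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)
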