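"""Group comparisons: one-way ANOVA with Student-Newman-Keuls post hoc,
one-sample t-tests against zero, and titration dose selection.

The SNK procedure orders group means, then tests pairs on the studentized
range q = |m_i - m_j| / sqrt(MSE / n_h) against q_crit(alpha, r, df_error),
where r is the number of rank positions the pair spans and n_h is the
harmonic mean of the pair's sample sizes.  Testing steps down from the
widest span; every pair inside a span that fails to reach significance is
declared non-significant without being tested (the SNK non-testing rule).
At k = 2 the decision coincides exactly with the pooled two-sample t-test
(q = t * sqrt(2)).  Studentized-range quantiles come from
``scipy.stats.studentized_range``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .assay_model import DataError

__all__ = [
    "GroupComparison",
    "anova_snk",
    "t_test_vs_zero",
    "TTestResult",
    "select_titration_dose",
    "snk_critical_q",
]


@lru_cache(maxsize=512)
def snk_critical_q(alpha: float, n_means: int, df: int) -> float:
    """Upper critical value of the studentized range, q(alpha; r, df)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, n_means, df))


class TTestResult(NamedTuple):
    t: float
    p: float
    significant: bool


@dataclass
class GroupComparison:
    """One-way ANOVA plus SNK pairwise decisions for labelled groups.

    ``significant`` is a symmetric boolean matrix in the order of ``labels``;
    ``q``/``critical_q``/``span`` record the pairwise statistics (NaN where
    the SNK rule skipped the test).  ``letters`` are homogeneous-subset
    annotations: groups sharing a letter are not significantly different.
    """

    labels: list
    n: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    f: float
    p: float
    alpha: float
    significant: np.ndarray
    q: np.ndarray
    critical_q: np.ndarray
    span: np.ndarray
    letters: list[str]
    degenerate: bool = False

    def pair(self, a, b) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.significant[i, j])

    def summary(self) -> str:
        lines = [f"one-way ANOVA: F = {self.f:.4g}, p = {self.p:.4g} (alpha = {self.alpha})"]
        for lab, n, m, s, letter in zip(self.labels, self.n, self.means, self.sems, self.letters):
            lines.append(f"  {lab}: n={n} mean={m:.4g} sem={s:.4g}  [{letter}]")
        return "\n".join(lines)


def _coerce_groups(groups) -> tuple[list, list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        data = [np.asarray(list(groups[k]), float) for k in labels]
    else:
        data = [np.asarray(list(g), float) for g in groups]
        labels = list(range(len(data)))
    return labels, data


def anova_snk(groups, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA F-test followed by the SNK step-down procedure.

    ``groups`` is a mapping label -> samples or a sequence of sample arrays;
    every group needs n >= 2.  Unequal sizes use the harmonic mean of each
    pair's n.  If within-group variance is exactly zero with unequal means
    the comparison is degenerate: every unequal pair is reported significant
    and the result is flagged.
    """
    labels, data = _coerce_groups(groups)
    k = len(data)
    if k < 2:
        raise DataError(f"need >= 2 groups, got {k}")
    for lab, g in zip(labels, data):
        if g.size < 2:
            raise DataError(f"group {lab!r} has n = {g.size} < 2")
    ns = np.array([g.size for g in data])
    means = np.array([g.mean() for g in data])
    sems = np.array([g.std(ddof=1) / np.sqrt(g.size) for g in data])
    n_tot = int(ns.sum())
    df_err = n_tot - k
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in data))
    grand = float(np.concatenate(data).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    mse = sse / df_err

    sig = np.zeros((k, k), dtype=bool)
    qmat = np.full((k, k), np.nan)
    qcrit = np.full((k, k), np.nan)
    span = np.full((k, k), np.nan)

    if mse == 0:
        degenerate = True
        f = np.inf if ssb > 0 else np.nan
        p = 0.0 if ssb > 0 else np.nan
        for i in range(k):
            for j in range(k):
                sig[i, j] = i != j and means[i] != means[j]
    else:
        degenerate = False
        f = (ssb / (k - 1)) / mse
        p = float(sps.f.sf(f, k - 1, df_err))
        order = np.argsort(means, kind="stable")  # ascending mean

        def q_stat(a: int, b: int) -> float:
            i, j = order[a], order[b]
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            return abs(means[j] - means[i]) / np.sqrt(mse / n_h)

        # step-down over rank spans with the SNK non-testing rule
        def test_span(a: int, b: int, blocked: set) -> None:
            if b <= a or (a, b) in blocked:
                return
            r = b - a + 1
            i, j = order[a], order[b]
            q = q_stat(a, b)
            crit = snk_critical_q(alpha, r, df_err)
            qmat[i, j] = qmat[j, i] = q
            qcrit[i, j] = qcrit[j, i] = crit
            span[i, j] = span[j, i] = r
            if q > crit:
                sig[i, j] = sig[j, i] = True
                test_span(a, b - 1, blocked)
                test_span(a + 1, b, blocked)
            else:
                for aa in range(a, b + 1):
                    for bb in range(aa + 1, b + 1):
                        blocked.add((aa, bb))

        test_span(0, k - 1, set())

    letters = _subset_letters(means, sig)
    return GroupComparison(
        labels=labels,
        n=ns,
        means=means,
        sems=sems,
        f=float(f),
        p=p,
        alpha=alpha,
        significant=sig,
        q=qmat,
        critical_q=qcrit,
        span=span,
        letters=letters,
        degenerate=degenerate,
    )


def _subset_letters(means: np.ndarray, sig: np.ndarray) -> list[str]:
    """Letter annotations from maximal non-significant spans in mean order."""
    k = means.size
    order = np.argsort(means, kind="stable")
    spans: list[tuple[int, int]] = []
    a = 0
    while a < k:
        b = a
        while b + 1 < k and not any(
            sig[order[i], order[b + 1]] for i in range(a, b + 1)
        ):
            b += 1
        spans.append((a, b))
        a += 1
    # keep only maximal spans
    maximal = [s for s in spans if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in spans)]
    letters = [""] * k
    for letter_idx, (a, b) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx % 26)
        for pos in range(a, b + 1):
            letters[order[pos]] += ch
    return letters


def t_test_vs_zero(values: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Two-sided one-sample Student's t-test of mean = 0."""
    v = np.asarray(list(values), float)
    if v.size < 2:
        raise DataError(f"need n >= 2 observations, got {v.size}")
    if v.std(ddof=1) == 0:
        raise DataError("zero variance; t statistic undefined")
    res = sps.ttest_1samp(v, 0.0)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), significant=bool(res.pvalue < alpha))


def select_titration_dose(curve, tolerance: float = 0.05) -> float:
    """Smallest non-lethal dose within ``tolerance`` of the non-lethal maximum.

    ``curve`` is a TitrationCurve or any object with ``doses``, ``responses``
    and ``dead`` arrays.  Operationalizes "maximum change in respiration
    without inducing death": near-plateau doses resolve to the lowest one.
    """
    doses = np.asarray(curve.doses, float)
    resp = np.abs(np.asarray(curve.responses, float))
    dead = np.asarray(curve.dead, bool)
    if doses.size < 2:
        raise DataError(f"need >= 2 doses, got {doses.size}")
    alive = ~dead
    if not alive.any():
        raise DataError("all doses were lethal")
    max_resp = resp[alive].max()
    ok = alive & (resp >= (1.0 - tolerance) * max_resp)
    return float(doses[ok].min())
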