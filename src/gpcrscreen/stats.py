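"""Small-sample statistics: normality-gated two-group tests, Spearman
correlation with exact small-n p-values, one-way ANOVA with Dunnett's
many-to-one post hoc, and an optional IQR outlier rule.

These are the group-comparison conventions of small-animal studies: test
each group for normality (Shapiro-Wilk at alpha = 0.05), use Student's
unpaired t when both pass and the exact Mann-Whitney U otherwise, report
Spearman's rho for correlations, and gate Dunnett's post hoc on the ANOVA
F test.  scipy provides the reference tests; this module adds the
dispatch, the exact enumeration p-values at the sample sizes where
asymptotics are unreliable, and explicit degenerate-input handling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "TwoGroupResult",
    "CorrelationResult",
    "DunnettResult",
    "two_group_test",
    "spearman",
    "anova_dunnett",
    "iqr_outliers",
]

NORMALITY_ALPHA = 0.05
#: exact Mann-Whitney enumeration up to this pooled sample size (no ties)
MWU_EXACT_MAX_N = 12
#: exact Spearman permutation p up to this n (n! permutations enumerated)
SPEARMAN_EXACT_MAX_N = 8


@dataclass(frozen=True)
class TwoGroupResult:
    statistic: float
    p: float
    test_used: str  # "t_student" | "mann_whitney"
    mean_diff: float  # group2 - group1
    normality_p: tuple[float, float]
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str  # "exact_permutation" | "t_approximation" | "undefined"

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < 0.05)


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    anova_p: float
    posthoc_p: tuple[float, ...] | None  # one per non-control group, None if suppressed
    suppressed: bool


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p, with constant input reported as decisively non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def two_group_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> TwoGroupResult:
    """Compare two independent groups (``y`` minus ``x`` is the reported effect).

    mode="auto" applies the Shapiro-Wilk gate to each group at alpha = 0.05:
    if both pass, a two-tailed unpaired Student t-test; otherwise the
    Mann-Whitney U test, with the exact two-sided p by enumeration when the
    pooled sample has no ties and at most 12 observations, and the normal
    approximation with tie correction beyond that.  mode="force_t" and
    mode="force_mwu" bypass the gate.

    Both groups constant with equal values is degenerate: p = 1 by
    convention, flagged.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("groups must be 1-D")
    min_n = 3 if mode == "auto" else 2
    if a.size < min_n or b.size < min_n:
        raise ValidationError(f"each group needs n >= {min_n} for mode={mode!r}")
    if mode not in {"auto", "force_t", "force_mwu"}:
        raise ValidationError(f"unknown mode {mode!r}")

    mean_diff = float(b.mean() - a.mean())
    norm_p = (_shapiro_p(a), _shapiro_p(b))

    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        test = "t_student" if mode == "force_t" else "mann_whitney"
        return TwoGroupResult(0.0, 1.0, test, 0.0, norm_p, degenerate=True)

    if mode == "force_t":
        use_t = True
    elif mode == "force_mwu":
        use_t = False
    else:
        use_t = norm_p[0] >= NORMALITY_ALPHA and norm_p[1] >= NORMALITY_ALPHA

    if use_t:
        res = sps.ttest_ind(b, a, equal_var=True)
        return TwoGroupResult(float(res.statistic), float(res.pvalue), "t_student", mean_diff, norm_p)

    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= MWU_EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method)
    return TwoGroupResult(float(res.statistic), float(res.pvalue), "mann_whitney", mean_diff, norm_p)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is the Pearson correlation of average ranks (ties allowed).  For
    n <= 8 the two-sided p enumerates all n! rank permutations of one
    variable (fraction with |rho| at least as extreme); for larger n the
    usual t approximation with n - 2 degrees of freedom is used.

    A constant input vector leaves rho undefined; the result is flagged
    with method="undefined" and NaN values.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("x and y must be 1-D and equal length")
    n = a.size
    if n < 4:
        raise ValidationError("need n >= 4 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "undefined")

    rx = sps.rankdata(a)
    ry = sps.rankdata(b)
    rho = _rank_pearson(rx, ry)

    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        denom = np.sqrt((pc**2).sum(axis=1) * float(rxc @ rxc))
        rhos = num / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, "exact_permutation")

    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, "t_approximation")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, min(p, 1.0), n, "t_approximation")


def anova_dunnett(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
) -> DunnettResult:
    """One-way ANOVA with Dunnett's many-to-one comparisons against a control.

    The post hoc p-values (multivariate-t, equal-correlation structure) are
    computed only when the ANOVA F test reaches p < 0.05; otherwise they
    are suppressed and the result flagged, mirroring the gated convention.
    ``posthoc_p`` is ordered as the non-control groups appear in ``groups``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 3:
        raise ValidationError("need >= 3 groups; use two_group_test for two")
    if any(a.size < 2 for a in arrs):
        raise ValidationError("each group needs n >= 2")
    if not 0 <= control_index < len(arrs):
        raise ValidationError(f"control_index {control_index} out of range")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = sps.f_oneway(*arrs)
    f_stat = float(f_res.statistic) if np.isfinite(f_res.statistic) else 0.0
    anova_p = float(f_res.pvalue) if np.isfinite(f_res.pvalue) else 1.0

    if anova_p >= 0.05:
        return DunnettResult(f_stat, anova_p, None, suppressed=True)

    control = arrs[control_index]
    others = [a for i, a in enumerate(arrs) if i != control_index]
    # fixed rng: the multivariate-t tail probability is evaluated by
    # quasi-Monte Carlo, so without it repeated calls differ in ~1e-4
    res = sps.dunnett(*others, control=control, rng=np.random.default_rng(0))
    return DunnettResult(f_stat, anova_p, tuple(float(p) for p in res.pvalue), suppressed=False)


def iqr_outliers(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Tukey fence outlier rule, iterated to a fixed point.

    Points outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are removed and the fences
    recomputed on the survivors until no point falls outside (a single
    pass is not idempotent: removing an extreme point shrinks the IQR, so
    the rule is applied until stable, keeping at least 4 points).
    Returns ``(kept_values, removed_indices)`` with indices into the
    original vector.  Off by default in every pipeline stage; offered as a
    transparent, documented alternative to proprietary robust-regression
    outlier calls.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise ValidationError("need a 1-D vector with n >= 4")
    keep = np.ones(v.size, dtype=bool)
    while keep.sum() >= 4:
        q1, q3 = np.percentile(v[keep], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        new_keep = keep & (v >= lo) & (v <= hi)
        if new_keep.sum() == keep.sum() or new_keep.sum() < 4:
            break
        keep = new_keep
    return v[keep], np.flatnonzero(~keep)
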