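"""Group-comparison statistics for three-group (C/F/FT) endpoint tables.

Mirrors the study's analysis plan: Lilliefors/Kolmogorov-Smirnov
normality screening, one-way ANOVA with the Student-Newman-Keuls (SNK)
step-down post-test on the studentized range, repeated-measures
(split-plot) ANOVA for before/after designs, and Pearson correlation.
Alpha defaults to 0.05 with two-sided tests throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    df: tuple
    p_value: float
    means: dict[str, float] = field(default_factory=dict)
    sems: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def _as_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {k!r} contains non-finite values")
    return out


def normality(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated mean/SD (Lilliefors).

    Returns ``(statistic, p_value)``.  Requires n >= 4; constant samples
    are rejected (the test statistic is undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def one_way_anova(groups: dict[str, np.ndarray]) -> TestResult:
    """Classical one-way fixed-effects ANOVA: F = MS_between / MS_within."""
    data = _as_groups(groups)
    k = len(data)
    ns = {g: v.size for g, v in data.items()}
    n_total = sum(ns.values())
    grand = sum(v.sum() for v in data.values()) / n_total
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, n_total - k
    means = {g: float(v.mean()) for g, v in data.items()}
    sems = {g: float(v.std(ddof=1) / math.sqrt(v.size)) for g, v in data.items()}
    flags: list[str] = []
    if ss_within == 0:
        if ss_between == 0:
            flags.append("all values identical: F undefined")
            return TestResult(math.nan, (df_b, df_w), math.nan, means, sems, flags)
        flags.append("zero within-group variance")
        return TestResult(math.inf, (df_b, df_w), 0.0, means, sems, flags)
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return TestResult(float(f_stat), (df_b, df_w), p, means, sems, flags,
                      extra={"ms_within": ss_within / df_w, "ns": ns})


def snk_posthoc(groups: dict[str, np.ndarray], alpha: float = DEFAULT_ALPHA,
                require_significant: bool = False) -> dict:
    """Student-Newman-Keuls step-down multiple comparisons.

    Group means are sorted; a pair spanning ``r`` ordered means is declared
    different when its mean difference exceeds
    ``q(1 - alpha, r, df_within) * sqrt(MS_within / n)`` (harmonic-mean n
    for unequal group sizes, flagged).  A non-significant stretch protects
    every pair inside it, the defining step-down property of SNK.

    Returns ``{"pairs": {(a, b): bool}, "anova": TestResult, "flags": [...]}``.
    """
    data = _as_groups(groups)
    anova = one_way_anova(data)
    flags = list(anova.flags)
    pairs: dict[tuple[str, str], bool] = {}
    names = sorted(data, key=lambda g: data[g].mean())
    k = len(names)
    for i in range(k):
        for j in range(i + 1, k):
            pairs[(names[i], names[j])] = False
    gate_closed = require_significant and not (anova.p_value < alpha)
    if gate_closed:
        flags.append("omnibus ANOVA not significant: all pairs declared ns")
    if not math.isfinite(anova.statistic) or gate_closed:
        return {"pairs": pairs, "anova": anova, "flags": flags}

    ns = [data[g].size for g in names]
    if len(set(ns)) > 1:
        flags.append("unequal group sizes: harmonic mean n used")
    n_h = len(ns) / sum(1.0 / n for n in ns)
    ms_w = anova.extra["ms_within"]
    df_w = anova.df[1]
    se = math.sqrt(ms_w / n_h)
    means = [data[g].mean() for g in names]

    protected = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):           # step down from the widest stretch
        q_crit = float(sps.studentized_range.ppf(1.0 - alpha, span, df_w))
        for i in range(0, k - span + 1):
            j = i + span - 1
            if protected[i, j]:
                continue
            if (means[j] - means[i]) / se > q_crit:
                pairs[(names[i], names[j])] = True
            else:                          # protect all inner pairs
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        protected[a, b] = True
    return {"pairs": pairs, "anova": anova, "flags": flags}


def repeated_measures(before: dict[str, np.ndarray],
                      after: dict[str, np.ndarray]) -> dict[str, TestResult]:
    """Two-time split-plot ANOVA: group (between) x time (within subject).

    ``before``/``after`` map group names to per-animal values in matching
    order.  Animals with a missing value at either time are dropped
    listwise (with a warning).  With two time points sphericity holds
    trivially, so no correction is applied.  Returns TestResults for the
    "group", "time" and "interaction" effects.
    """
    if set(before) != set(after):
        raise ValueError("before/after must cover the same groups")
    y = {}
    for g in before:
        b = np.asarray(before[g], dtype=float)
        a = np.asarray(after[g], dtype=float)
        if b.size != a.size:
            raise ValueError(f"group {g!r}: unequal before/after lengths")
        ok = np.isfinite(b) & np.isfinite(a)
        if not ok.all():
            warnings.warn(f"group {g!r}: dropping {int((~ok).sum())} animals "
                          "with missing pairs", stacklevel=2)
        if ok.sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 complete pairs")
        y[g] = np.stack([b[ok], a[ok]], axis=1)   # (n_subjects, 2 times)

    groups = sorted(y)
    a_levels = len(groups)
    n_i = {g: y[g].shape[0] for g in groups}
    n_total = sum(n_i.values())
    all_y = np.concatenate([y[g] for g in groups], axis=0)
    mu = all_y.mean()

    subj_means = {g: y[g].mean(axis=1) for g in groups}
    grp_means = {g: y[g].mean() for g in groups}
    time_means = all_y.mean(axis=0)
    cell_means = {g: y[g].mean(axis=0) for g in groups}

    ss_group = sum(2 * n_i[g] * (grp_means[g] - mu) ** 2 for g in groups)
    ss_between_subj = sum(2 * ((subj_means[g] - mu) ** 2).sum() for g in groups)
    ss_subj_within = ss_between_subj - ss_group
    ss_time = sum(n_total * (tm - mu) ** 2 for tm in time_means)
    ss_cells = sum(n_i[g] * ((cell_means[g] - mu) ** 2).sum() for g in groups)
    ss_int = ss_cells - ss_group - ss_time
    ss_within_subj = sum(((y[g] - subj_means[g][:, None]) ** 2).sum() for g in groups)
    ss_resid = ss_within_subj - ss_time - ss_int

    df_group, df_subj = a_levels - 1, n_total - a_levels
    df_time, df_int, df_resid = 1, a_levels - 1, n_total - a_levels

    def _res(ss_eff, df_eff, ss_err, df_err) -> TestResult:
        if ss_err <= 0 or df_eff == 0:
            return TestResult(math.nan, (df_eff, df_err), math.nan,
                              flags=["degenerate error term"])
        f_stat = (ss_eff / df_eff) / (ss_err / df_err)
        return TestResult(float(f_stat), (df_eff, df_err),
                          float(sps.f.sf(f_stat, df_eff, df_err)))

    out = {
        "time": _res(ss_time, df_time, ss_resid, df_resid),
        "interaction": _res(ss_int, df_int, ss_resid, df_resid)
        if a_levels > 1 else TestResult(math.nan, (0, df_resid), math.nan,
                                        flags=["single group: no interaction"]),
        "group": _res(ss_group, df_group, ss_subj_within, df_subj)
        if a_levels > 1 else TestResult(math.nan, (0, df_subj), math.nan,
                                        flags=["single group: no group effect"]),
    }
    if len(set(n_i.values())) > 1:
        for r in out.values():
            r.flags.append("unbalanced groups: weighted-means decomposition")
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
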