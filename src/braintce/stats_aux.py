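"""Supporting statistics: repeated-measures correlation, tSNR maps, group tests.

The repeated-measures correlation r_rm estimates the common within-subject
association between two repeatedly measured variables: an analysis of
covariance with one intercept per subject and a single shared slope for x.
It asks "when x goes up within a person, does y go up?" while removing
stable between-person differences. Here it relates, per subject, the
whole-brain cost of each hierarchy-transition class to how often that class
of transition occurred.

Group comparisons (hemisphere, age bins) are thin wrappers over the
standard scipy tests; the temporal signal-to-noise ratio map summarizes raw
(pre-standardization) signal quality per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = ["RepeatedMeasuresResult", "GroupCompareResult", "rmcorr", "tsnr_map", "group_compare"]


@dataclass(frozen=True)
class RepeatedMeasuresResult:
    r_rm: float
    degrees_of_freedom: int
    p_value: float
    common_slope: float


@dataclass(frozen=True)
class GroupCompareResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]


def rmcorr(subject_ids, x, y) -> RepeatedMeasuresResult:
    """Repeated-measures correlation via ANCOVA with a common slope.

    Fits ``y ~ subject intercepts + slope * x`` by least squares;
    ``r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_error))`` where ``SS_x``
    is the sum of squares attributable to the shared slope (full-model SSE
    subtracted from the intercepts-only SSE). The F test of the slope uses
    ``df = n_observations - n_subjects - 1``.
    """
    subject_ids = np.asarray(subject_ids)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (subject_ids.size == x.size == y.size):
        raise ValueError("subject_ids, x, y must have equal length")
    subjects, codes = np.unique(subject_ids, return_inverse=True)
    k = subjects.size
    n = x.size
    counts = np.bincount(codes)
    if k < 2:
        raise ValueError("need at least 2 subjects")
    if counts.min() < 2:
        raise ValueError(f"subject {subjects[counts.argmin()]} has fewer than 2 observations")
    df = n - k - 1
    if df <= 0:
        raise ValueError("nonpositive error degrees of freedom")

    # subject-dummy design; full model adds the common slope for x
    D = np.zeros((n, k))
    D[np.arange(n), codes] = 1.0
    X_full = np.column_stack([D, x])
    coef, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    slope = float(coef[-1])
    sse_full = float(np.sum((y - X_full @ coef) ** 2))
    # intercepts-only model: residual = within-subject centering of y
    y_centered = y - (np.bincount(codes, weights=y) / counts)[codes]
    sse_reduced = float(np.sum(y_centered**2))
    x_centered = x - (np.bincount(codes, weights=x) / counts)[codes]
    if np.allclose(x_centered, 0.0):
        raise ValueError("zero within-subject variance in x")

    ss_effect = max(sse_reduced - sse_full, 0.0)
    denom = ss_effect + sse_full
    r = np.sqrt(ss_effect / denom) if denom > 0 else 0.0
    r_rm = float(np.sign(slope) * r) if slope != 0 else float(r)
    if sse_full == 0.0:
        p = 0.0
    else:
        F = (ss_effect / 1.0) / (sse_full / df)
        p = float(scipy.stats.f.sf(F, 1, df))
    return RepeatedMeasuresResult(
        r_rm=r_rm, degrees_of_freedom=df, p_value=p, common_slope=slope
    )


def tsnr_map(raw: np.ndarray, run_boundaries: list[int] | None = None) -> np.ndarray:
    """Temporal SNR per region: mean/SD of the raw signal, min-max rescaled.

    Computed per run (mean over SD with sample SD), rescaled to [0, 1]
    across regions within the run, then averaged across runs.
    """
    raw = np.asarray(raw, dtype=float)
    starts = list(run_boundaries or [0]) + [raw.shape[0]]
    maps = []
    for a, b in zip(starts[:-1], starts[1:]):
        block = raw[a:b]
        if block.shape[0] < 2:
            raise ValueError(f"run [{a}:{b}) too short for tSNR")
        sd = block.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero-SD region at column {bad[0]} in run [{a}:{b})")
        t = block.mean(axis=0) / sd
        span = t.max() - t.min()
        maps.append((t - t.min()) / span if span > 0 else np.zeros_like(t))
    return np.mean(maps, axis=0)


def group_compare(values, groups, test: str) -> GroupCompareResult:
    """Standard two-or-more-sample tests keyed by name.

    ``mannwhitney`` (exactly two groups, two-sided), ``anova`` (one-way F),
    ``levene`` (homogeneity of variances).
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups)
    names = [str(g) for g in np.unique(groups)]
    samples = [values[groups == g] for g in np.unique(groups)]
    sizes = {name: int(s.size) for name, s in zip(names, samples)}
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need at least two nonempty groups")
    if test == "mannwhitney":
        if len(samples) != 2:
            raise ValueError("mannwhitney requires exactly two groups")
        res = scipy.stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif test == "anova":
        res = scipy.stats.f_oneway(*samples)
    elif test == "levene":
        if any(s.size < 2 for s in samples):
            raise ValueError("levene requires at least two observations per group")
        res = scipy.stats.levene(*samples)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupCompareResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=sizes,
    )
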