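"""Antibiotic-exposure variables and their association with vaccine
response.

The prescription log is a long-format table of courses
(``subject_id, route, start_day, duration_days``) with route one of
oral / IM / IV / topical. Analysis is restricted to systemic routes and,
for the count variables, to oral courses. Cumulative exposure is the
size of the union of exposed calendar days, so overlapping courses are
not double counted.

Cumulative oral exposure days in the first year follow a zero-inflated
Poisson (ZIP) law: with probability ``pi`` a subject is a structural
zero, otherwise the day count is Poisson(``lambda``). Group comparison
uses an omnibus likelihood-ratio test on 2 df, decomposed post hoc into
a zero component (exposed vs unexposed, Fisher exact) and a count
component (rank-sum on the positive counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

ROUTES = ("oral", "IM", "IV", "topical")
SYSTEMIC_ROUTES = ("oral", "IM", "IV")

EXPOSURE_COLUMNS = ["subject_id", "route", "start_day", "duration_days"]


def _check_log(log: pd.DataFrame) -> None:
    missing = [c for c in EXPOSURE_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"exposure log missing columns: {missing}")
    bad = set(log["route"]) - set(ROUTES)
    if bad:
        raise ValueError(f"unknown routes {sorted(bad)}; valid routes are {ROUTES}")
    if (log["duration_days"] < 1).any():
        raise ValueError("duration_days must be >= 1")
    if (log["start_day"] < 0).any():
        raise ValueError("start_day must be >= 0")


def _course_days(row) -> range:
    return range(int(row.start_day), int(row.start_day) + int(row.duration_days))


def cumulative_oral_days(log: pd.DataFrame, cutoff_day: int = 365) -> pd.Series:
    """Union of oral-exposure calendar days before ``cutoff_day``, per subject."""
    _check_log(log)
    oral = log[log["route"] == "oral"]
    out: dict = {}
    for subject, grp in oral.groupby("subject_id"):
        days: set[int] = set()
        for row in grp.itertuples():
            days.update(d for d in _course_days(row) if d < cutoff_day)
        out[subject] = len(days)
    return pd.Series(out, dtype=int, name=f"cumulative_oral_days_{cutoff_day}")


def used_at_birth(log: pd.DataFrame, birth_window_days: int = 7) -> pd.Series:
    """True iff any systemic course starts within the first week of life.

    The birth window (default days 0-7 inclusive) is configurable since
    "at the time of birth" has no canonical day bound.
    """
    _check_log(log)
    systemic = log[log["route"].isin(SYSTEMIC_ROUTES)]
    flags = systemic.groupby("subject_id")["start_day"].apply(
        lambda s: bool((s <= birth_window_days).any())
    )
    return flags.rename("used_at_birth")


def use_in_window(
    log: pd.DataFrame, day: int, window_days: int = 7, routes=("oral",)
) -> pd.Series:
    """True iff any course of the given routes overlaps [day - window, day]."""
    _check_log(log)
    sub = log[log["route"].isin(routes)]
    lo = day - window_days

    def overlaps(grp: pd.DataFrame) -> bool:
        start = grp["start_day"]
        end = grp["start_day"] + grp["duration_days"] - 1
        return bool(((start <= day) & (end >= lo)).any())

    return sub.groupby("subject_id").apply(overlaps, include_groups=False).rename(
        f"use_within_{window_days}d_of_{day}"
    )


def current_use(log: pd.DataFrame, day: int, routes=("oral",)) -> pd.Series:
    """True iff a course of the given routes covers the given day."""
    return use_in_window(log, day, window_days=0, routes=routes).rename(
        f"current_use_{day}"
    )


def build_exposure_variables(
    log: pd.DataFrame,
    subjects: pd.Index | list,
    cutoff_day: int = 365,
    birth_window_days: int = 7,
) -> pd.DataFrame:
    """Per-subject exposure variables over a fixed subject roster.

    Subjects absent from the log get zero exposure. Cumulative days are
    clipped to [0, cutoff_day) by construction and can never exceed it.
    """
    _check_log(log)
    idx = pd.Index(subjects, name="subject_id")
    out = pd.DataFrame(index=idx)
    out["cumulative_oral_days"] = cumulative_oral_days(log, cutoff_day).reindex(
        idx, fill_value=0
    )
    out["used_at_birth"] = (
        used_at_birth(log, birth_window_days).reindex(idx, fill_value=False).astype(bool)
    )
    return out


def summarize_courses(log: pd.DataFrame) -> pd.DataFrame:
    """Course counts and percentages by route (over all logged courses)."""
    _check_log(log)
    counts = log["route"].value_counts().reindex(ROUTES, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "route": counts.index,
            "n_courses": counts.to_numpy(),
            "pct": 100.0 * counts.to_numpy() / total if total else 0.0,
        }
    )


# ---------------------------------------------------------------------------
# 2x2 exact test


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Zero-inflated Poisson


@dataclass(frozen=True)
class ZipModel:
    """Intercept-only zero-inflated Poisson maximum-likelihood fit.

    ``P(0) = pi + (1-pi) e^{-lambda}``,
    ``P(k) = (1-pi) lambda^k e^{-lambda} / k!`` for k >= 1.
    ``degenerate`` flags boundary fits (all observations zero).
    """

    pi: float
    lam: float
    loglik: float
    degenerate: bool = False


def zip_loglik(counts: np.ndarray, pi: float, lam: float) -> float:
    """ZIP log-likelihood at (pi, lambda); -inf outside the support."""
    counts = np.asarray(counts)
    if not (0 <= pi <= 1) or lam < 0:
        return -np.inf
    n0 = int((counts == 0).sum())
    pos = counts[counts > 0]
    with np.errstate(divide="ignore"):
        ll0 = n0 * np.log(pi + (1 - pi) * np.exp(-lam)) if n0 else 0.0
        if len(pos):
            if pi >= 1 or lam == 0:
                return -np.inf
            llp = len(pos) * np.log(1 - pi) + np.sum(
                stats.poisson.logpmf(pos, lam)
            )
        else:
            llp = 0.0
    return float(ll0 + llp)


def _profile_pi(lam: float, p0: float) -> float:
    # MLE of pi given lambda equates fitted and empirical zero mass.
    q = np.exp(-lam)
    if q >= 1.0:
        return max(0.0, min(1.0, p0))
    return float(np.clip((p0 - q) / (1 - q), 0.0, 1.0))


def zip_fit(counts) -> ZipModel:
    """Maximum-likelihood fit of the intercept-only ZIP model.

    Profiles pi out analytically (the MLE matches the fitted zero
    probability to the empirical zero fraction whenever that is
    feasible) and maximizes the one-dimensional profile likelihood in
    lambda numerically. Data with no zeros sit on the ``pi = 0``
    boundary where lambda reduces to the Poisson MLE (the sample mean);
    all-zero data are a degenerate ``pi -> 1`` boundary fit.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-D sample of size >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(int)

    n = counts.size
    n0 = int((counts == 0).sum())
    p0 = n0 / n
    if n0 == n:
        return ZipModel(pi=1.0, lam=0.0, loglik=0.0, degenerate=True)
    if n0 == 0:
        lam = float(counts.mean())
        return ZipModel(pi=0.0, lam=lam, loglik=zip_loglik(counts, 0.0, lam))

    def neg_profile(lam: float) -> float:
        return -zip_loglik(counts, _profile_pi(lam, p0), lam)

    pos_mean = counts[counts > 0].mean()
    res = optimize.minimize_scalar(
        neg_profile, bounds=(1e-8, max(2 * pos_mean, 10.0)), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(res.x)
    pi = _profile_pi(lam, p0)
    return ZipModel(pi=pi, lam=lam, loglik=zip_loglik(counts, pi, lam))


def zip_omnibus_lrt(counts_a, counts_b) -> tuple[float, float, bool]:
    """Omnibus 2-df likelihood-ratio test of ZIP equality across groups.

    Statistic: ``2 * (loglik_a + loglik_b - loglik_pooled)``, referred
    to chi-square with 2 degrees of freedom (both pi and lambda free
    per group under the alternative).

    Returns ``(statistic, p_value, degenerate)``; ``degenerate`` is True
    when any component fit sat on a boundary (all-zero group), in which
    case the chi-square reference is unreliable and the result is
    flagged rather than silently reported.
    """
    counts_a, counts_b = np.asarray(counts_a), np.asarray(counts_b)
    if counts_a.size == 0 or counts_b.size == 0:
        raise ValueError("both groups must be non-empty")
    fit_a = zip_fit(counts_a)
    fit_b = zip_fit(counts_b)
    fit_p = zip_fit(np.concatenate([counts_a, counts_b]))
    stat = max(0.0, 2.0 * (fit_a.loglik + fit_b.loglik - fit_p.loglik))
    p = float(stats.chi2.sf(stat, df=2))
    degenerate = fit_a.degenerate or fit_b.degenerate or fit_p.degenerate
    return stat, p, degenerate


def zip_component_tests(counts_a, counts_b) -> tuple[float, float]:
    """Post-hoc decomposition of a ZIP group difference.

    Zero component: Fisher exact on the 2x2 of (zero, positive) counts
    per group — "was the fraction never exposed different?". Count
    component: Wilcoxon rank-sum restricted to the strictly positive
    counts — "among the exposed, was exposure heavier?". The count
    component is NaN when either group has no positive counts.
    """
    a, b = np.asarray(counts_a), np.asarray(counts_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    table = [
        [int((a == 0).sum()), int((a > 0).sum())],
        [int((b == 0).sum()), int((b > 0).sum())],
    ]
    zero_p = fisher_exact_2x2(table)
    pos_a, pos_b = a[a > 0], b[b > 0]
    if len(pos_a) == 0 or len(pos_b) == 0:
        return zero_p, float("nan")
    count_p = float(stats.mannwhitneyu(pos_a, pos_b, alternative="two-sided")[1])
    return zero_p, count_p
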