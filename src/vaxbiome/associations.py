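"""Cross-sectional association of features with vaccine-response
outcomes.

Samples are matched to nominal study time points through age windows
(e.g. the "2 months" window spans days 46-75); when a subject has
several samples inside one window, the sample closest to the window
center is used. Each feature is tested against the categorical outcome
with a Mann-Whitney U test and against each continuous composite with
Spearman's rho. Benjamini-Hochberg correction is applied separately per
(assay x time point x outcome) family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .multiplicity import bh_adjust

CONTINUOUS_OUTCOMES = ("median_cross", "median_dtap_hib", "median_pcv")

#: Default age windows (days) for the nominal analysis time points.
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "2mo": (46, 75),
    "4mo": (107, 137),
    "6mo": (168, 198),
    "1yr": (335, 395),
}


@dataclass(frozen=True)
class TimepointWindow:
    label: str
    lo: int
    hi: int

    @property
    def center(self) -> float:
        return (self.lo + self.hi) / 2.0

    def contains(self, age_days: float) -> bool:
        return self.lo <= age_days <= self.hi


def make_windows(bounds: dict[str, tuple[int, int]] | None = None) -> list[TimepointWindow]:
    """Build (and validate) a non-overlapping window list."""
    bounds = bounds if bounds is not None else DEFAULT_WINDOWS
    windows = [TimepointWindow(label, int(lo), int(hi)) for label, (lo, hi) in bounds.items()]
    windows.sort(key=lambda w: w.lo)
    for a, b in zip(windows, windows[1:]):
        if b.lo <= a.hi:
            raise ValueError(f"windows {a.label!r} and {b.label!r} overlap")
    return windows


def assign_timepoint(age_days: float, windows: list[TimepointWindow]) -> str | None:
    """Label of the window containing ``age_days``, or None."""
    for w in windows:
        if w.contains(age_days):
            return w.label
    return None


def select_window_samples(
    meta: pd.DataFrame, window: TimepointWindow
) -> pd.DataFrame:
    """One sample per subject inside a window, nearest to its center.

    ``meta`` needs columns ``subject_id, age_days`` with sample ids on
    the index. Ties on distance-to-center break toward the earlier
    sample.
    """
    inside = meta[meta["age_days"].apply(window.contains)].copy()
    if inside.empty:
        return inside
    inside["_dist"] = (inside["age_days"] - window.center).abs()
    inside = inside.sort_values(["_dist", "age_days"], kind="mergesort")
    picked = inside.groupby("subject_id", sort=False).head(1)
    return picked.drop(columns="_dist").sort_index()


# ---------------------------------------------------------------------------
# Per-feature tests

_EXACT_MAX_N = 12


def _mwu_exact_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Full enumeration of group assignments of the pooled sample;
    # tie-safe because U is computed on each relabeling directly.
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mean_u = nx * (n - nx) / 2.0
    dev_obs = abs(u_obs - mean_u)
    hits = 0
    total = comb(n, nx)
    for idx in combinations(range(n), nx):
        u = float(ranks[list(idx)].sum() - nx * (nx + 1) / 2)
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def mwu_association(x, y) -> tuple[float, float]:
    """Mann-Whitney U test of a feature between two outcome groups.

    Exact two-sided p by full enumeration of relabelings when the
    combined sample size is at most 12 (tie-safe); otherwise the normal
    approximation with tie correction. Returns ``(U, p)``; if either
    group is empty the result is (NaN, NaN).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan")
    if len(x) + len(y) <= _EXACT_MAX_N:
        return _mwu_exact_enumeration(x, y)
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def spearman_association(x, y, min_n: int = 4) -> tuple[float, float, int]:
    """Spearman rank correlation of a feature with a continuous outcome.

    Pairs with a missing value on either side are dropped. Returns
    ``(rho, p, n)``; rho is NaN when fewer than ``min_n`` complete pairs
    remain or either vector is constant.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_n or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


# ---------------------------------------------------------------------------
# Screen

RESULT_COLUMNS = [
    "assay", "feature_id", "outcome", "timepoint",
    "statistic", "raw_p", "adjusted_p", "direction", "n",
]


def _screen_family(
    values: pd.DataFrame, outcome_name: str, outcome: pd.Series,
    assay: str, timepoint: str,
) -> list[dict]:
    """Test every feature column of ``values`` against one outcome.

    ``values`` and ``outcome`` are indexed by subject. Categorical
    outcomes use Mann-Whitney (direction = sign of median difference
    LVR - NVR); continuous outcomes use Spearman (direction = sign of
    rho).
    """
    rows = []
    if outcome_name == "category":
        is_lvr = outcome == "LVR"
        is_nvr = outcome == "NVR"
        for feat in values.columns:
            v = values[feat]
            x, y = v[is_lvr].to_numpy(), v[is_nvr].to_numpy()
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            stat, p = mwu_association(x, y)
            if np.isnan(p):
                continue
            direction = float(np.sign(np.median(x) - np.median(y)))
            rows.append(dict(assay=assay, feature_id=feat, outcome=outcome_name,
                             timepoint=timepoint, statistic=stat, raw_p=p,
                             direction=direction, n=len(x) + len(y)))
    else:
        for feat in values.columns:
            rho, p, n = spearman_association(values[feat], outcome)
            if np.isnan(p):
                continue
            rows.append(dict(assay=assay, feature_id=feat, outcome=outcome_name,
                             timepoint=timepoint, statistic=rho, raw_p=p,
                             direction=float(np.sign(rho)), n=n))
    return rows


def run_association_screen(
    feature_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    outcomes: pd.DataFrame,
    windows: list[TimepointWindow] | None = None,
    timepoints: list[str] | None = None,
    outcome_names: list[str] | None = None,
) -> pd.DataFrame:
    """Run the full per-feature association screen.

    Parameters
    ----------
    feature_tables
        ``assay -> (values, meta)`` where ``values`` is a samples x
        features table (counts or continuous abundances) and ``meta``
        carries ``subject_id, age_days`` per sample id.
    outcomes
        Outcome table with ``subject_id, category`` and the continuous
        composites.
    windows, timepoints
        Age windows and the window labels to screen (default: 2mo).
    outcome_names
        Outcomes to test (default: category + the three composites).

    Returns
    -------
    Tidy results with one BH family per (assay x timepoint x outcome);
    ``adjusted_p`` is BH within that family.
    """
    windows = windows if windows is not None else make_windows()
    timepoints = timepoints if timepoints is not None else ["2mo"]
    outcome_names = (
        outcome_names if outcome_names is not None
        else ["category", *CONTINUOUS_OUTCOMES]
    )
    by_label = {w.label: w for w in windows}
    out = outcomes.set_index("subject_id")

    all_rows: list[dict] = []
    for assay, (values, meta) in feature_tables.items():
        for label in timepoints:
            picked = select_window_samples(meta, by_label[label])
            if picked.empty:
                continue
            vals = values.loc[picked.index].copy()
            vals.index = picked["subject_id"].to_numpy()
            vals = vals.loc[vals.index.intersection(out.index)]
            for name in outcome_names:
                if name not in out.columns:
                    continue
                outcome = out.loc[vals.index, name]
                all_rows.extend(_screen_family(vals, name, outcome, assay, label))
    result = pd.DataFrame(all_rows, columns=[c for c in RESULT_COLUMNS if c != "adjusted_p"])
    if result.empty:
        result["adjusted_p"] = []
        return result[RESULT_COLUMNS]
    result["adjusted_p"] = np.nan
    for _, idx in result.groupby(["assay", "timepoint", "outcome"]).groups.items():
        result.loc[idx, "adjusted_p"] = bh_adjust(result.loc[idx, "raw_p"])
    return result[RESULT_COLUMNS]
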