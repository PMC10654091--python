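"""Antibody-titer processing: outlier removal, responder classification,
min-max normalization and composite response outcomes.

A titer table is a long-format :class:`pandas.DataFrame` with columns
``subject_id, antigen, timepoint, value`` (and optionally ``units``); at
most one value per (subject, antigen, timepoint), values non-negative.

The outcome variables are:

* a categorical low/normal vaccine responder (LVR/NVR) label — LVR when
  four or more of the six DTaP/Hib titers lie strictly below their
  protective thresholds at the assessment time point;
* three continuous composites: the per-subject median of the min-max
  normalized titers across all antigens ("cross-vaccine"), across the
  DTaP/Hib antigens, and across the PCV serotypes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import DTAP_HIB_ANTIGENS, PCV_ANTIGENS, PROTECTIVE_THRESHOLDS

logger = logging.getLogger(__name__)

TITER_COLUMNS = ["subject_id", "antigen", "timepoint", "value"]

LVR = "LVR"
NVR = "NVR"
UNKNOWN = "unknown"


def _check_titer_table(titers: pd.DataFrame) -> None:
    missing = [c for c in TITER_COLUMNS if c not in titers.columns]
    if missing:
        raise ValueError(f"titer table missing columns: {missing}")
    if (titers["value"] < 0).any():
        raise ValueError("titer values must be non-negative")
    dup = titers.duplicated(subset=["subject_id", "antigen", "timepoint"])
    if dup.any():
        raise ValueError(
            "duplicate (subject, antigen, timepoint) rows at positions "
            f"{list(titers.index[dup])[:5]}"
        )


def remove_outliers(
    titers: pd.DataFrame, n_sd: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove titers more than ``n_sd`` standard deviations from their
    (antigen, timepoint) group mean.

    The pass is single-shot: mean and SD (sample SD, ``ddof=1``) are
    computed over the full group including each candidate value, and a
    value is removed iff ``|v - mean| > n_sd * SD`` (strict; a value
    exactly at the fence is retained). Groups of size 1 are retained
    unchanged and logged as untestable.

    Returns
    -------
    (kept, removal_log)
        ``kept`` is the filtered table; ``removal_log`` has one row per
        removed value plus per-group ``untestable`` notes, with columns
        ``subject_id, antigen, timepoint, value, reason``.
    """
    _check_titer_table(titers)
    log_rows: list[dict] = []
    keep_mask = pd.Series(True, index=titers.index)
    for (antigen, timepoint), grp in titers.groupby(["antigen", "timepoint"], sort=False):
        if len(grp) < 2:
            for _, row in grp.iterrows():
                log_rows.append(
                    dict(subject_id=row.subject_id, antigen=antigen,
                         timepoint=timepoint, value=row.value, reason="untestable")
                )
            continue
        mean = grp["value"].mean()
        sd = grp["value"].std(ddof=1)
        out = (grp["value"] - mean).abs() > n_sd * sd
        for _, row in grp[out].iterrows():
            keep_mask.loc[row.name] = False
            log_rows.append(
                dict(subject_id=row.subject_id, antigen=antigen,
                     timepoint=timepoint, value=row.value, reason="outlier")
            )
    removal_log = pd.DataFrame(
        log_rows, columns=["subject_id", "antigen", "timepoint", "value", "reason"]
    )
    return titers[keep_mask].copy(), removal_log


def classify_responder(
    subject_titers: pd.DataFrame | dict[str, float],
    thresholds: dict[str, float] | None = None,
    min_below: int = 4,
) -> str:
    """Classify one subject's assessment-time DTaP/Hib titers as LVR/NVR.

    LVR iff at least ``min_below`` of the measured DTaP/Hib titers are
    strictly below their protective thresholds. NVR only when all six
    antigens were measured and fewer than ``min_below`` fall below;
    with missing antigens and fewer than ``min_below`` sub-threshold
    values the label is ``unknown`` (missingness cannot certify a
    normal response).

    Parameters
    ----------
    subject_titers
        Either a mapping ``antigen -> value`` or a titer-table slice for
        a single subject at a single time point.
    thresholds
        ``antigen -> protective threshold``; defaults to the established
        DTaP/Hib thresholds.

    Raises
    ------
    KeyError
        If an antigen without a threshold is passed in.
    """
    if thresholds is None:
        thresholds = PROTECTIVE_THRESHOLDS
    if isinstance(subject_titers, pd.DataFrame):
        if subject_titers["subject_id"].nunique() > 1:
            raise ValueError("classify_responder expects a single subject")
        values = dict(zip(subject_titers["antigen"], subject_titers["value"]))
    else:
        values = dict(subject_titers)
    for antigen in values:
        if antigen not in thresholds:
            raise KeyError(f"no protective threshold defined for antigen {antigen!r}")
    n_below = sum(1 for a, v in values.items() if v < thresholds[a])
    if n_below >= min_below:
        return LVR
    if set(values) >= set(thresholds):
        return NVR
    return UNKNOWN


def minmax_normalize(titers: pd.DataFrame) -> pd.DataFrame:
    """Min-max transform values within each (antigen, timepoint) group.

    The group minimum maps to 0 and the maximum to 1, preserving rank
    order and the shape of the distribution. A degenerate group whose
    values are all equal is set to 0.5 (scale information is absent;
    the midpoint leaves downstream medians unbiased) and a warning is
    logged.
    """
    _check_titer_table(titers)
    out = titers.copy()
    for (antigen, timepoint), grp in out.groupby(["antigen", "timepoint"], sort=False):
        lo, hi = grp["value"].min(), grp["value"].max()
        if hi == lo:
            logger.warning(
                "degenerate scale for antigen=%s timepoint=%s: all %d values "
                "equal; normalized to 0.5", antigen, timepoint, len(grp)
            )
            out.loc[grp.index, "value"] = 0.5
        else:
            out.loc[grp.index, "value"] = (grp["value"] - lo) / (hi - lo)
    return out


def composite_outcomes(normalized: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Per-subject median composites of normalized titers at a time point.

    Medians are taken over the antigens actually measured for the
    subject; a composite with zero available antigens is missing.

    Returns columns ``subject_id, median_cross, median_dtap_hib,
    median_pcv, n_cross, n_dtap_hib, n_pcv``.
    """
    sub = normalized[normalized["timepoint"] == timepoint]
    rows = []
    for subject, grp in sub.groupby("subject_id", sort=True):
        vals = dict(zip(grp["antigen"], grp["value"]))
        all_v = list(vals.values())
        dtap_v = [v for a, v in vals.items() if a in DTAP_HIB_ANTIGENS]
        pcv_v = [v for a, v in vals.items() if a in PCV_ANTIGENS]
        rows.append(
            dict(
                subject_id=subject,
                median_cross=float(np.median(all_v)) if all_v else np.nan,
                median_dtap_hib=float(np.median(dtap_v)) if dtap_v else np.nan,
                median_pcv=float(np.median(pcv_v)) if pcv_v else np.nan,
                n_cross=len(all_v), n_dtap_hib=len(dtap_v), n_pcv=len(pcv_v),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "median_cross", "median_dtap_hib", "median_pcv",
                 "n_cross", "n_dtap_hib", "n_pcv"],
    )


def compute_outcomes(
    titers: pd.DataFrame,
    timepoint: str = "1yr",
    thresholds: dict[str, float] | None = None,
    remove_outliers_first: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full outcome construction for one assessment time point.

    LVR/NVR classification applies the threshold rule to the measured
    titers directly: a value is above or below its protective threshold
    regardless of whether it is extreme for the cohort, and dropping an
    antigen from a subject can only turn a decidable label into
    ``unknown``. The population-level outlier pass (applied exactly
    once) feeds the min-max normalization and the median composites,
    where extreme values would distort the group scale.

    Returns ``(outcomes, outlier_log)`` where ``outcomes`` has columns
    ``subject_id, category, median_cross, median_dtap_hib, median_pcv,
    n_cross, n_dtap_hib, n_pcv``.
    """
    if thresholds is None:
        thresholds = PROTECTIVE_THRESHOLDS
    if remove_outliers_first:
        clean, outlier_log = remove_outliers(titers)
    else:
        clean, outlier_log = titers, pd.DataFrame(
            columns=["subject_id", "antigen", "timepoint", "value", "reason"]
        )
    at_tp = titers[titers["timepoint"] == timepoint]
    categories = {}
    for subject, grp in at_tp.groupby("subject_id", sort=True):
        dtap = grp[grp["antigen"].isin(thresholds)]
        categories[subject] = classify_responder(
            dict(zip(dtap["antigen"], dtap["value"])), thresholds
        )
    normalized = minmax_normalize(clean)
    outcomes = composite_outcomes(normalized, timepoint)
    outcomes.insert(1, "category", outcomes["subject_id"].map(categories).fillna(UNKNOWN))
    return outcomes, outlier_log
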