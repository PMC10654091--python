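"""Multiple-testing control: Benjamini-Hochberg and the grouped
two-stage ("double FDR") procedure.

The double-FDR procedure controls the false discovery rate at both the
group level and the individual-hypothesis level when hypotheses come in
a small number of scientifically coherent groups (here: cumulative,
recent, current, and at-birth antibiotic use). Stage 1 BH-adjusts one
representative p-value per group (the group minimum) across groups;
stage 2 BH-adjusts within each group; the final adjusted p-value of a
hypothesis is the maximum of its within-group adjusted value and its
group's stage-1 adjusted value.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def _validate_pvalues(p: np.ndarray) -> None:
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    _validate_pvalues(p)
    return multipletests(p, method="fdr_bh")[1]


def double_fdr(
    groups: Mapping[str, Sequence[tuple[str, float]]],
    q: float = 0.1,
) -> pd.DataFrame:
    """Two-stage grouped BH adjustment.

    Parameters
    ----------
    groups
        Mapping ``group label -> [(hypothesis id, raw p), ...]``. Every
        hypothesis belongs to exactly one group; groups must be
        non-empty.
    q
        FDR control level for the final reject decision.

    Returns
    -------
    DataFrame with columns ``hypothesis, group, raw_p, within_group_p,
    group_p, adjusted_p, reject`` where ``adjusted_p = max(within-group
    BH p, stage-1 group BH p)``; always >= raw p.
    """
    if not groups:
        raise ValueError("at least one hypothesis group is required")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    labels = list(groups)
    for g in labels:
        if len(groups[g]) == 0:
            raise ValueError(f"hypothesis group {g!r} is empty")
    hyp_ids = [h for g in labels for h, _ in groups[g]]
    if len(set(hyp_ids)) != len(hyp_ids):
        raise ValueError("a hypothesis appears in more than one group")

    # Stage 1: group representatives (minimum raw p), BH across groups.
    reps = np.array([min(p for _, p in groups[g]) for g in labels])
    _validate_pvalues(reps)
    group_adj = dict(zip(labels, bh_adjust(reps)))

    rows = []
    for g in labels:
        ids, raw = zip(*groups[g])
        within = bh_adjust(raw)
        for h, p, w in zip(ids, raw, within):
            adj = max(w, group_adj[g])
            rows.append(
                dict(hypothesis=h, group=g, raw_p=float(p),
                     within_group_p=float(w), group_p=float(group_adj[g]),
                     adjusted_p=float(adj), reject=bool(adj < q))
            )
    return pd.DataFrame(rows)
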