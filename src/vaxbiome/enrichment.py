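"""KEGG-module over-representation analysis of nominally significant
KOs.

Given the set of KOs nominally associated with an outcome and the
universe of KOs detected in the experiment, each KEGG module is tested
for over-representation with a one-sided Fisher exact (hypergeometric
tail) test. Modules are first intersected with the detected universe
and modules with fewer than five detected KOs are excluded; BH
correction runs across exactly the modules tested.
"""

from __future__ import annotations

import re

import pandas as pd
from scipy import stats

from .multiplicity import bh_adjust

MIN_MODULE_SIZE = 5
_KO_RE = re.compile(r"^K\d{5}$")

ENRICHMENT_COLUMNS = [
    "module_id", "k", "K", "n", "N", "p", "adjusted_p", "gene_ratio", "k_over_K",
]


def load_module_map(path_or_df) -> dict[str, set[str]]:
    """Read a two-column (module_id, ko_id) table into a module map."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep="\t"
    )
    for col in ("module_id", "ko_id"):
        if col not in df.columns:
            raise ValueError(f"module map needs column {col!r}")
    modules: dict[str, set[str]] = {}
    for module_id, grp in df.groupby("module_id"):
        modules[str(module_id)] = set(grp["ko_id"])
    for m, kos in modules.items():
        bad = [k for k in kos if not _KO_RE.match(str(k))]
        if bad:
            raise ValueError(f"module {m} contains invalid KO ids: {bad[:3]}")
    return modules


def select_nominal(
    associations: pd.DataFrame, alpha: float = 0.05, sign_filter: str = "any"
) -> set[str]:
    """KO ids with raw p < alpha in a single association family.

    ``sign_filter`` restricts to positively or negatively associated
    features (``positive`` / ``negative``); ``any`` pools both. The
    input must come from one (assay, timepoint, outcome) family.
    """
    keys = associations[["assay", "timepoint", "outcome"]].drop_duplicates()
    if len(keys) > 1:
        raise ValueError(
            "associations span multiple (assay, timepoint, outcome) families; "
            "filter to one family before nominal selection"
        )
    sel = associations[associations["raw_p"] < alpha]
    if sign_filter == "positive":
        sel = sel[sel["direction"] > 0]
    elif sign_filter == "negative":
        sel = sel[sel["direction"] < 0]
    elif sign_filter != "any":
        raise ValueError("sign_filter must be one of any/positive/negative")
    return set(sel["feature_id"])


def module_enrichment(
    significant_kos: set[str],
    detected_kos: set[str],
    modules: dict[str, set[str]],
    min_module_size: int = MIN_MODULE_SIZE,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric tail) module over-representation.

    For each module, with N detected KOs in total, n of them significant,
    K detected KOs in the module and k of those significant, the p-value
    is ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``. Modules with
    ``K < min_module_size`` are removed before testing, and BH runs
    across the modules actually tested. Results are sorted by adjusted
    p (ties by module id).

    ``gene_ratio`` is k/n, the fraction of significant KOs falling in
    the module (0 when n = 0); ``k_over_K`` is the module coverage.
    """
    significant_kos, detected_kos = set(significant_kos), set(detected_kos)
    stray = significant_kos - detected_kos
    if stray:
        raise ValueError(
            f"significant KOs not in the detected universe: {sorted(stray)[:5]} "
            "(family mix-up upstream?)"
        )
    N = len(detected_kos)
    n = len(significant_kos)
    rows = []
    for module_id in sorted(modules):
        in_module = modules[module_id] & detected_kos
        K = len(in_module)
        if K < min_module_size:
            continue
        k = len(in_module & significant_kos)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(module_id=module_id, k=k, K=K, n=n, N=N, p=p,
                         gene_ratio=(k / n) if n else 0.0,
                         k_over_K=k / K))
    result = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "adjusted_p"])
    if result.empty:
        result["adjusted_p"] = []
        return result[ENRICHMENT_COLUMNS]
    result["adjusted_p"] = bh_adjust(result["p"])
    return (
        result[ENRICHMENT_COLUMNS]
        .sort_values(["adjusted_p", "module_id"], kind="mergesort")
        .reset_index(drop=True)
    )
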