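"""Community metrics: rarefaction, alpha diversity, Bray-Curtis
dissimilarity, and gene-to-KO count aggregation.

Feature tables are :class:`pandas.DataFrame` objects with sample ids on
the index and feature ids on the columns, holding non-negative integer
counts. Rarefaction subsamples each sample without replacement
(multivariate hypergeometric) to a common depth so diversity is
comparable across sequencing efforts; samples below the depth are
dropped.

Shannon diversity is computed in bits (log base 2) and Pielou evenness
as H / log2(richness); both via scikit-bio. The base is configurable —
evenness is base-invariant either way.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis_pair  # noqa: F401 (oracle use)
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import pielou_e, shannon

logger = logging.getLogger(__name__)

#: Default rarefaction depths by assay; synthetic desk-scale runs
#: override these downward.
DEFAULT_DEPTHS = {"nasal_otu": 10_000, "stool_genus": 10_000, "stool_ko": 2_500_000}


def _check_counts(table: pd.DataFrame) -> np.ndarray:
    arr = table.to_numpy()
    if (arr < 0).any():
        raise ValueError("feature counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("feature counts must be integers")
    return arr.astype(np.int64)


def rarefy(
    table: pd.DataFrame, depth: int, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without
    replacement.

    Samples with fewer than ``depth`` total reads are dropped and their
    ids returned. Deterministic for a fixed seed.

    Returns ``(rarefied_table, dropped_sample_ids)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    arr = _check_counts(table)
    rng = np.random.default_rng(seed)
    totals = arr.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.index[~keep])
    if dropped:
        logger.info("rarefy: dropped %d/%d samples below depth %d",
                    len(dropped), len(table), depth)
    rows = []
    for counts, total in zip(arr[keep], totals[keep]):
        if total == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(-1, arr.shape[1]),
        index=table.index[keep], columns=table.columns,
    )
    if out.empty:
        logger.warning("rarefy: no samples at depth %d", depth)
    return out, dropped


def alpha_diversity(table: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Richness, Shannon diversity and Pielou evenness per sample.

    richness = number of features with count > 0; Shannon
    H = -sum p_i log_base p_i over the non-zero proportions; evenness
    = H / log_base(richness), undefined (NaN) for single-feature
    samples.
    """
    arr = _check_counts(table)
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample: rarefy before computing diversity")
    rows = []
    for sample_id, counts in zip(table.index, arr):
        richness = int((counts > 0).sum())
        h = float(shannon(counts, base=base))
        evenness = float(pielou_e(counts)) if richness > 1 else np.nan
        rows.append(dict(sample_id=sample_id, richness=richness,
                         shannon=h, evenness=evenness))
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix.

    ``BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y)``; zero
    diagonal, symmetric, values in [0, 1] for non-negative tables.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    arr = _check_counts(table)
    dm = beta_diversity("braycurtis", arr, ids=[str(i) for i in table.index])
    return pd.DataFrame(dm.data, index=table.index, columns=table.index)


def genes_to_kos(
    gene_counts: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Aggregate gene-level counts to KEGG Orthology (KO) groups.

    A gene mapped to m KO groups contributes count/m to each (equal
    splitting), so total mapped mass is conserved. Genes absent from the
    mapping (or mapped to zero KOs) are dropped and tallied.

    Parameters
    ----------
    gene_counts
        samples x genes count table.
    mapping
        Two-column table ``gene_id, ko_id`` (many-to-many).

    Returns
    -------
    (ko_counts, info)
        ``ko_counts`` is samples x KOs with real-valued (fractional)
        counts; ``info`` reports ``n_unmapped_genes`` and
        ``unmapped_mass``.
    """
    for col in ("gene_id", "ko_id"):
        if col not in mapping.columns:
            raise ValueError(f"mapping needs column {col!r}")
    mapping = mapping.drop_duplicates()
    genes = list(gene_counts.columns)
    kos = sorted(mapping["ko_id"].unique())
    ko_index = {k: j for j, k in enumerate(kos)}
    m_per_gene = mapping.groupby("gene_id")["ko_id"].apply(list).to_dict()

    weight = np.zeros((len(genes), len(kos)))
    unmapped = []
    for i, g in enumerate(genes):
        targets = m_per_gene.get(g, [])
        if not targets:
            unmapped.append(g)
            continue
        w = 1.0 / len(targets)
        for k in targets:
            weight[i, ko_index[k]] += w
    ko_counts = pd.DataFrame(
        gene_counts.to_numpy(dtype=float) @ weight,
        index=gene_counts.index, columns=kos,
    )
    info = {
        "n_unmapped_genes": len(unmapped),
        "unmapped_mass": float(gene_counts[unmapped].to_numpy().sum()) if unmapped else 0.0,
    }
    if unmapped:
        logger.info("genes_to_kos: %d unmapped genes carrying %.0f counts dropped",
                    info["n_unmapped_genes"], info["unmapped_mass"])
    return ko_counts, info
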