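"""Gene-level screen statistics: phenotype collapse, hit calling, binning.

Each gene's guide enrichments are compared to the distribution of
non-targeting control guides with a two-sided Mann-Whitney U test (exact
for small tie-free samples, tie-corrected normal approximation with
continuity correction otherwise).  The gene phenotype score is the mean of
the three guides with the largest absolute enrichment (the most extreme
guides carry the signal under a five-guides-per-TSS design where not every
guide knocks down well).  Hits are genes with raw p below a strict
threshold (default 0.005, no multiple-testing correction; a
Benjamini-Hochberg column is emitted for information only).

For cross-screen comparison, essential genes (phenotype score < 0) are
unity normalized, Z = (score - min) / (max - min) over the negative-score
subset, and binned into five Z intervals; designated genes with positive
scores can be carried into bin 5 by an override set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

__all__ = [
    "gene_mannwhitney",
    "collapse_gene_score",
    "score_genes",
    "call_hits",
    "unity_normalize_bin",
]

#: Columns of the gene-phenotype table produced by :func:`score_genes`.
GENE_PHENOTYPE_COLUMNS = [
    "gene", "phenotype_score", "p_value", "n_guides_used",
    "flagged_few_guides", "is_hit", "direction",
]

# exact-enumeration limits for the U test (larger samples use the
# tie-corrected normal approximation with continuity correction)
_EXACT_MAX_N = 8
_EXACT_MAX_M = 12


def gene_mannwhitney(
    gene_guide_enrichments: Sequence[float],
    control_enrichments: Sequence[float],
) -> float:
    """Two-sided Mann-Whitney p for one gene's guides vs the control null.

    Uses the exact U distribution when the gene has <= 8 guides, there are
    <= 12 controls and no ties; otherwise the tie-corrected normal
    approximation with continuity correction.  Fewer than 2 usable guides
    returns NaN (the gene is reported but excluded from hit calling);
    empty controls are an error.
    """
    x = np.asarray(gene_guide_enrichments, dtype=float)
    y = np.asarray(control_enrichments, dtype=float)
    if y.size == 0:
        raise ValidationError("empty control-guide distribution")
    if x.size < 2:
        return float("nan")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_M and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def collapse_gene_score(
    gene_guide_enrichments: Sequence[float], k: int = 3
) -> float:
    """Gene phenotype score: mean of the k most extreme guide enrichments.

    "Most extreme" is by absolute enrichment; the signed values are
    averaged.  With fewer than k guides all are used (callers flag this).
    An empty list is an error.
    """
    x = np.asarray(gene_guide_enrichments, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot collapse an empty guide set")
    if k < 1:
        raise ValidationError("k must be >= 1")
    order = np.argsort(-np.abs(x), kind="stable")
    return float(x[order[:k]].mean())


def score_genes(
    guide_table: pd.DataFrame,
    k: int = 3,
    alpha: float = 0.005,
    min_guides: int = 2,
) -> pd.DataFrame:
    """Collapse a guide-phenotype table into gene-level scores and p-values.

    ``guide_table`` is the output of ``guide_quant.guide_enrichment`` (or
    ``average_replicates``).  Only guides with ``passes_qc`` contribute;
    control guides (``is_control``) form the null distribution.  Genes with
    fewer than ``min_guides`` usable guides get p = NaN and are never hits.

    Returns a gene table with columns ``GENE_PHENOTYPE_COLUMNS`` plus
    ``p_bh`` (Benjamini-Hochberg adjusted p, informational only), sorted
    by p then |score| descending.
    """
    usable = guide_table[guide_table["passes_qc"]]
    controls = usable.loc[usable["is_control"], "log2_enrichment"].to_numpy()
    if controls.size == 0:
        raise ValidationError(
            "no usable control guides: a statistical run requires at least "
            "one control entry"
        )
    records = []
    for gene, grp in usable[~usable["is_control"]].groupby("gene", sort=True):
        values = grp["log2_enrichment"].to_numpy()
        score = collapse_gene_score(values, k=k)
        p = gene_mannwhitney(values, controls) if values.size >= min_guides else float("nan")
        records.append(
            {
                "gene": gene,
                "phenotype_score": score,
                "p_value": p,
                "n_guides_used": int(values.size),
                "flagged_few_guides": values.size < k,
            }
        )
    genes = pd.DataFrame.from_records(records)
    if genes.empty:
        genes = pd.DataFrame(columns=GENE_PHENOTYPE_COLUMNS + ["p_bh"])
        return genes
    genes["p_bh"] = _benjamini_hochberg(genes["p_value"].to_numpy())
    return call_hits(genes, alpha=alpha)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values; NaNs propagate."""
    out = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size:
        adjusted = stats.false_discovery_control(pv, method="bh")
        out[mask] = adjusted
    return out


def call_hits(genes: pd.DataFrame, alpha: float = 0.005) -> pd.DataFrame:
    """Mark hits (p strictly below alpha) and direction, and sort.

    Direction is read from the score's sign: negative (guides depleted in
    the sorted HDR population) means the gene is required for HDR;
    positive means it represses HDR.  Output is sorted by p-value then by
    |score| descending; genes with NaN p sort last and are never hits.
    """
    out = genes.copy()
    p = out["p_value"].to_numpy(dtype=float)
    out["is_hit"] = (p < alpha) & ~np.isnan(p)
    out["direction"] = np.where(
        out["phenotype_score"].to_numpy() < 0, "required", "repressor"
    )
    out["_abs_score"] = out["phenotype_score"].abs()
    out = out.sort_values(
        ["p_value", "_abs_score"],
        ascending=[True, False],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_abs_score")
    return out.reset_index(drop=True)


_BIN_EDGES = (0.2, 0.4, 0.6, 0.8)


def _bin_for_z(z: float) -> int:
    """Bins 1..5 over half-open intervals [0,.2), [.2,.4), [.4,.6), [.6,.8), [.8,1]."""
    for b, edge in enumerate(_BIN_EDGES, start=1):
        if z < edge:
            return b
    return 5


def unity_normalize_bin(
    scores: Mapping[str, float],
    fa_positive_overrides: Iterable[str] = (),
) -> pd.DataFrame:
    """Unity-normalize essential-gene scores for cross-screen comparison.

    Only genes with phenotype score < 0 (essential for the repair outcome)
    enter the normalization: Z = (score - min) / (max - min) over that
    subset, so Z = 0 is the strongest and Z = 1 the weakest essential
    phenotype.  Z is binned 1-5 by the half-open intervals above.  Genes in
    ``fa_positive_overrides`` whose score is positive are carried with
    bin 5 and undefined Z (NaN); other positive-score genes are omitted.

    Requires at least two distinct negative scores.
    """
    overrides = set(fa_positive_overrides)
    neg = {g: s for g, s in scores.items() if s < 0}
    distinct = set(neg.values())
    if len(distinct) < 2:
        raise ValidationError(
            "unity normalization needs >= 2 distinct negative phenotype scores"
        )
    lo = min(neg.values())
    hi = max(neg.values())
    records = []
    for gene, s in scores.items():
        if s < 0:
            z = (s - lo) / (hi - lo)
            records.append(
                {"gene": gene, "phenotype_score": s, "Z": z, "bin": _bin_for_z(z)}
            )
        elif gene in overrides and s > 0:
            records.append(
                {"gene": gene, "phenotype_score": s, "Z": float("nan"), "bin": 5}
            )
    return pd.DataFrame.from_records(records)
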