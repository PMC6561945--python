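"""Single-sample gene set enrichment (ssGSEA) scoring.

Per sample, genes are ranked by expression (highest expression = highest
rank).  Walking genes from the top rank down, the enrichment score for a
set is the cumulative difference between the weighted in-set empirical
distribution (weights ``rank ** alpha``) and the uniform out-of-set
distribution:

    ES = sum_i [ P_in(i) - P_out(i) ]

so a set concentrated at the top of the ranking scores positive.  Scores
depend on expression only through within-sample ranks, hence are invariant
under any strictly monotone per-sample transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SsgseaError",
    "SsgseaParams",
    "rank_transform",
    "enrichment_score",
    "ssgsea_matrix",
    "zscore_rows",
]

logger = logging.getLogger(__name__)


class SsgseaError(ValueError):
    pass


@dataclass(frozen=True)
class SsgseaParams:
    """Rank-weight exponent and matrix-wide range normalization switch."""

    alpha: float = 0.25
    normalize_global: bool = True
    min_genes: int = 3

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise SsgseaError("alpha must be non-negative")
        if self.min_genes < 1:
            raise SsgseaError("min_genes must be >= 1")


def rank_transform(expr: ExpressionMatrix) -> pd.DataFrame:
    """Within-sample integer ranks, 1..n_genes, highest expression = highest rank.

    Ties are broken by first-occurrence gene order: of two tied genes the one
    appearing first in the matrix receives the higher rank (stable ordering).
    """
    values = expr.data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise SsgseaError("rank transform requires finite expression values")
    n = values.shape[0]
    ranks = np.empty_like(values, dtype=int)
    idx = np.arange(n)
    for j in range(values.shape[1]):
        # stable sort on (-value, original position): first occurrence wins ties
        order = np.lexsort((idx, -values[:, j]))
        col = np.empty(n, dtype=int)
        col[order] = n - idx  # top of ordering -> rank n
        ranks[:, j] = col
    return pd.DataFrame(ranks, index=expr.data.index, columns=expr.data.columns)


def enrichment_score(
    sample_ranks: pd.Series, gene_set, params: SsgseaParams = SsgseaParams()
) -> float:
    """Raw ssGSEA enrichment score of one gene set in one sample.

    ``sample_ranks`` maps every panel gene to its within-sample rank (a
    permutation of 1..n).  Set members absent from the ranking are dropped
    with a warning; a set covering the entire panel has an empty complement
    and is rejected.
    """
    members = [g for g in gene_set if g in sample_ranks.index]
    dropped = len(tuple(gene_set)) - len(members)
    if dropped:
        logger.warning("dropping %d set members absent from the matrix", dropped)
    if not members:
        raise SsgseaError("gene set has no members present in the matrix")
    n = len(sample_ranks)
    if len(members) == n:
        raise SsgseaError("gene set covers the entire panel; complement is empty")

    ranks = sample_ranks.to_numpy(dtype=float)
    in_set = np.zeros(n, dtype=bool)
    in_set[sample_ranks.index.get_indexer(members)] = True

    # walk genes in decreasing rank
    order = np.argsort(-ranks, kind="stable")
    walk_in = in_set[order]
    weights = np.where(walk_in, ranks[order] ** params.alpha, 0.0)
    p_in = np.cumsum(weights)
    total_in = p_in[-1]
    if total_in <= 0:
        raise SsgseaError("degenerate in-set weights (all zero)")
    p_in = p_in / total_in
    p_out = np.cumsum(~walk_in) / float(n - len(members))
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
) -> pd.DataFrame:
    """Enrichment scores for every (set, sample): sets x samples.

    Sets with fewer than ``params.min_genes`` members present in the matrix
    are skipped (with a warning).  When ``normalize_global`` is set, every
    entry is divided by the max - min range of the whole matrix (skipped when
    the range is zero, e.g. a degenerate single-entry matrix).
    """
    ranks = rank_transform(expr)
    kept: dict[str, tuple[str, ...]] = {}
    for name, members in sets.items():
        present = [g for g in members if g in expr.data.index]
        if len(present) < params.min_genes:
            logger.warning(
                "skipping set %r: %d genes present (< %d)",
                name,
                len(present),
                params.min_genes,
            )
            continue
        kept[name] = tuple(present)
    if not kept:
        raise SsgseaError("no gene set passes the min_genes filter")
    scores = pd.DataFrame(
        index=list(kept), columns=expr.data.columns, dtype=float
    )
    for name, members in kept.items():
        for sample in ranks.columns:
            scores.loc[name, sample] = enrichment_score(ranks[sample], members, params)
    if params.normalize_global:
        spread = float(scores.to_numpy().max() - scores.to_numpy().min())
        if spread > 0:
            scores = scores / spread
    return scores


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, population SD 1.

    Constant rows cannot be standardized; they are emitted as zeros with a
    warning rather than NaN so downstream displays stay rectangular.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant rows z-scored to zeros", int(flat.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(
        (values - mean) / sd, index=matrix.index, columns=matrix.columns
    )
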