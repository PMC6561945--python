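"""Immunologic Constant of Rejection (ICR) scoring and consensus classification.

The ICR signature is 20 transcripts in four functional categories —
CXCR3/CCR5 chemokines, Th-1 signaling, effector, and immune-regulatory
genes.  A sample's ICR score is the mean log2 expression of the signature
genes.  Samples are classified ICR High / Medium / Low by consensus
clustering (resampled Ward hierarchical clustering) on the 20 gene values,
cut at k = 3, with clusters ordered by their mean ICR z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .panel_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "IcrError",
    "ICR_CATEGORIES",
    "ICR_GENES",
    "icr_gene_sets",
    "icr_score",
    "ConsensusResult",
    "consensus_cluster",
    "assign_icr_classes",
    "classify_icr",
]

logger = logging.getLogger(__name__)


class IcrError(ValueError):
    pass


#: The four functional categories of the 20-gene ICR signature.
ICR_CATEGORIES: dict[str, tuple[str, ...]] = {
    "CXCR3/CCR5 chemokines": ("CXCL9", "CXCL10", "CCL5"),
    "Th1 signaling": ("IFNG", "IL12B", "TBX21", "CD8A", "STAT1", "IRF1", "CD8B"),
    "Effector": ("GNLY", "PRF1", "GZMA", "GZMB", "GZMH"),
    "Immune regulatory": ("CD274", "CTLA4", "FOXP3", "IDO1", "PDCD1"),
}

#: Flat 20-gene ICR list, category order preserved.
ICR_GENES: tuple[str, ...] = tuple(g for genes in ICR_CATEGORIES.values() for g in genes)

assert len(ICR_GENES) == len(set(ICR_GENES)) == 20


def icr_gene_sets() -> GeneSetCollection:
    """The ICR signature as a gene-set collection (one set per category plus the union)."""
    sets = {name: genes for name, genes in ICR_CATEGORIES.items()}
    sets["ICR"] = ICR_GENES
    return GeneSetCollection(sets)


def icr_score(expr: ExpressionMatrix, genes=ICR_GENES) -> pd.Series:
    """Per-sample ICR score: mean log2 expression over the present signature genes."""
    present = [g for g in genes if g in expr.data.index]
    if not present:
        raise IcrError("no ICR genes present in the expression matrix")
    if len(present) < len(tuple(genes)):
        logger.warning(
            "ICR score uses %d/%d signature genes present in the matrix",
            len(present),
            len(tuple(genes)),
        )
    return expr.data.loc[present].mean(axis=0).rename("icr_score")


@dataclass
class ConsensusResult:
    """Consensus matrices per k, the chosen k, and final cluster assignments."""

    sample_ids: list[str]
    consensus: dict[int, pd.DataFrame]  # k -> samples x samples in [0, 1]
    chosen_k: int
    assignments: pd.Series  # sample -> cluster id 1..k at chosen_k
    labels: pd.Series | None = None  # sample -> ICR class, set by assign_icr_classes
    params: dict = field(default_factory=dict)


def _ward_cut(data: np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage hierarchical clustering of rows, cut into k clusters."""
    z = linkage(data, method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    data: pd.DataFrame,
    maxK: int = 7,
    reps: int = 5000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    chosen_k: int = 3,
) -> ConsensusResult:
    """Resampled Ward-linkage consensus clustering of samples.

    ``data`` is samples x features (for ICR classification: 20 ICR gene log2
    values per sample).  Each replicate subsamples ``floor(fraction * n)``
    samples without replacement, Ward-clusters them on Euclidean distance and
    cuts at k; consensus(i, j) = co-cluster count / co-sampling count.  Final
    assignment Ward-clusters the (1 - consensus) distance at ``chosen_k``.
    """
    n = data.shape[0]
    if n < maxK:
        raise IcrError(f"need at least maxK={maxK} samples, got {n}")
    if reps < 1:
        raise IcrError("reps must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise IcrError("subsample_fraction must be in (0, 1]")
    if not 2 <= chosen_k <= maxK:
        raise IcrError("chosen_k must lie in 2..maxK")
    rng = np.random.default_rng(seed)
    values = data.to_numpy(dtype=float)
    sample_ids = list(data.index)
    m = max(int(np.floor(subsample_fraction * n)), 2)

    ks = list(range(2, maxK + 1))
    together = {k: np.zeros((n, n)) for k in ks}
    sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sampled[np.ix_(idx, idx)] += 1
        sub = values[idx]
        z = linkage(sub, method="ward")
        for k in ks:
            labels = fcluster(z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            together[k][np.ix_(idx, idx)] += same
    if (sampled == 0).any():
        never = int((np.triu(sampled == 0, 1)).sum())
        raise IcrError(
            f"{never} sample pairs never co-sampled in {reps} replicates; increase reps"
        )
    consensus = {}
    for k in ks:
        mat = together[k] / sampled
        np.fill_diagonal(mat, 1.0)
        mat = (mat + mat.T) / 2.0
        consensus[k] = pd.DataFrame(mat, index=sample_ids, columns=sample_ids)

    dist = 1.0 - consensus[chosen_k].to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    assignments = pd.Series(
        fcluster(z, t=chosen_k, criterion="maxclust"), index=sample_ids, name="cluster"
    )
    return ConsensusResult(
        sample_ids=sample_ids,
        consensus=consensus,
        chosen_k=chosen_k,
        assignments=assignments,
        params={
            "maxK": maxK,
            "reps": reps,
            "subsample_fraction": subsample_fraction,
            "seed": seed,
        },
    )


def assign_icr_classes(result: ConsensusResult, scores: pd.Series) -> pd.Series:
    """Order the three consensus clusters by mean member ICR z-score.

    The top cluster becomes ICR High, the middle Medium, the bottom Low.
    ``scores`` are per-sample ICR scores (z-scored internally, so any affine
    rescaling of the input leaves the ordering unchanged).  Ties in cluster
    means are broken by cluster size, then cluster index (logged).
    """
    if result.chosen_k != 3:
        raise IcrError("ICR High/Medium/Low labels require exactly 3 clusters")
    scores = scores.reindex(result.sample_ids)
    if scores.isna().any():
        raise IcrError("scores missing for some clustered samples")
    sd = scores.std(ddof=0)
    z = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    stats = []
    for cluster in sorted(result.assignments.unique()):
        members = result.assignments.index[result.assignments == cluster]
        stats.append((float(z[members].mean()), len(members), int(cluster)))
    means = [s[0] for s in stats]
    if len(set(means)) < len(means):
        logger.warning("tied cluster mean z-scores; breaking by size then index")
    order = sorted(stats)  # ascending mean, then size, then index
    label_of = {cluster: lab for (_, _, cluster), lab in zip(order, ("Low", "Medium", "High"))}
    labels = result.assignments.map(label_of).rename("icr_class")
    result.labels = labels
    return labels


def classify_icr(
    expr: ExpressionMatrix,
    genes=ICR_GENES,
    maxK: int = 7,
    reps: int = 5000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, ConsensusResult]:
    """Score and classify samples: returns (icr_score, icr_class, consensus result).

    Clustering features are the per-sample log2 values of the signature genes
    present in the matrix (samples x genes).
    """
    present = [g for g in genes if g in expr.data.index]
    if not present:
        raise IcrError("no ICR genes present in the expression matrix")
    scores = icr_score(expr, genes)
    features = expr.data.loc[present].T
    result = consensus_cluster(
        features,
        maxK=maxK,
        reps=reps,
        subsample_fraction=subsample_fraction,
        seed=seed,
        chosen_k=3,
    )
    labels = assign_icr_classes(result, scores)
    return scores, labels, result
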