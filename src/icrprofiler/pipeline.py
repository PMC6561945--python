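"""End-to-end orchestration: normalize -> ssGSEA -> ICR -> DEG -> enrichment -> deconvolution -> PCA.

The full analysis reproduces the study's comparison set by default (paired
post-vs-pre over all patients, unpaired CR-vs-NR at each timepoint with the
PR excluded) and emits a structured, deterministic report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deconvolution import FoldChangeRecord, score_fold_change
from .differential import Comparison, differential_table, select_degs, study_comparisons
from .enrichment import CategoryEnrichment, SignatureChange, category_enrichment, signature_change
from .icr import ICR_GENES, classify_icr
from .normalization import NormalizationReport, normalize_pipeline
from .panel_io import (
    CountMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
)
from .ssgsea import SsgseaParams, ssgsea_matrix, zscore_rows

__all__ = ["AnalysisConfig", "ReportBundle", "run_pca", "run_full_analysis"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def run_pca(expr: ExpressionMatrix, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the leading principal components of the expression.

    Genes are centered (no scaling); coordinates come from the SVD of the
    centered genes x samples matrix.  Components are ordered by explained
    variance; each component's sign is fixed so its largest-magnitude gene
    loading is positive.  Returns (samples x components frame, variance
    fractions).
    """
    data = expr.data
    if data.shape[1] < 2:
        raise PipelineError("PCA needs at least 2 samples")
    centered = data.to_numpy(dtype=float) - data.to_numpy(dtype=float).mean(
        axis=1, keepdims=True
    )
    total_var = float((centered**2).sum())
    if total_var == 0:
        raise PipelineError("constant matrix has zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    coords = np.empty((data.shape[1], k))
    for i in range(k):
        loading = u[:, i]
        sign = 1.0 if loading[np.argmax(np.abs(loading))] >= 0 else -1.0
        coords[:, i] = sign * s[i] * vt[i]
    fractions = (s[:k] ** 2) / total_var
    frame = pd.DataFrame(
        coords, index=data.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, fractions


@dataclass
class AnalysisConfig:
    """Everything one full run needs; hashable for provenance."""

    normalized_input: bool = False  # input already normalized: skip to log2/identity
    log2_input: bool = False  # input already on log2 scale (with normalized_input)
    normalization_order: str = "housekeeping_first"
    background_mode: str = "mean"
    pseudocount: float = 1.0
    ssgsea: SsgseaParams = field(default_factory=SsgseaParams)
    variance_mode: str = "pooled"
    p_cut: float = 0.05
    fdr_cut: float = 0.25
    fc_threshold: float = 1.5
    display_cut: float = 15.0
    consensus_reps: int = 5000
    consensus_maxk: int = 7
    subsample_fraction: float = 0.8
    n_pca_components: int = 3
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {k: (v.__dict__ if isinstance(v, SsgseaParams) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All stage outputs of one full analysis run."""

    expression: ExpressionMatrix
    normalization_report: NormalizationReport | None
    enrichment_scores: pd.DataFrame
    enrichment_z: pd.DataFrame
    icr_scores: pd.Series
    icr_classes: pd.Series
    deg_tables: dict[str, pd.DataFrame]
    deg_lists: dict[str, pd.DataFrame]
    category_enrichment: dict[str, list[CategoryEnrichment]]
    signature_changes: dict[str, list[SignatureChange]]
    fold_change_records: dict[str, list[FoldChangeRecord]]
    pca_coordinates: pd.DataFrame
    pca_variance: np.ndarray
    metadata: dict

    def write(self, directory) -> Path:
        """Write every table as TSV plus a single JSON report."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.expression.data.to_csv(directory / "expression.tsv", sep="\t",
                                    index_label="gene_id")
        self.enrichment_scores.to_csv(directory / "ssgsea.tsv", sep="\t",
                                      index_label="signature")
        self.enrichment_z.to_csv(directory / "ssgsea_z.tsv", sep="\t",
                                 index_label="signature")
        pd.DataFrame({"icr_score": self.icr_scores, "icr_class": self.icr_classes}).to_csv(
            directory / "icr.tsv", sep="\t", index_label="sample_id"
        )
        for name, table in self.deg_tables.items():
            table.to_csv(directory / f"deg_{name}.tsv", sep="\t")
        self.pca_coordinates.to_csv(directory / "pca.tsv", sep="\t",
                                    index_label="sample_id")
        report = {
            "metadata": self.metadata,
            "deg_counts": {k: int(len(v)) for k, v in self.deg_lists.items()},
            "icr_classes": self.icr_classes.to_dict(),
            "pca_variance_fractions": [float(f) for f in self.pca_variance],
            "category_enrichment": {
                k: [e.__dict__ for e in v] for k, v in self.category_enrichment.items()
            },
            "signature_changes": {
                k: [s.__dict__ for s in v] for k, v in self.signature_changes.items()
            },
            "fold_changes": {
                k: [r.__dict__ for r in v] for k, v in self.fold_change_records.items()
            },
        }
        (directory / "report.json").write_text(json.dumps(report, indent=2))
        return directory


def run_full_analysis(
    counts: CountMatrix | ExpressionMatrix,
    samples: SampleTable,
    signatures: GeneSetCollection,
    categories: GeneSetCollection | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    comparisons: list[Comparison] | None = None,
) -> ReportBundle:
    """Run every stage on one dataset and collect the results.

    ``counts`` may be a raw :class:`CountMatrix` (full normalization chain) or
    an already-normalized :class:`ExpressionMatrix` (``config.normalized_input``
    controls whether a log2 transform is still applied).
    """
    panel = None
    norm_report = None
    if isinstance(counts, CountMatrix):
        panel = counts.panel
        expr, norm_report = normalize_pipeline(
            counts,
            order=config.normalization_order,
            background_mode=config.background_mode,
            pseudocount=config.pseudocount,
        )
    else:
        expr = counts
        if not config.log2_input:
            from .normalization import log2_transform

            expr = log2_transform(expr.data, pseudocount=config.pseudocount)
    missing = [s for s in samples.sample_ids if s not in expr.data.columns]
    if missing:
        raise PipelineError(f"annotated samples absent from matrix: {missing}")

    # ssGSEA over the leukocyte signatures plus the ICR set
    all_sets = GeneSetCollection({**signatures, "ICR": ICR_GENES})
    es = ssgsea_matrix(expr, all_sets, config.ssgsea)
    es_z = zscore_rows(es)

    icr_scores, icr_classes, consensus = classify_icr(
        expr,
        maxK=min(config.consensus_maxk, expr.data.shape[1] - 1),
        reps=config.consensus_reps,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed,
    )

    comparisons = comparisons if comparisons is not None else study_comparisons(samples)
    deg_tables: dict[str, pd.DataFrame] = {}
    deg_lists: dict[str, pd.DataFrame] = {}
    cat_enrichment: dict[str, list[CategoryEnrichment]] = {}
    sig_changes: dict[str, list[SignatureChange]] = {}
    fc_records: dict[str, list[FoldChangeRecord]] = {}
    background = list(expr.data.index)
    cat_sets = categories
    if cat_sets is None and panel is not None and panel.categories:
        cat_sets = GeneSetCollection(dict(panel.categories))
    for comp in comparisons:
        try:
            table = differential_table(
                expr, comp, panel=panel, variance_mode=config.variance_mode
            )
        except Exception as exc:  # partial-failure contract: other contrasts still run
            logger.warning("comparison %s failed: %s", comp.name, exc)
            continue
        deg_tables[comp.name] = table
        degs = select_degs(table, p_cut=config.p_cut)
        deg_lists[comp.name] = degs
        if cat_sets:
            cat_enrichment[comp.name] = category_enrichment(
                list(degs.index), cat_sets.restricted_to(background), background
            )
        sig_changes[comp.name] = signature_change(
            expr,
            comp.group_a,
            comp.group_b,
            signatures,
            fc_threshold=config.fc_threshold,
            display_cut=config.display_cut,
        )
        fc_records[comp.name] = score_fold_change(
            es, comp, variance_mode=config.variance_mode, p_cut=config.p_cut
        )

    pca_coords, pca_var = run_pca(expr, config.n_pca_components)
    metadata = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_genes": expr.data.shape[0],
        "n_samples": expr.data.shape[1],
        "comparisons": [c.name for c in comparisons],
        "consensus_params": consensus.params,
    }
    return ReportBundle(
        expression=expr,
        normalization_report=norm_report,
        enrichment_scores=es,
        enrichment_z=es_z,
        icr_scores=icr_scores,
        icr_classes=icr_classes,
        deg_tables=deg_tables,
        deg_lists=deg_lists,
        category_enrichment=cat_enrichment,
        signature_changes=sig_changes,
        fold_change_records=fc_records,
        pca_coordinates=pca_coords,
        pca_variance=pca_var,
        metadata=metadata,
    )
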