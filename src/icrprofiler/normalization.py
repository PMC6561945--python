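"""Count-to-log2 normalization chain for targeted immune-panel data.

The chain mirrors the standard nCounter-style preprocessing: per-sample
housekeeping scaling (geometric-mean ratio), negative-control background
subtraction, quantile normalization across samples, and a log2(x + 1)
transform.  Stage order is configurable; the default runs housekeeping
scaling first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import CountMatrix, ExpressionMatrix, ProbeClass

__all__ = [
    "NormalizationError",
    "NormalizationReport",
    "background_subtract",
    "housekeeping_scale",
    "quantile_normalize",
    "log2_transform",
    "normalize_pipeline",
]

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationReport:
    """Per-sample scale factors, background estimates and clamping diagnostics."""

    housekeeping_factor: dict[str, float] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=dict)
    clamped_cells: dict[str, int] = field(default_factory=dict)

    def n_clamped(self) -> int:
        return sum(self.clamped_cells.values())


def background_subtract(
    counts: CountMatrix,
    report: NormalizationReport | None = None,
    mode: str = "mean",
) -> CountMatrix:
    """Subtract the per-sample negative-control background from every probe.

    Background for sample ``s`` is the mean of its negative-control counts
    (``mode="mean"``) or mean + 2 SD (``mode="mean2sd"``).  Endogenous and
    housekeeping counts are clamped at zero after subtraction; control rows
    are left untouched so the background stays recomputable.
    """
    if mode not in ("mean", "mean2sd", "none"):
        raise NormalizationError(f"unknown background mode {mode!r}")
    if mode == "none":
        return counts.copy()
    negatives = counts.panel.negative_controls
    if not negatives:
        raise NormalizationError("panel has no negative-control probes")
    neg = counts.counts.loc[negatives]
    background = neg.mean(axis=0)
    if mode == "mean2sd":
        background = background + 2.0 * neg.std(axis=0, ddof=1).fillna(0.0)
    out = counts.counts.copy()
    subject = [
        g
        for g, c in zip(counts.panel.gene_ids, counts.panel.probe_class)
        if c in (ProbeClass.ENDOGENOUS, ProbeClass.HOUSEKEEPING)
    ]
    shifted = out.loc[subject].sub(background, axis=1)
    clamped = (shifted < 0).sum(axis=0)
    out.loc[subject] = shifted.clip(lower=0.0)
    if report is not None:
        report.background = {s: float(b) for s, b in background.items()}
        report.clamped_cells = {s: int(c) for s, c in clamped.items()}
    n_clamped = int(clamped.sum())
    if n_clamped:
        logger.warning("background subtraction clamped %d cells at zero", n_clamped)
    return CountMatrix(counts.panel, out)


def housekeeping_scale(
    counts: CountMatrix, report: NormalizationReport | None = None
) -> CountMatrix:
    """Scale each sample by the ratio of reference to sample housekeeping geomean.

    ``f_s = G* / G_s`` with ``G_s`` the geometric mean of housekeeping counts in
    sample ``s`` and ``G*`` the geometric mean of the ``G_s``; the log factors
    therefore sum to zero.
    """
    hk = counts.panel.housekeeping
    if len(hk) < 2:
        raise NormalizationError("need at least two housekeeping probes")
    hk_counts = counts.counts.loc[hk]
    if (hk_counts.to_numpy() <= 0).any():
        bad = hk_counts.columns[(hk_counts <= 0).any(axis=0)].tolist()
        raise NormalizationError(
            f"zero/negative housekeeping counts in samples {bad}; geometric mean undefined"
        )
    log_g = np.log(hk_counts).mean(axis=0)  # log G_s
    factors = np.exp(log_g.mean() - log_g)  # G* / G_s
    out = counts.counts.mul(factors, axis=1)
    if report is not None:
        report.housekeeping_factor = {s: float(f) for s, f in factors.items()}
    return CountMatrix(counts.panel, out)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common per-rank mean distribution.

    Classic quantile normalization: sort each column, average across columns
    at each rank, then map values back through their (average, for ties)
    ranks.  Tied values within a column receive the mean of the quantile
    values their tied ranks span.
    """
    if matrix.size == 0:
        raise NormalizationError("empty matrix")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise NormalizationError("quantile normalization requires finite values")
    target = np.sort(values, axis=0).mean(axis=1)  # per-rank mean
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups share the mean of the target values their ranks span
        start = 0
        while start < n:
            stop = start
            while stop + 1 < n and sorted_col[stop + 1] == sorted_col[start]:
                stop += 1
            out[order[start : stop + 1], j] = target[start : stop + 1].mean()
            start = stop + 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply ``log2(x + pseudocount)``; monotone, defined for all x >= 0."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise NormalizationError("log2 transform requires non-negative values")
    if pseudocount < 0:
        raise NormalizationError("pseudocount must be non-negative")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(values + pseudocount), index=matrix.index, columns=matrix.columns
        )
    )


def normalize_pipeline(
    counts: CountMatrix,
    order: str = "housekeeping_first",
    background_mode: str = "mean",
    pseudocount: float = 1.0,
    quantile: bool = True,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Run the full chain and return endogenous-gene log2 expression.

    Stages: housekeeping scaling and background subtraction (order set by
    ``order``: ``housekeeping_first`` default, or ``background_first``), then
    quantile normalization over endogenous genes, then log2.
    """
    if order not in ("housekeeping_first", "background_first"):
        raise NormalizationError(f"unknown stage order {order!r}")
    report = NormalizationReport()
    if order == "housekeeping_first":
        staged = background_subtract(
            housekeeping_scale(counts, report), report, mode=background_mode
        )
    else:
        staged = housekeeping_scale(
            background_subtract(counts, report, mode=background_mode), report
        )
    endo = staged.counts.loc[counts.panel.endogenous]
    if quantile:
        endo = quantile_normalize(endo)
    return log2_transform(endo, pseudocount=pseudocount), report
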