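"""Group comparisons of ssGSEA enrichment scores (forest-plot statistics).

For each leukocyte signature the fold change between two groups of samples
is expressed on the natural-exponential scale of the enrichment scores:

    FC_e = exp(mean ES group A) / exp(mean ES group B) = exp(mean_A - mean_B)

with a 95% t-based confidence interval of the mean difference, exponentiated,
and a paired or unpaired two-tailed t-test p-value matching the design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import Comparison, DifferentialError

__all__ = ["FoldChangeRecord", "score_fold_change"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldChangeRecord:
    signature: str
    fold_change: float  # exp-scale ratio of mean enrichment scores
    ci_low: float
    ci_high: float
    mean_diff: float  # raw mean ES difference (A - B)
    diff_ci_low: float
    diff_ci_high: float
    p_value: float
    design: str
    significant: bool
    degenerate: bool = False


def _paired_stats(a: np.ndarray, b: np.ndarray, level: float):
    d = a - b
    n = len(d)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        return mean, (mean, mean), 1.0, True
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return mean, (mean - tcrit * se, mean + tcrit * se), float(p), False


def _unpaired_stats(a: np.ndarray, b: np.ndarray, level: float, variance_mode: str):
    mean = a.mean() - b.mean()
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variance_mode == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:  # welch
        se2a, se2b = va / na, vb / nb
        se = math.sqrt(se2a + se2b)
        df = (
            (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
            if se > 0
            else 1.0
        )
    if se == 0:
        return mean, (mean, mean), 1.0, True
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return mean, (mean - tcrit * se, mean + tcrit * se), float(p), False


def score_fold_change(
    es: pd.DataFrame,
    comparison: Comparison,
    ci_level: float = 0.95,
    variance_mode: str = "pooled",
    p_cut: float = 0.05,
) -> list[FoldChangeRecord]:
    """Per-signature exp-scale fold change, CI and t-test p for one contrast.

    ``es`` is signatures x samples (the ssGSEA matrix).  Paired designs test
    per-patient score differences; unpaired designs use a two-sample t with
    the selected variance mode.  Degenerate (zero-variance) signatures are
    flagged with p = 1 and a collapsed CI rather than dropped.
    """
    a_ids, b_ids = list(comparison.group_a), list(comparison.group_b)
    missing = [s for s in a_ids + b_ids if s not in es.columns]
    if missing:
        raise DifferentialError(f"samples absent from enrichment matrix: {missing}")
    if comparison.design == "paired" and len(a_ids) < 2:
        raise DifferentialError("paired design needs >= 2 pairs")
    if comparison.design == "unpaired" and (len(a_ids) < 2 or len(b_ids) < 2):
        raise DifferentialError("unpaired design needs >= 2 samples per group")
    out = []
    for sig in es.index:
        a = es.loc[sig, a_ids].to_numpy(dtype=float)
        b = es.loc[sig, b_ids].to_numpy(dtype=float)
        if comparison.design == "paired":
            mean, (lo, hi), p, degen = _paired_stats(a, b, ci_level)
        else:
            mean, (lo, hi), p, degen = _unpaired_stats(a, b, ci_level, variance_mode)
        if degen:
            logger.warning("signature %r has zero-variance contrast; flagged", sig)
        out.append(
            FoldChangeRecord(
                signature=str(sig),
                fold_change=math.exp(mean),
                ci_low=math.exp(lo),
                ci_high=math.exp(hi),
                mean_diff=mean,
                diff_ci_low=lo,
                diff_ci_high=hi,
                p_value=p,
                design=comparison.design,
                significant=bool(p < p_cut and not degen),
                degenerate=degen,
            )
        )
    return out
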