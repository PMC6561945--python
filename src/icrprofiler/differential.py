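"""Paired and unpaired differential expression on log2 expression.

Comparisons follow the study design: paired post-vs-pre t-tests over all
patients with complete biopsy pairs (CR, PR and NR alike), and unpaired
t-tests between complete responders (CR) and non-responders (NR) at a fixed
timepoint, with the partial responder excluded.  Fold change is the anti-log2
of the difference of mean log2 values.  The unpaired default is the pooled
(Student) variance; Welch is available by flag.

Benjamini–Hochberg adjustment is step-up with an explicit universe size m:
q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  m defaults to the number of
non-degenerate genes actually tested in the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import ExpressionMatrix, GenePanel, SampleTable

__all__ = [
    "DifferentialError",
    "Comparison",
    "paired_ttest",
    "unpaired_ttest",
    "fold_change",
    "bh_adjust",
    "differential_table",
    "select_degs",
    "study_comparisons",
]

logger = logging.getLogger(__name__)


class DifferentialError(ValueError):
    pass


@dataclass(frozen=True)
class Comparison:
    """A named two-group contrast resolved to concrete sample ids.

    For ``paired`` designs, ``group_a``/``group_b`` are aligned post/pre
    sample lists (element i of each belongs to the same patient).
    """

    name: str
    design: str  # "paired" | "unpaired"
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.design not in ("paired", "unpaired"):
            raise DifferentialError(f"unknown design {self.design!r}")
        if self.design == "paired" and len(self.group_a) != len(self.group_b):
            raise DifferentialError("paired design requires aligned groups")
        if set(self.group_a) & set(self.group_b):
            raise DifferentialError("groups overlap")
        if not self.group_a or not self.group_b:
            raise DifferentialError("empty group")


def study_comparisons(samples: SampleTable) -> list[Comparison]:
    """The study's three contrasts resolved against a sample table.

    post-vs-pre paired over all complete pairs (PR included); CR vs NR
    unpaired at pre and at post (PR excluded).  Contrasts that cannot be
    formed (e.g. no CR samples) are dropped with a warning.
    """
    out = []
    pairs = samples.pairs()
    if len(pairs) >= 2:
        pre, post = zip(*pairs)
        out.append(Comparison("post_vs_pre", "paired", tuple(post), tuple(pre)))
    else:
        logger.warning("fewer than 2 complete pairs; skipping paired contrast")
    for tp in ("pre", "post"):
        cr = tuple(samples.samples_where(timepoint=tp, response="CR"))
        nr = tuple(samples.samples_where(timepoint=tp, response="NR"))
        if len(cr) >= 2 and len(nr) >= 2:
            out.append(Comparison(f"CR_vs_NR_{tp}", "unpaired", cr, nr))
        else:
            logger.warning("skipping CR_vs_NR_%s: group too small (CR=%d, NR=%d)",
                           tp, len(cr), len(nr))
    return out


def _degenerate(p: np.ndarray, t: np.ndarray, flag: np.ndarray):
    p = np.where(flag, 1.0, p)
    t = np.where(flag, 0.0, t)
    return p, t


def paired_ttest(expr: ExpressionMatrix, pairs) -> pd.DataFrame:
    """Classical paired t-test per gene on (post - pre) log2 differences.

    ``pairs`` is a sequence of (pre, post) sample-id pairs.  Genes whose
    per-patient differences have zero variance are flagged degenerate and get
    p = 1 (kept, so result tables stay rectangular).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise DifferentialError("paired t-test needs at least 2 complete pairs")
    pre_ids = [p for p, _ in pairs]
    post_ids = [q for _, q in pairs]
    missing = [s for s in pre_ids + post_ids if s not in expr.data.columns]
    if missing:
        raise DifferentialError(f"samples absent from matrix: {missing}")
    diffs = expr.data[post_ids].to_numpy() - expr.data[pre_ids].to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    flag = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p, t = _degenerate(p, t, flag)
    if flag.any():
        logger.warning("%d genes with zero-variance differences set to p=1", flag.sum())
    return pd.DataFrame(
        {"t": t, "df": float(df), "p_value": p, "degenerate": flag},
        index=expr.data.index,
    )


def unpaired_ttest(
    expr: ExpressionMatrix, group_a, group_b, variance_mode: str = "pooled"
) -> pd.DataFrame:
    """Two-sample t-test per gene (group_a vs group_b), pooled or Welch variance."""
    if variance_mode not in ("pooled", "welch"):
        raise DifferentialError(f"unknown variance mode {variance_mode!r}")
    a = expr.data[list(group_a)].to_numpy()
    b = expr.data[list(group_b)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DifferentialError("each group needs at least 2 samples")
    import warnings

    with warnings.catch_warnings():
        # zero-variance genes raise a precision warning; they are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=(variance_mode == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    flag = ~np.isfinite(t)
    p, t = _degenerate(p, t, flag)
    df = np.where(np.isfinite(df), df, 0.0)
    if flag.any():
        logger.warning("%d genes with degenerate two-sample t set to p=1", flag.sum())
    return pd.DataFrame(
        {"t": t, "df": df, "p_value": p, "degenerate": flag}, index=expr.data.index
    )


def fold_change(expr: ExpressionMatrix, group_a, group_b) -> pd.Series:
    """Per-gene fold change: 2 ** (mean log2 in a - mean log2 in b)."""
    if not list(group_a) or not list(group_b):
        raise DifferentialError("fold change needs non-empty groups")
    delta = expr.data[list(group_a)].mean(axis=1) - expr.data[list(group_b)].mean(axis=1)
    return np.power(2.0, delta).rename("fold_change")


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with universe size m >= len(p)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DifferentialError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DifferentialError("p-values must lie in [0, 1]")
    k = len(p)
    if k == 0:
        return np.array([])
    if m is None:
        m = k
    if m < k:
        raise DifferentialError(f"universe m={m} smaller than number of tests {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_table(
    expr: ExpressionMatrix,
    comparison: Comparison,
    panel: GenePanel | None = None,
    variance_mode: str = "pooled",
    bh_universe: int | None = None,
) -> pd.DataFrame:
    """Per-gene p, BH q, fold change and annotation for one comparison.

    The BH universe defaults to the number of non-degenerate genes tested;
    degenerate genes keep q = 1.  Fold change is group_a over group_b
    (post/pre or CR/NR in the study contrasts).
    """
    if comparison.design == "paired":
        pairs = list(zip(comparison.group_b, comparison.group_a))  # (pre, post)
        tested = paired_ttest(expr, pairs)
    else:
        tested = unpaired_ttest(
            expr, comparison.group_a, comparison.group_b, variance_mode
        )
    fc = fold_change(expr, comparison.group_a, comparison.group_b)
    ok = ~tested["degenerate"]
    q = pd.Series(1.0, index=tested.index)
    if ok.any():
        q[ok] = bh_adjust(tested.loc[ok, "p_value"].to_numpy(), m=bh_universe)
    table = pd.DataFrame(
        {
            "gene": tested.index,
            "p_value": tested["p_value"],
            "q_value": q,
            "fold_change": fc,
            "direction": np.where(fc >= 1.0, "up", "down"),
            "degenerate": tested["degenerate"],
        }
    ).set_index("gene")
    table["annotation"] = (
        [panel.annotation_string(g) for g in table.index] if panel is not None else ""
    )
    table.attrs["comparison"] = comparison.name
    return table


def select_degs(
    results: pd.DataFrame, p_cut: float = 0.05, fdr_cut: float | None = None
) -> pd.DataFrame:
    """Significant genes at p < p_cut, ordered by fold change descending.

    With ``fdr_cut`` set, filters additionally on q <= fdr_cut (the study's
    secondary 0.25-FDR list).
    """
    keep = results["p_value"] < p_cut
    if fdr_cut is not None:
        keep &= results["q_value"] <= fdr_cut
    return results[keep].sort_values("fold_change", ascending=False)
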