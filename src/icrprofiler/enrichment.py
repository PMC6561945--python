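"""Annotation-category over-representation and per-signature net fold-change summaries.

Category enrichment is a one-sided hypergeometric (upper-tail) test of the
overlap between a DEG list and each annotation category, over the panel's
endogenous genes as background.  The signature summary counts, per gene set,
genes moving up or down past a fold-change threshold between two sample
groups, with inversely regulated genes canceling:

    net_percent = 100 * (n_up - n_down) / n_genes
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import fold_change
from .panel_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "EnrichmentError",
    "CategoryEnrichment",
    "category_enrichment",
    "SignatureChange",
    "signature_change",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    overlap: int
    category_size: int
    deg_size: int
    background_size: int
    p_value: float


def category_enrichment(
    degs, categories: GeneSetCollection, background
) -> list[CategoryEnrichment]:
    """Hypergeometric upper-tail enrichment of a DEG list in each category.

    P(X >= overlap) with population = background, successes = category
    members (restricted to background), draws = DEG list.  Results sorted by
    ascending p, then category name.
    """
    degs = list(dict.fromkeys(degs))
    background = list(dict.fromkeys(background))
    bg = set(background)
    offenders = [g for g in degs if g not in bg]
    if offenders:
        raise EnrichmentError(f"DEGs absent from background: {offenders}")
    deg_set = set(degs)
    out = []
    for name, members in categories.items():
        members_bg = [g for g in members if g in bg]
        k = len(deg_set.intersection(members_bg))
        # P(X >= k) for X ~ Hypergeom(N=|bg|, K=|category|, n=|degs|)
        p = float(hypergeom.sf(k - 1, len(background), len(members_bg), len(degs)))
        out.append(
            CategoryEnrichment(
                category=name,
                overlap=k,
                category_size=len(members_bg),
                deg_size=len(degs),
                background_size=len(background),
                p_value=min(p, 1.0),
            )
        )
    return sorted(out, key=lambda e: (e.p_value, e.category))


@dataclass(frozen=True)
class SignatureChange:
    signature: str
    n_genes: int
    n_up: int
    n_down: int
    net_percent: float
    displayed: bool  # False when |net_percent| < display cut-off


def signature_change(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    sets: GeneSetCollection,
    fc_threshold: float = 1.5,
    display_cut: float = 15.0,
    strict: bool = False,
) -> list[SignatureChange]:
    """Net percentage of threshold-crossing genes per signature, a vs b.

    A gene counts up when FC >= fc_threshold and down when FC <= 1/fc_threshold
    (strict inequalities with ``strict=True``).  ``display_cut`` only marks
    entries for display masking; net_percent values are always retained.
    """
    if fc_threshold <= 1:
        raise EnrichmentError("fc_threshold must exceed 1")
    fc = fold_change(expr, group_a, group_b)
    out = []
    for name, members in sets.items():
        present = [g for g in members if g in fc.index]
        if not present:
            continue
        values = fc[present].to_numpy()
        if strict:
            n_up = int((values > fc_threshold).sum())
            n_down = int((values < 1.0 / fc_threshold).sum())
        else:
            n_up = int((values >= fc_threshold).sum())
            n_down = int((values <= 1.0 / fc_threshold).sum())
        net = 100.0 * (n_up - n_down) / len(present)
        out.append(
            SignatureChange(
                signature=name,
                n_genes=len(present),
                n_up=n_up,
                n_down=n_down,
                net_percent=net,
                displayed=abs(net) >= display_cut,
            )
        )
    return out
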