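"""Synthetic paired immune-panel count datasets with known injected effects.

Emulates the study design: a small cohort of patients with paired pre/post
treatment biopsies profiled on a 770-gene immune panel (plus housekeeping,
negative- and positive-control probes).  Counts are negative binomial around
lognormal per-gene baselines scaled by a per-sample library factor and by
injected log2 effects:

* ICR genes are shifted up in post-treatment samples of responders
  (CR and PR patients) — the treatment-induced immune activation.
* A designated antigen-presentation gene set is shifted up in responder
  samples at both timepoints — the pre-activated baseline microenvironment.
* One leukocyte signature ("T_cells") is shifted up post-treatment in all
  patients — the treatment-wide T-cell infiltration.

Ground truth (affected genes, per-gene effects, library factors) is returned
alongside the data so recovery is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .icr import ICR_CATEGORIES, ICR_GENES
from .panel_io import (
    CountMatrix,
    GenePanel,
    GeneSetCollection,
    ProbeClass,
    SampleAnnotation,
    SampleTable,
    write_gmt,
    write_sample_annotation,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and noise parameters of the generated cohort.

    Defaults mirror the study: 8 patients (2 CR, 1 PR, 5 NR), paired pre/post
    biopsies, a 770-gene endogenous panel with 40 housekeeping and 8
    negative-control probes.
    """

    n_patients: int = 8
    n_cr: int = 2
    n_pr: int = 1
    n_endogenous: int = 770
    n_housekeeping: int = 40
    n_negative_controls: int = 8
    n_positive_controls: int = 6
    baseline_log_mean_sd: tuple[float, float] = (5.5, 1.5)
    signature_log_mean_sd: tuple[float, float] = (6.2, 0.5)
    nb_dispersion: float = 0.1
    icr_post_effect_log2: float = 2.0
    baseline_responder_effect_log2: float = 1.25
    tcell_post_effect_log2: float = 1.0
    library_size_cv: float = 0.1
    n_signatures: int = 12
    n_antigen_genes: int = 12
    n_categories: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cr + self.n_pr > self.n_patients:
            raise ValueError("responders exceed patient count")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for sd in (self.baseline_log_mean_sd[1], self.signature_log_mean_sd[1]):
            if sd <= 0:
                raise ValueError("baseline log-sd must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be non-negative")
        if self.n_endogenous < len(ICR_GENES) + self.n_antigen_genes:
            raise ValueError("endogenous panel too small for the injected gene sets")

    @property
    def n_responders(self) -> int:
        """Patients with clinical benefit (CR + PR)."""
        return self.n_cr + self.n_pr


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset: what was injected where."""

    affected_genes: dict[str, tuple[str, ...]]
    effect_log2: pd.DataFrame  # genes x samples true log2 shifts
    library_factor: pd.Series  # per-sample scale
    signatures: GeneSetCollection
    categories: GeneSetCollection
    responder_patients: tuple[str, ...] = field(default_factory=tuple)


def _build_panel(config: SyntheticConfig, rng: np.random.Generator) -> tuple[GenePanel, dict]:
    n_other = config.n_endogenous - len(ICR_GENES)
    other = [f"GENE{i:04d}" for i in range(1, n_other + 1)]
    endogenous = list(ICR_GENES) + other
    housekeeping = [f"HK{i:03d}" for i in range(1, config.n_housekeeping + 1)]
    negatives = [f"NEG{i:02d}" for i in range(1, config.n_negative_controls + 1)]
    positives = [f"POS{i:02d}" for i in range(1, config.n_positive_controls + 1)]

    # disjoint leukocyte signatures (5-30 genes) drawn from the non-ICR pool
    pool = list(other)
    rng.shuffle(pool)
    cursor = 0
    signatures: dict[str, tuple[str, ...]] = {}
    names = ["T_cells", "Cytotoxic_cells", "NK_cells", "Macrophages", "B_cells",
             "Dendritic_cells", "Neutrophils", "Tregs", "Th1_cells", "Tcm_cells",
             "Mast_cells", "Eosinophils"]
    for i in range(config.n_signatures):
        size = int(rng.integers(5, 31))
        members = pool[cursor : cursor + size]
        if len(members) < 5:
            break
        cursor += size
        name = names[i] if i < len(names) else f"Signature_{i + 1}"
        signatures[name] = tuple(members)
    antigen = tuple(pool[cursor : cursor + config.n_antigen_genes])
    cursor += config.n_antigen_genes

    # annotation categories: antigen presentation is a real category; the rest
    # partition a random slice of the panel
    categories: dict[str, tuple[str, ...]] = {
        "Antigen processing and presentation": antigen + tuple(ICR_GENES[:4]),
    }
    cat_pool = list(endogenous)
    rng.shuffle(cat_pool)
    per_cat = max(len(cat_pool) // max(config.n_categories - 1, 1), 5)
    for i in range(config.n_categories - 1):
        members = tuple(cat_pool[i * per_cat : (i + 1) * per_cat])
        if members:
            categories[f"Immune response category {i + 1}"] = members

    gene_ids = tuple(endogenous + housekeeping + negatives + positives)
    classes = tuple(
        [ProbeClass.ENDOGENOUS] * len(endogenous)
        + [ProbeClass.HOUSEKEEPING] * len(housekeeping)
        + [ProbeClass.NEGATIVE_CONTROL] * len(negatives)
        + [ProbeClass.POSITIVE_CONTROL] * len(positives)
    )
    panel = GenePanel(gene_ids, classes, categories)
    layout = {
        "endogenous": endogenous,
        "housekeeping": housekeeping,
        "negatives": negatives,
        "positives": positives,
        "signatures": GeneSetCollection(signatures),
        "antigen": antigen,
        "categories": GeneSetCollection(categories),
    }
    return panel, layout


def _annotations(config: SyntheticConfig) -> SampleTable:
    anns = []
    for i in range(config.n_patients):
        pid = f"SP{i + 1}"
        if i < config.n_cr:
            resp = "CR"
        elif i < config.n_cr + config.n_pr:
            resp = "PR"
        else:
            resp = "NR"
        hr = "Neg" if i % 8 == 1 else "Pos"
        her2 = "Pos" if i % 2 == 0 else "Neg"
        for tp in ("pre", "post"):
            anns.append(
                SampleAnnotation(f"{pid}_{tp}", pid, tp, resp, hr, her2)
            )
    return SampleTable(anns)


def generate_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[CountMatrix, SampleTable, SyntheticTruth]:
    """Draw one paired count dataset; identical config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    panel, layout = _build_panel(config, rng)
    samples = _annotations(config)
    sample_ids = samples.sample_ids
    n_samples = len(sample_ids)

    mu, sd = config.baseline_log_mean_sd
    baselines = pd.Series(
        np.exp(rng.normal(mu, sd, size=len(panel.gene_ids))), index=panel.gene_ids
    )
    # injected signature genes are solidly expressed immune transcripts:
    # keeps them clear of the negative-control background floor
    smu, ssd = config.signature_log_mean_sd
    special = list(ICR_GENES) + list(layout["antigen"]) + list(
        layout["signatures"]["T_cells"]
    )
    baselines[special] = np.exp(rng.normal(smu, ssd, size=len(special)))
    hk = layout["housekeeping"]
    baselines[hk] = np.exp(rng.normal(6.5, 0.3, size=len(hk)))
    # negative controls sit an order of magnitude below the endogenous median
    neg_mean = float(baselines[layout["endogenous"]].median()) / 10.0
    baselines[layout["negatives"]] = neg_mean
    baselines[layout["positives"]] = np.geomspace(8, 32768, config.n_positive_controls)

    # per-sample library factor, lognormal with the requested CV, mean 1
    if config.library_size_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.library_size_cv**2)))
        lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_samples))
    else:
        lib = np.ones(n_samples)
    library_factor = pd.Series(lib, index=sample_ids, name="library_factor")

    responders = tuple(
        a.patient_id for a in samples if a.response in ("CR", "PR")
    )
    responder_patients = tuple(dict.fromkeys(responders))
    effect = pd.DataFrame(0.0, index=panel.gene_ids, columns=sample_ids)
    for ann in samples:
        is_responder = ann.patient_id in responder_patients
        if is_responder and ann.timepoint == "post":
            effect.loc[list(ICR_GENES), ann.sample_id] += config.icr_post_effect_log2
        if is_responder:
            effect.loc[list(layout["antigen"]), ann.sample_id] += (
                config.baseline_responder_effect_log2
            )
        if ann.timepoint == "post":
            effect.loc[list(layout["signatures"]["T_cells"]), ann.sample_id] += (
                config.tcell_post_effect_log2
            )

    mean = (
        baselines.to_numpy()[:, None]
        * library_factor.to_numpy()[None, :]
        * np.power(2.0, effect.to_numpy())
    )
    r = 1.0 / config.nb_dispersion  # NB size; var = m + dispersion * m^2
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(float)
    matrix = CountMatrix(
        panel, pd.DataFrame(counts, index=panel.gene_ids, columns=sample_ids)
    )
    truth = SyntheticTruth(
        affected_genes={
            "icr_post": tuple(ICR_GENES),
            "baseline_responder": tuple(layout["antigen"]),
            "tcell_post": tuple(layout["signatures"]["T_cells"]),
        },
        effect_log2=effect,
        library_factor=library_factor,
        signatures=layout["signatures"],
        categories=layout["categories"],
        responder_patients=responder_patients,
    )
    return matrix, samples, truth


def write_fixture_bundle(
    dataset: tuple[CountMatrix, SampleTable, SyntheticTruth], directory
) -> dict[str, Path]:
    """Write counts, panel, annotation and GMT files readable by panel_io."""
    counts, samples, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "panel": directory / "panel.tsv",
        "annotation": directory / "annotation.tsv",
        "icr_gmt": directory / "icr.gmt",
        "signatures_gmt": directory / "signatures.gmt",
        "categories_gmt": directory / "categories.gmt",
    }
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    pd.DataFrame(
        {
            "gene_id": counts.panel.gene_ids,
            "probe_class": [c.value for c in counts.panel.probe_class],
        }
    ).to_csv(paths["panel"], sep="\t", index=False)
    write_sample_annotation(samples, paths["annotation"])
    icr_sets = GeneSetCollection(
        {**{k: v for k, v in ICR_CATEGORIES.items()}, "ICR": ICR_GENES}
    )
    write_gmt(icr_sets, paths["icr_gmt"])
    write_gmt(truth.signatures, paths["signatures_gmt"])
    write_gmt(truth.categories, paths["categories_gmt"])
    return paths


def read_fixture_bundle(directory) -> tuple[CountMatrix, SampleTable, dict[str, GeneSetCollection]]:
    """Reload a fixture bundle written by :func:`write_fixture_bundle`."""
    from .panel_io import read_gmt, read_sample_annotation

    directory = Path(directory)
    panel_frame = pd.read_csv(directory / "panel.tsv", sep="\t", dtype=str)
    classes = dict(zip(panel_frame["gene_id"], panel_frame["probe_class"]))
    counts_frame = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    counts_frame.index.name = None
    categories = read_gmt(directory / "categories.gmt")
    panel = GenePanel(
        tuple(counts_frame.index),
        tuple(ProbeClass(classes[g]) for g in counts_frame.index),
        categories,
    )
    counts = CountMatrix(panel, counts_frame.astype(float))
    samples = read_sample_annotation(directory / "annotation.tsv")
    sets = {
        "icr": read_gmt(directory / "icr.gmt"),
        "signatures": read_gmt(directory / "signatures.gmt"),
        "categories": categories,
    }
    return counts, samples, sets
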