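"""Readers and writers for panel expression tables, GMT gene sets and sample annotations.

All tabular I/O is delimited text: ``.tsv`` means tab, ``.csv`` means comma
(decided by extension, never sniffed).  Gene symbols are matched
case-sensitively by exact string equality; the targeted panel fixes its
symbols, so no alias resolution is attempted.  Expression tables must be
complete — a missing cell is an error, not a NaN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "GenePanel",
    "CountMatrix",
    "ExpressionMatrix",
    "SampleAnnotation",
    "SampleTable",
    "GeneSetCollection",
    "PanelIOError",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_sample_annotation",
    "write_sample_annotation",
    "study_sample_table",
    "STUDY_TABLE1",
]


class PanelIOError(ValueError):
    """Raised for malformed input files or invariant violations."""


class ProbeClass(str, enum.Enum):
    ENDOGENOUS = "endogenous"
    HOUSEKEEPING = "housekeeping"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"


@dataclass(frozen=True)
class GenePanel:
    """The probe content of a targeted panel.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, file order preserved.
    probe_class
        Probe class per gene, aligned with ``gene_ids``.
    categories
        Annotation-category name -> member genes (all must be panel genes).
    """

    gene_ids: tuple[str, ...]
    probe_class: tuple[ProbeClass, ...]
    categories: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            dupes = pd.Index(self.gene_ids)
            raise PanelIOError(
                f"duplicate gene ids in panel: {sorted(dupes[dupes.duplicated()])}"
            )
        if len(self.probe_class) != len(self.gene_ids):
            raise PanelIOError("probe_class length does not match gene_ids")
        if not any(c is ProbeClass.ENDOGENOUS for c in self.probe_class):
            raise PanelIOError("panel must contain at least one endogenous gene")
        known = set(self.gene_ids)
        for name, members in self.categories.items():
            missing = [g for g in members if g not in known]
            if missing:
                raise PanelIOError(
                    f"annotation category {name!r} references non-panel genes: {missing}"
                )

    def genes_of_class(self, probe_class: ProbeClass) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.probe_class) if c is probe_class]

    @property
    def endogenous(self) -> list[str]:
        return self.genes_of_class(ProbeClass.ENDOGENOUS)

    @property
    def housekeeping(self) -> list[str]:
        return self.genes_of_class(ProbeClass.HOUSEKEEPING)

    @property
    def negative_controls(self) -> list[str]:
        return self.genes_of_class(ProbeClass.NEGATIVE_CONTROL)

    def annotation_string(self, gene: str) -> str:
        """Comma-joined annotation categories containing ``gene``."""
        cats = [name for name, members in self.categories.items() if gene in members]
        return ", ".join(sorted(cats))


@dataclass
class CountMatrix:
    """Raw (or partially normalized) probe counts, genes x samples."""

    panel: GenePanel
    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.panel.gene_ids):
            raise PanelIOError("count matrix rows do not match panel gene ids")
        if self.counts.columns.duplicated().any():
            raise PanelIOError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise PanelIOError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.panel, self.counts.copy())


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, genes x samples; the substrate of all statistics."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise PanelIOError("duplicate gene ids in expression matrix")
        if self.data.columns.duplicated().any():
            raise PanelIOError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise PanelIOError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])


_TIMEPOINTS = ("pre", "post")
_RESPONSES = ("CR", "PR", "NR")
_STATUS = ("Pos", "Neg")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample clinical annotation: patient, biopsy timepoint, response class."""

    sample_id: str
    patient_id: str
    timepoint: str  # pre | post
    response: str  # CR | PR | NR
    hr_status: str = "Pos"
    her2_status: str = "Neg"

    def __post_init__(self) -> None:
        if self.timepoint not in _TIMEPOINTS:
            raise PanelIOError(f"unknown timepoint {self.timepoint!r} for {self.sample_id}")
        if self.response not in _RESPONSES:
            raise PanelIOError(f"unknown response {self.response!r} for {self.sample_id}")
        if self.hr_status not in _STATUS:
            raise PanelIOError(f"unknown hr_status {self.hr_status!r} for {self.sample_id}")
        if self.her2_status not in _STATUS:
            raise PanelIOError(f"unknown her2_status {self.her2_status!r} for {self.sample_id}")


class SampleTable:
    """An ordered collection of sample annotations with pairing helpers.

    Enforces the paired-biopsy design invariants: at most one pre and one
    post sample per patient, and a single response label per patient.
    """

    def __init__(self, annotations: Iterable[SampleAnnotation]):
        self.annotations = list(annotations)
        seen: dict[tuple[str, str], str] = {}
        responses: dict[str, str] = {}
        ids = set()
        for ann in self.annotations:
            if ann.sample_id in ids:
                raise PanelIOError(f"duplicate sample id {ann.sample_id!r}")
            ids.add(ann.sample_id)
            key = (ann.patient_id, ann.timepoint)
            if key in seen:
                raise PanelIOError(
                    f"patient {ann.patient_id!r} has two {ann.timepoint!r} samples "
                    f"({seen[key]!r}, {ann.sample_id!r})"
                )
            seen[key] = ann.sample_id
            prev = responses.setdefault(ann.patient_id, ann.response)
            if prev != ann.response:
                raise PanelIOError(
                    f"patient {ann.patient_id!r} has inconsistent responses {prev!r}/{ann.response!r}"
                )

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations]

    def pairs(self) -> list[tuple[str, str]]:
        """Complete (pre, post) sample-id pairs, one per fully sampled patient."""
        by_patient: dict[str, dict[str, str]] = {}
        order: list[str] = []
        for ann in self.annotations:
            if ann.patient_id not in by_patient:
                order.append(ann.patient_id)
            by_patient.setdefault(ann.patient_id, {})[ann.timepoint] = ann.sample_id
        return [
            (tp["pre"], tp["post"])
            for pid in order
            if len(tp := by_patient[pid]) == 2
        ]

    def samples_where(
        self,
        timepoint: str | None = None,
        response: str | Sequence[str] | None = None,
    ) -> list[str]:
        if isinstance(response, str):
            response = (response,)
        out = []
        for ann in self.annotations:
            if timepoint is not None and ann.timepoint != timepoint:
                continue
            if response is not None and ann.response not in response:
                continue
            out.append(ann.sample_id)
        return out

    def summarize(self) -> dict[str, float]:
        """Per-patient cohort summary: counts and receptor-status fractions.

        Fractions are over distinct patients (each patient contributes once
        regardless of how many biopsies it has).
        """
        patients: dict[str, SampleAnnotation] = {}
        for ann in self.annotations:
            patients.setdefault(ann.patient_id, ann)
        n = len(patients)
        if n == 0:
            raise PanelIOError("no patients to summarize")
        anns = list(patients.values())
        frac = lambda pred: 100.0 * sum(pred(a) for a in anns) / n
        return {
            "n_patients": float(n),
            "n_samples": float(len(self.annotations)),
            "n_complete_pairs": float(len(self.pairs())),
            "hr_positive_percent": frac(lambda a: a.hr_status == "Pos"),
            "her2_positive_percent": frac(lambda a: a.her2_status == "Pos"),
            "cr_percent": frac(lambda a: a.response == "CR"),
            "pr_percent": frac(lambda a: a.response == "PR"),
            "nr_percent": frac(lambda a: a.response == "NR"),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": a.sample_id,
                    "patient_id": a.patient_id,
                    "timepoint": a.timepoint,
                    "response": a.response,
                    "hr_status": a.hr_status,
                    "her2_status": a.her2_status,
                }
                for a in self.annotations
            ]
        )


class GeneSetCollection(dict):
    """Named, ordered gene lists. ``dict[str, tuple[str, ...]]`` with invariants."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        cleaned = {}
        for name, members in sets.items():
            members = tuple(members)
            if not members:
                raise PanelIOError(f"gene set {name!r} is empty")
            if len(members) != len(set(members)):
                raise PanelIOError(f"gene set {name!r} has duplicate members")
            cleaned[name] = members
        super().__init__(cleaned)

    def restricted_to(self, genes: Sequence[str]) -> "GeneSetCollection":
        """Drop members absent from ``genes``; drop sets left empty."""
        genes = set(genes)
        kept = {
            name: present
            for name, members in self.items()
            if (present := tuple(g for g in members if g in genes))
        }
        return GeneSetCollection(kept)


# ---------------------------------------------------------------------------
# delimited-table plumbing


def _delimiter_for(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_expression_table(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a delimited numeric expression table with one header row of ids.

    Parameters
    ----------
    path
        ``.tsv`` (tab) or ``.csv`` (comma) file; first column holds row ids.
    orientation
        ``genes_in_rows`` (default) or ``samples_in_rows`` (table is transposed
        after reading so genes always end up in rows).
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise PanelIOError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise PanelIOError(f"duplicate row ids in {path.name}: {dupes}")
    if raw.columns.duplicated().any():
        dupes = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise PanelIOError(f"duplicate column ids in {path.name}: {dupes}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("missing cell")
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise PanelIOError(
                    f"non-numeric or missing cell at row {raw.index[i]!r}, "
                    f"column {col!r} in {path.name}: {cell!r}"
                ) from None
    frame = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    frame.index.name = None
    frame.columns.name = None
    if orientation == "samples_in_rows":
        frame = frame.T
    return ExpressionMatrix(frame)


def write_expression_table(matrix: ExpressionMatrix | pd.DataFrame, path) -> Path:
    path = Path(path)
    frame = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    frame.to_csv(path, sep=_delimiter_for(path), index_label="gene_id")
    return path


def read_counts_table(path, panel_classes: Mapping[str, str] | None = None) -> CountMatrix:
    """Read a counts table plus a probe-class map into a :class:`CountMatrix`.

    ``panel_classes`` maps gene id -> probe class token; genes absent from the
    map default to ``endogenous``.
    """
    expr = read_expression_table(path)
    classes = tuple(
        ProbeClass((panel_classes or {}).get(g, "endogenous")) for g in expr.gene_ids
    )
    panel = GenePanel(tuple(expr.gene_ids), classes)
    return CountMatrix(panel, expr.data)


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, members per tab line."""
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise PanelIOError(f"{path.name}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise PanelIOError(
                f"{path.name}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise PanelIOError(f"{path.name}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = tuple(members)
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
    return path


_ANNOTATION_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "response",
    "hr_status",
    "her2_status",
)


def read_sample_annotation(path) -> SampleTable:
    """Read a sample-annotation table (TSV/CSV) into a :class:`SampleTable`."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelIOError(f"{path.name}: missing annotation columns {missing}")
    return SampleTable(
        SampleAnnotation(**{c: row[c] for c in _ANNOTATION_COLUMNS})
        for _, row in frame.iterrows()
    )


def write_sample_annotation(table: SampleTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_delimiter_for(path), index=False)
    return path


# ---------------------------------------------------------------------------
# The study cohort: 8 patients with paired skin-metastasis biopsies.
# (id, age, HR, HER2, grade, response)
STUDY_TABLE1 = (
    ("1", 50, "Pos", "Pos", "III", "NR"),
    ("2", 44, "Neg", "Neg", "III", "NR"),
    ("3", 49, "Pos", "Pos", "III", "NR"),
    ("4", 57, "Pos", "Neg", "III", "NR"),
    ("5", 50, "Pos", "Pos", "III", "CR"),
    ("6", 49, "Pos", "Neg", "II", "CR"),
    ("7", 57, "Pos", "Pos", "III", "NR"),
    ("8", 71, "Pos", "Neg", "III", "PR"),
)


def study_sample_table() -> SampleTable:
    """The published cohort as a paired pre/post sample table (16 samples)."""
    anns = []
    for pid, _age, hr, her2, _grade, resp in STUDY_TABLE1:
        for tp in ("pre", "post"):
            anns.append(
                SampleAnnotation(
                    sample_id=f"P{pid}_{tp}",
                    patient_id=f"P{pid}",
                    timepoint=tp,
                    response=resp,
                    hr_status=hr,
                    her2_status=her2,
                )
            )
    return SampleTable(anns)
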