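"""Count-matrix container and table I/O for hybridization-counting panels.

The central object is :class:`CountMatrix`: a genes × samples table of
nonnegative counts with a per-gene probe class (endogenous, housekeeping,
positive, negative) and optional pathway label. Plain TSV/CSV readers cover
the matrix, annotation and sample-sheet schemas; a reader for the plain-text
RCC lane dialect (``<CodeSummary>`` sections) assembles per-lane files into
one matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# canonical probe classes
ENDOGENOUS = "endogenous"
HOUSEKEEPING = "housekeeping"
POSITIVE = "positive"
NEGATIVE = "negative"
PROBE_CLASSES = (ENDOGENOUS, HOUSEKEEPING, POSITIVE, NEGATIVE)

# sample-sheet group labels
TUMOR = "tumor"
FALLOPIAN_TUBE = "fallopian_tube"


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its structural invariants."""


@dataclass
class CountMatrix:
    """Genes × samples counts with per-gene probe class and pathway labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns are sample identifiers,
        entries nonnegative (integers for raw counts, reals after
        normalization).
    annotation
        DataFrame indexed by gene with at least a ``probe_class`` column and
        optionally a ``pathway`` column. Every gene of ``values`` must be
        annotated with exactly one probe class.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise CountMatrixError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise CountMatrixError("duplicate sample identifiers")
        if (self.values.to_numpy() < 0).any():
            raise CountMatrixError("negative counts")
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise CountMatrixError(
                f"genes without annotation: {list(missing[:5])}"
            )
        bad = set(self.annotation["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise CountMatrixError(f"unknown probe classes: {sorted(bad)}")
        # keep annotation aligned and restricted to the matrix genes
        self.annotation = self.annotation.loc[self.values.index]

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def probe_class(self) -> pd.Series:
        return self.annotation["probe_class"]

    def genes_of_class(self, probe_class: str) -> pd.Index:
        return self.values.index[self.probe_class == probe_class]

    def class_values(self, probe_class: str) -> pd.DataFrame:
        """Sub-matrix restricted to one probe class (view by label)."""
        return self.values.loc[self.genes_of_class(probe_class)]

    def with_values(self, values: pd.DataFrame) -> "CountMatrix":
        """New matrix with replaced values, annotation carried over."""
        return CountMatrix(values=values, annotation=self.annotation.copy())

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        keep = self.values.index.intersection(pd.Index(genes))
        return CountMatrix(
            values=self.values.loc[keep],
            annotation=self.annotation.loc[keep].copy(),
        )

    def drop_genes(self, genes: Iterable[str]) -> "CountMatrix":
        keep = self.values.index.difference(pd.Index(list(genes)))
        # .difference sorts; preserve original order
        keep = self.values.index[self.values.index.isin(keep)]
        return CountMatrix(
            values=self.values.loc[keep],
            annotation=self.annotation.loc[keep].copy(),
        )


# -- flat-file I/O ---------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes-in-rows count table (first column = gene id)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = "gene"
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (columns gene, probe_class[, pathway])."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return df.set_index("gene")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (columns sample, group[, replicate_of])."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df = df.set_index("sample")
    if "replicate_of" in df.columns:
        df["replicate_of"] = df["replicate_of"].replace({np.nan: ""})
    else:
        df["replicate_of"] = ""
    return df


def read_count_matrix(
    counts_path: str | Path, annotation_path: str | Path
) -> CountMatrix:
    return CountMatrix(
        values=read_counts(counts_path),
        annotation=read_annotation(annotation_path),
    )


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index_label="gene")


# -- RCC-dialect lane files ------------------------------------------------

_RCC_CLASS_MAP = {
    "endogenous": ENDOGENOUS,
    "housekeeping": HOUSEKEEPING,
    "positive": POSITIVE,
    "negative": NEGATIVE,
}


def parse_rcc(text: str) -> tuple[str, pd.Series, pd.DataFrame]:
    """Parse one plain-text RCC lane.

    Returns ``(sample_id, counts, annotation)``. The sample id is taken from
    the ``ID`` attribute of the ``<Sample_Attributes>`` (or ``<Lane_Attributes>``)
    section when present, otherwise ``"lane"``. Only the ``<CodeSummary>``
    section (columns CodeClass, Name, ..., Count) is interpreted.
    """
    sample_id = "lane"
    for section in ("Sample_Attributes", "Lane_Attributes"):
        m = re.search(rf"<{section}>(.*?)</{section}>", text, re.S)
        if m:
            for line in m.group(1).strip().splitlines():
                parts = line.split(",")
                if parts[0].strip() == "ID" and len(parts) > 1 and parts[1].strip():
                    sample_id = parts[1].strip()
                    break
    m = re.search(r"<CodeSummary>(.*?)</CodeSummary>", text, re.S)
    if not m:
        raise CountMatrixError("no <CodeSummary> section in RCC input")
    lines = [ln for ln in m.group(1).strip().splitlines() if ln.strip()]
    header = [h.strip() for h in lines[0].split(",")]
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise CountMatrixError(f"RCC CodeSummary header missing column: {exc}")
    names, classes, counts = [], [], []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(",")]
        cls = _RCC_CLASS_MAP.get(parts[i_class].lower())
        if cls is None:  # SpikeIn / Binding etc. are ignored
            continue
        names.append(parts[i_name])
        classes.append(cls)
        counts.append(float(parts[i_count]))
    ann = pd.DataFrame(
        {"probe_class": classes}, index=pd.Index(names, name="gene")
    )
    return sample_id, pd.Series(counts, index=ann.index, name=sample_id), ann


def assemble_rcc(paths: Sequence[str | Path]) -> CountMatrix:
    """Assemble several RCC lane files (one sample each) into a CountMatrix.

    All lanes must share the same probe panel (same Name/CodeClass rows).
    """
    columns: dict[str, pd.Series] = {}
    annotation: pd.DataFrame | None = None
    for path in paths:
        text = Path(path).read_text()
        sample_id, counts, ann = parse_rcc(text)
        if sample_id in columns:
            sample_id = f"{sample_id}_{Path(path).stem}"
        if annotation is None:
            annotation = ann
        elif not annotation.index.equals(ann.index):
            raise CountMatrixError(
                f"lane {path} has a different probe panel"
            )
        columns[sample_id] = counts
    if annotation is None:
        raise CountMatrixError("no RCC lanes given")
    values = pd.DataFrame(columns)
    values.index.name = "gene"
    if "pathway" not in annotation.columns:
        annotation["pathway"] = ""
    return CountMatrix(values=values, annotation=annotation)
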