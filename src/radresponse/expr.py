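"""Annotated expression-matrix container and readers for panel count data.

The analysis works on a genes × samples matrix from a targeted immune gene
panel.  Each probe carries a *gene class*: ``endogenous`` genes are the
biology, ``housekeeping`` genes anchor content normalization, and the
``positive_control`` / ``negative_control`` spike-ins calibrate lane
efficiency and background.  Samples carry the study metadata (patient,
timepoint, batch, response group).  The matrix moves through a strict state
machine: ``raw`` (nonnegative integer counts) → ``normalized`` (log2 units)
→ ``batch_corrected``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_CLASSES = ("endogenous", "housekeeping", "positive_control", "negative_control")
STATES = ("raw", "normalized", "batch_corrected")

#: mapping from NanoString RCC CodeClass values to our gene classes
_RCC_CLASS_MAP = {
    "endogenous": "endogenous",
    "housekeeping": "housekeeping",
    "positive": "positive_control",
    "negative": "negative_control",
}


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with gene-class and sample metadata.

    Parameters
    ----------
    values : DataFrame
        Genes in rows, samples in columns.  Nonnegative integers in the
        ``raw`` state, real log2 units otherwise.
    gene_classes : Series
        One of :data:`GENE_CLASSES` per gene, indexed like ``values``.
    samples : DataFrame
        Per-sample metadata indexed by sample id (columns such as
        ``patient``, ``timepoint``, ``batch``, ``group`` are free-form).
    state : str
        One of :data:`STATES`.
    norm_factors : DataFrame, optional
        Per-sample normalization provenance (filled by the preprocessor).
    """

    values: pd.DataFrame
    gene_classes: pd.Series
    samples: pd.DataFrame = field(default=None)
    state: str = "raw"
    norm_factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        # axis-label names carry no information here; normalize them so
        # file round-trips compare clean
        self.values.index.name = None
        self.values.columns.name = None
        self.gene_classes.name = None
        if self.values.index.duplicated().any():
            raise ExpressionError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ExpressionError("duplicate sample ids")
        self.gene_classes = self.gene_classes.reindex(self.values.index)
        if self.gene_classes.isna().any():
            missing = self.gene_classes.index[self.gene_classes.isna()][:3]
            raise ExpressionError(f"genes without a gene class, e.g. {list(missing)}")
        bad = set(self.gene_classes.unique()) - set(GENE_CLASSES)
        if bad:
            raise ExpressionError(f"unknown gene classes {sorted(bad)}")
        if not self.values.columns.equals(self.samples.reindex(self.values.columns).index):
            raise ExpressionError("sample metadata does not cover all samples")
        self.samples = self.samples.reindex(self.values.columns)
        if self.state not in STATES:
            raise ExpressionError(f"unknown state {self.state!r}")
        if self.state == "raw":
            arr = self.values.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ExpressionError("raw counts must be nonnegative integers")

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def genes_of_class(self, cls: str) -> pd.Index:
        if cls not in GENE_CLASSES:
            raise ExpressionError(f"unknown gene class {cls!r}")
        return self.genes[self.gene_classes == cls]

    @property
    def endogenous(self) -> pd.Index:
        return self.genes_of_class("endogenous")

    def subset_genes(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = pd.Index(keep)
        return replace(
            self,
            values=self.values.loc[keep],
            gene_classes=self.gene_classes.loc[keep],
        )

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = pd.Index(keep)
        nf = self.norm_factors.loc[keep] if self.norm_factors is not None else None
        return replace(
            self,
            values=self.values[keep],
            samples=self.samples.loc[keep],
            norm_factors=nf,
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_classes=self.gene_classes.copy(),
            samples=self.samples.copy(),
            norm_factors=None if self.norm_factors is None else self.norm_factors.copy(),
        )


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write genes × samples values with a ``gene_class`` column."""
    out = matrix.values.copy()
    out.insert(0, "gene_class", matrix.gene_classes)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_meta_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    meta = matrix.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, meta_path: str | Path | None = None,
                    state: str = "raw") -> ExpressionMatrix:
    """Read a counts TSV written by :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_class" not in df.columns:
        raise ExpressionError(f"{path}: missing required 'gene_class' column")
    classes = df.pop("gene_class")
    df.index.name = None
    classes.name = None
    samples = None
    if meta_path is not None:
        samples = pd.read_csv(meta_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, gene_classes=classes, samples=samples, state=state)


# ---------------------------------------------------------------------------
# RCC (NanoString Reporter Code Count) reader
# ---------------------------------------------------------------------------

def _parse_rcc(path: Path) -> tuple[str, pd.DataFrame]:
    """Parse one RCC file, returning (lane id, CodeSummary table)."""
    text = Path(path).read_text()
    lane_id = Path(path).stem
    m = re.search(r"<Lane[ _]Attributes>(.*?)</Lane[ _]Attributes>", text, re.S)
    if m:
        for line in m.group(1).strip().splitlines():
            parts = line.split(",")
            if parts[0].strip().lower() == "id" and len(parts) > 1 and parts[1].strip():
                lane_id = f"{Path(path).stem}_lane{parts[1].strip()}"
    m = re.search(r"<Code[ _]Summary>(.*?)</Code[ _]Summary>", text, re.S)
    if m is None:
        raise ExpressionError(f"{path}: no <CodeSummary> section")
    lines = [ln for ln in m.group(1).strip().splitlines() if ln.strip()]
    header = [h.strip() for h in lines[0].split(",")]
    required = {"CodeClass", "Name", "Count"}
    if not required.issubset(header):
        raise ExpressionError(f"{path}: CodeSummary header lacks {sorted(required - set(header))}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != len(header):
            raise ExpressionError(f"{path}: malformed CodeSummary line {lineno}: {ln!r}")
        rec = dict(zip(header, parts))
        try:
            rec["Count"] = int(float(rec["Count"]))
        except ValueError as exc:
            raise ExpressionError(f"{path}: non-numeric count on line {lineno}: {ln!r}") from exc
        rows.append(rec)
    return lane_id, pd.DataFrame(rows)


def read_rcc(paths: Sequence[str | Path]) -> ExpressionMatrix:
    """Read one or more RCC files; each lane becomes one sample column.

    CodeClass values are mapped onto the panel gene classes; SpikeIn or
    other unrecognized classes raise.  All files must report the same gene
    universe.
    """
    if not paths:
        raise ExpressionError("no RCC files given")
    columns: dict[str, pd.Series] = {}
    classes: pd.Series | None = None
    for path in paths:
        lane, tab = _parse_rcc(Path(path))
        cls = tab["CodeClass"].str.lower().str.replace(r"\d+$", "", regex=True)
        unknown = set(cls) - set(_RCC_CLASS_MAP)
        if unknown:
            raise ExpressionError(f"{path}: unrecognized CodeClass values {sorted(unknown)}")
        this_classes = pd.Series(
            [_RCC_CLASS_MAP[c] for c in cls], index=tab["Name"].to_numpy()
        )
        if classes is None:
            classes = this_classes
        elif not classes.sort_index().equals(this_classes.sort_index()):
            raise ExpressionError(f"{path}: gene universe differs from previous RCC files")
        columns[lane] = pd.Series(tab["Count"].to_numpy(), index=tab["Name"].to_numpy())
    values = pd.DataFrame({k: v.reindex(classes.index) for k, v in columns.items()})
    return ExpressionMatrix(values=values, gene_classes=classes, state="raw")


def read_counts(path: str | Path | Sequence[str | Path], format: str = "tsv",
                meta_path: str | Path | None = None) -> ExpressionMatrix:
    """Dispatching reader: ``tsv`` matrix file or list/dir of ``rcc`` files."""
    if format == "tsv":
        return read_counts_tsv(path, meta_path=meta_path)
    if format == "rcc":
        p = Path(path) if isinstance(path, (str, Path)) else None
        if p is not None and p.is_dir():
            files = sorted(p.glob("*.RCC")) + sorted(p.glob("*.rcc"))
        elif p is not None:
            files = [p]
        else:
            files = [Path(x) for x in path]
        return read_rcc(files)
    raise ExpressionError(f"unknown format {format!r}")
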