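"""Data model and readers/writers for expression studies.

The central container is :class:`ExpressionDataset`: a log2 expression
matrix (features x samples) carried together with a sample design table
that records, for every array, the experimental group, circadian time
(ZT, hours since lights-on), replicate structure, source study and array
platform.  Every analysis stage consumes and produces this object.

Supported on-disk formats are deliberately plain text: TSV matrices, the
tab-delimited table block of GEO series-matrix files, GMT gene-set
collections, one-id-per-line control lists and a TSV design table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionDataset",
    "ControlGeneSets",
    "GeneSetCollection",
    "DESIGN_COLUMNS",
    "PAPER_GROUPS",
    "load_expression",
    "write_expression",
    "load_design",
    "write_design",
    "load_controls",
    "load_gene_list",
    "load_gmt",
    "write_gmt",
]

#: Required columns of a sample design table.
DESIGN_COLUMNS = ("group", "zt_time", "replicate_group", "study", "platform")

#: Canonical group labels of the sleep-deprivation / recovery-sleep design:
#: undisturbed circadian controls at ZT 0/6/7/8/11, sleep deprivation (SD,
#: sacrificed at ZT6) and recovery sleep for 1, 2, 3 or 6 hours.
PAPER_GROUPS = ("CC0", "CC6", "CC7", "CC8", "CC11", "SD", "RS1", "RS2", "RS3", "RS6")


class ValidationError(ValueError):
    """A dataset, design or control set violates a structural invariant."""


def _check_design_frame(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design table missing required columns: {missing}")
    if design.index.has_duplicates:
        dups = design.index[design.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in design: {dups}")
    zt = pd.to_numeric(design["zt_time"], errors="coerce")
    if zt.isna().any():
        bad = design.index[zt.isna()].tolist()
        raise ValidationError(f"non-numeric zt_time for samples: {bad}")
    if ((zt < 0) | (zt >= 24)).any():
        bad = design.index[(zt < 0) | (zt >= 24)].tolist()
        raise ValidationError(f"zt_time outside [0, 24) for samples: {bad}")
    design = design.copy()
    design["zt_time"] = zt.astype(float)
    # replicate_group must be constant within a (group, study) pair
    nuniq = design.groupby(["group", "study"], observed=True)["replicate_group"].nunique()
    if (nuniq > 1).any():
        bad = nuniq[nuniq > 1].index.tolist()
        raise ValidationError(
            f"replicate_group is not constant within (group, study) pairs: {bad}"
        )
    return design


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with an aligned sample design table.

    Parameters
    ----------
    matrix
        Features x samples table of log2 expression. Index holds unique
        feature ids (probesets or genes), columns hold sample ids.
    design
        One row per sample, indexed by sample id, with columns
        ``group, zt_time, replicate_group, study, platform``. Reordered
        to match the matrix columns on construction.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate the first offending cell for an actionable message
            for col in self.matrix.columns:
                coerced = pd.to_numeric(self.matrix[col], errors="coerce")
                if coerced.isna().any():
                    row = self.matrix.index[coerced.isna()][0]
                    raise ValidationError(
                        f"non-numeric expression value at feature {row!r}, sample {col!r}"
                    )
            raise ValidationError("expression matrix is not numeric")
        if np.isnan(values).any():
            rows = self.matrix.index[np.isnan(values).any(axis=1)][:5].tolist()
            raise ValidationError(f"missing expression values (e.g. features {rows})")
        if not np.isfinite(values).all():
            rows = self.matrix.index[~np.isfinite(values).all(axis=1)][:5].tolist()
            raise ValidationError(f"non-finite expression values (e.g. features {rows})")
        design = _check_design_frame(self.design)
        missing = [s for s in self.matrix.columns if s not in design.index]
        if missing:
            raise ValidationError(f"design is missing samples present in matrix: {missing}")
        extra = [s for s in design.index if s not in self.matrix.columns]
        if extra:
            raise ValidationError(f"design has samples absent from matrix: {extra}")
        object.__setattr__(self, "design", design.loc[self.matrix.columns])
        object.__setattr__(self, "matrix", self.matrix.astype(float))

    # -- convenience accessors -------------------------------------------
    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def groups(self) -> pd.Series:
        return self.design["group"]

    def with_matrix(self, matrix: pd.DataFrame) -> "ExpressionDataset":
        """Return a new dataset sharing this design with a new matrix."""
        return ExpressionDataset(matrix=matrix, design=self.design.copy())

    def subset_features(self, feature_ids) -> "ExpressionDataset":
        return ExpressionDataset(matrix=self.matrix.loc[feature_ids], design=self.design.copy())

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix.loc[:, sample_ids], design=self.design.loc[sample_ids]
        )


@dataclass
class ControlGeneSets:
    """Negative and positive control features.

    ``negative`` holds ids assumed unaffected by the treatment (used to
    learn unwanted variation and to check p-value uniformity);
    ``positive`` maps a contrast name to ids independently known to be
    differentially expressed in that contrast (used to benchmark recall).
    """

    negative: set = field(default_factory=set)
    positive: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_pos = set().union(*self.positive.values()) if self.positive else set()
        overlap = self.negative & all_pos
        if overlap:
            raise ValidationError(
                f"features listed as both negative and positive controls: {sorted(overlap)[:5]}"
            )

    def restrict_to(self, feature_ids) -> "ControlGeneSets":
        """Drop control ids absent from ``feature_ids``, warning about them."""
        present = set(feature_ids)
        missing = (self.negative - present) | {
            g for s in self.positive.values() for g in s if g not in present
        }
        if missing:
            warnings.warn(
                f"{len(missing)} control ids absent from dataset after harmonization",
                stacklevel=2,
            )
        return ControlGeneSets(
            negative=self.negative & present,
            positive={k: s & present for k, s in self.positive.items()},
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content): term id -> (term name, member genes)."""

    sets: dict
    source: str = ""

    def __post_init__(self) -> None:
        empty = [t for t, (_, genes) in self.sets.items() if not genes]
        if empty:
            raise ValidationError(f"empty gene sets: {empty[:5]}")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    """Parse the table block of a GEO series-matrix file."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValidationError(
            f"{path}: no !series_matrix_table_begin/end block found"
        ) from None
    block = "\n".join(lines[start + 1 : end])
    from io import StringIO

    df = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def load_expression(path, format: str = "tsv", log_base: float = 2.0, design=None):
    """Load an expression matrix (features x samples) from disk.

    Values are assumed to already be on a log scale with base ``log_base``
    and are converted to log2. A warning is emitted when the value range
    suggests a linear scale (max > 30). When ``design`` is given (a design
    table or a path to one) a validated :class:`ExpressionDataset` is
    returned; otherwise the bare matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_tsv_matrix(path)
    elif format == "geo_series_matrix":
        df = _read_geo_series_matrix(path)
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature ids: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"{path}: non-numeric value at feature {df.index[bad][0]!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in expression matrix")
    values = df.to_numpy(float)
    if values.size and np.nanmax(values) > 30:
        warnings.warn(
            f"{path}: maximum value {np.nanmax(values):.3g} > 30 suggests a linear "
            "(non-log) scale",
            stacklevel=2,
        )
    if log_base != 2.0:
        df = df * (np.log(log_base) / np.log(2.0))
    df.index.name = None
    df = df.astype(float)
    if design is not None:
        if not isinstance(design, pd.DataFrame):
            design = load_design(design)
        return ExpressionDataset(matrix=df, design=design)
    return df


def write_expression(matrix, path, feature_col: str = "feature_id") -> None:
    """Write a features x samples matrix (or ExpressionDataset) as TSV.

    Floats are written with 6 significant digits; the first column holds
    the feature id.
    """
    if isinstance(matrix, ExpressionDataset):
        matrix = matrix.matrix
    df = matrix.copy()
    df.index.name = feature_col
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

def load_design(path) -> pd.DataFrame:
    """Load a sample design table (TSV, first column sample_id)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    if first != "sample_id":
        raise ValidationError(f"{path}: first design column must be sample_id, got {first!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return _check_design_frame(df)


def write_design(design: pd.DataFrame, path) -> None:
    out = design.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Control lists and gene sets
# ---------------------------------------------------------------------------

def load_gene_list(path) -> list:
    """Plain text, one id per line; blank lines and '#' comments skipped."""
    return [
        l
        for l in (line.strip() for line in Path(path).read_text().splitlines())
        if l and not l.startswith("#")
    ]


def load_controls(neg_path, pos_path) -> ControlGeneSets:
    """Load control gene sets.

    Negative controls: one feature id per line. Positive controls: two
    tab-separated columns ``contrast<TAB>feature_id`` (a line with no tab
    is assigned to every contrast under the key ``"*"``).
    """
    negative = set()
    for line in Path(neg_path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            negative.add(line)
    positive: dict = {}
    for line in Path(pos_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            contrast, gene = line.split("\t")[:2]
        else:
            contrast, gene = "*", line
        positive.setdefault(contrast, set()).add(gene)
    if not positive:
        warnings.warn(f"{pos_path}: no positive controls found", stacklevel=2)
    return ControlGeneSets(negative=negative, positive=positive)


def load_gmt(path) -> GeneSetCollection:
    """Load a GMT gene-set file: term, description, member genes."""
    sets: dict = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{n}: GMT line has fewer than 3 fields")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in sets:
            raise ValidationError(f"{path}:{n}: duplicate term id {term!r}")
        sets[term] = (desc, set(genes))
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")
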