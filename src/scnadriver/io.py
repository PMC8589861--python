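"""Readers, writers and validation for the on-disk formats of the pipeline.

All genomic coordinates are converted to a 0-based half-open convention at
the I/O boundary; every in-memory table in this package uses that convention.
SEG files (tab-separated ``Sample Chromosome Start End Value``) are read as
1-based inclusive by default, matching the common export dialect of segmented
copy-number callers; a ``dialect`` argument exists because public exports are
ambiguous on this point.

Chromosome labels are normalised (a leading ``chr`` is stripped) and must come
from the ordered human set 1..22, X, Y; that fixed order defines "genomic
order" for every genome-wide output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered chromosome labels; defines genomic sort order package-wide.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "value"]


class FormatError(ValueError):
    """A file does not follow the declared format (missing columns, bad field)."""


class ValidationError(ValueError):
    """A well-formed file violates a semantic invariant (overlap, negative value)."""


def normalize_chromosome(label: str) -> str:
    """Strip an optional ``chr`` prefix and check membership in the ordered set."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    if lab == "23":
        lab = "X"
    if lab not in _CHROM_RANK:
        raise ValidationError(f"unknown chromosome label {label!r}")
    return lab


def chromosome_rank(label: str) -> int:
    return _CHROM_RANK[normalize_chromosome(label)]


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

def read_seg(path, dialect: str = "1-based-inclusive", permissive: bool = False) -> pd.DataFrame:
    """Read a SEG file into a segment table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header naming (case-insensitively)
        sample, chromosome, start, end, value.
    dialect : {"1-based-inclusive", "0-based-half-open"}
        Coordinate convention of the file. The default treats a row
        ``start=1 end=1000`` as covering bases 1..1000 inclusive, i.e. the
        internal half-open span ``[0, 1000)``.
    permissive : bool
        Downgrade overlapping-segment errors to warnings (real exports are
        messy); the offending later segment is kept as-is.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample, chromosome, start, end, value`` with internal
        0-based half-open coordinates and linear-scale copy ratio values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SEG file {path} missing required column(s): {missing}")
    df = df[SEG_COLUMNS].copy()
    if df.empty:
        return df.astype({"start": int, "end": int, "value": float})

    bad_rows: list[str] = []
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["value"] = df["value"].astype(float)
    except (TypeError, ValueError):
        # re-parse row by row to report line numbers (header is line 1)
        for i, row in df.iterrows():
            try:
                int(row["start"]), int(row["end"]), float(row["value"])
            except (TypeError, ValueError):
                bad_rows.append(f"line {i + 2}: {list(row)}")
        raise FormatError(f"SEG file {path}: malformed rows: {bad_rows}")

    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    if dialect == "1-based-inclusive":
        df["start"] = df["start"] - 1
    elif dialect != "0-based-half-open":
        raise ValueError(f"unknown SEG dialect {dialect!r}")

    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][:5].tolist()
        raise ValidationError(f"SEG file {path}: start >= end at rows {bad}")
    if (df["value"] <= 0).any():
        bad = df.index[df["value"] <= 0][:5].tolist()
        raise ValidationError(
            f"SEG file {path}: non-positive linear copy ratio at rows {bad}"
        )

    validate_segments(df, permissive=permissive, source=str(path))
    return df.reset_index(drop=True)


def validate_segments(segments: pd.DataFrame, permissive: bool = False, source: str = "<segments>") -> None:
    """Check that segments of each (sample, chromosome) are non-overlapping."""
    for (sample, chrom), grp in segments.groupby(["sample", "chromosome"], sort=False):
        g = grp.sort_values(["start", "end"])
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            msg = (f"{source}: overlapping segments for sample {sample!r} "
                   f"on chromosome {chrom}")
            if permissive:
                logger.warning(msg)
            else:
                raise ValidationError(msg)


def write_seg(segments: pd.DataFrame, path, dialect: str = "1-based-inclusive") -> None:
    """Write a segment table; inverse of :func:`read_seg` for the same dialect."""
    out = segments[SEG_COLUMNS].copy()
    if dialect == "1-based-inclusive":
        out["start"] = out["start"] + 1
    elif dialect != "0-based-half-open":
        raise ValueError(f"unknown SEG dialect {dialect!r}")
    out.columns = ["Sample", "Chromosome", "Start", "End", "Value"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV of nonnegative abundances (FPKM-like).

    First column is the gene identifier; remaining columns are samples.
    Duplicate gene rows, duplicate sample columns, or negative values raise
    :class:`ValidationError`.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if pd.Index(header[1:]).duplicated().any():
        raise ValidationError(f"expression file {path}: duplicated sample column")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()[:5].tolist()
        raise ValidationError(f"expression file {path}: duplicated gene_id(s) {dups}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"expression file {path}: missing values not allowed")
    if (values < 0).any():
        raise ValidationError(f"expression file {path}: negative abundance value")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene annotation (BED-like)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["chromosome", "start", "end", "gene_id", "symbol"]


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like annotation TSV (chrom, start, end, gene_id, symbol[, tags]).

    Coordinates are taken as 0-based half-open (BED convention). An optional
    sixth column carries comma-separated set-membership tags (e.g. ``MRP``).
    Returns a DataFrame indexed by ``gene_id``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 5:
        raise FormatError(
            f"annotation file {path}: expected >= 5 columns "
            "(chrom, start, end, gene_id, symbol), got " + str(df.shape[1])
        )
    df = df.iloc[:, :6] if df.shape[1] >= 6 else df.iloc[:, :5]
    df.columns = ANNOTATION_COLUMNS + (["tags"] if df.shape[1] == 6 else [])
    if "tags" not in df.columns:
        df["tags"] = ""
    df["tags"] = df["tags"].fillna("")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"][:5].tolist()
        raise ValidationError(f"annotation file {path}: start >= end for {bad}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5].tolist()
        raise ValidationError(f"annotation file {path}: duplicated gene_id(s) {dups}")
    return df.set_index("gene_id")


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.reset_index()[["chromosome", "start", "end", "gene_id", "symbol", "tags"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def sort_genomic(annotation: pd.DataFrame) -> pd.DataFrame:
    """Sort an annotation frame by (chromosome order, start, gene_id)."""
    rank = annotation["chromosome"].map(_CHROM_RANK)
    order = np.lexsort((annotation.index, annotation["start"].to_numpy(), rank.to_numpy()))
    return annotation.iloc[order]


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def read_templates(path) -> pd.DataFrame:
    """Read subclass templates: TSV with columns class, gene_id, direction (+-1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = ["class", "gene_id", "direction"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"template file {path}: missing column(s) {missing}")
    df = df[needed].rename(columns={"class": "class_label"})
    df["direction"] = df["direction"].astype(int)
    if not df["direction"].isin([-1, 1]).all():
        bad = df.loc[~df["direction"].isin([-1, 1]), "direction"].unique()[:5].tolist()
        raise ValidationError(f"template file {path}: directions must be +-1, got {bad}")
    if df.empty:
        raise ValidationError(f"template file {path}: no template genes")
    counts = df.groupby("class_label").size()
    if (counts < 1).any():
        raise ValidationError(f"template file {path}: class with no genes")
    if df.duplicated(["class_label", "gene_id"]).any():
        raise ValidationError(f"template file {path}: duplicated gene within a class")
    return df.reset_index(drop=True)


def write_templates(templates: pd.DataFrame, path) -> None:
    out = templates.rename(columns={"class_label": "class"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, os_time, os_event, optional covariates)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise FormatError(f"clinical file {path}: missing column {col!r}")
    if (df["os_time"] < 0).any():
        raise ValidationError(f"clinical file {path}: negative os_time")
    if not df["os_event"].isin([0, 1]).all():
        raise ValidationError(f"clinical file {path}: os_event must be 0/1")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """A paired tumor/normal cohort: expression, segmented copy number, clinical.

    ``expression_pt``/``expression_nt`` are genes x samples abundance frames;
    ``dcn_pt``/``dcn_nt`` are segment tables; ``pairing`` maps each tumor DCN
    sample to its matched-normal DCN sample. Expression and DCN sample sets
    may differ; their intersection (the samples usable for dosage association)
    is recorded in ``intersection_samples``.
    """

    expression_pt: pd.DataFrame
    expression_nt: pd.DataFrame
    dcn_pt: pd.DataFrame
    dcn_nt: pd.DataFrame
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    pairing: dict[str, str]
    intersection_samples: list[str] = field(default_factory=list)
    orphan_clinical: pd.DataFrame | None = None


def assemble_cohort(
    expression_pt: pd.DataFrame,
    expression_nt: pd.DataFrame,
    dcn_pt: pd.DataFrame,
    dcn_nt: pd.DataFrame,
    annotation: pd.DataFrame,
    clinical: pd.DataFrame,
    pairing: dict[str, str],
) -> CohortDataset:
    """Assemble validated components into a :class:`CohortDataset`.

    Records the intersection of tumor expression and tumor DCN samples;
    samples present in only one assay are kept in that assay and logged.
    Clinical rows for unknown samples are set aside (``orphan_clinical``)
    with a warning. A tumor DCN sample without a matched-normal pairing
    entry is an error.
    """
    dcn_pt_samples = set(dcn_pt["sample"].unique())
    dcn_nt_samples = set(dcn_nt["sample"].unique())
    unpaired = sorted(dcn_pt_samples - set(pairing))
    if unpaired:
        raise ValidationError(f"tumor DCN sample(s) without matched-normal pairing: {unpaired[:5]}")
    missing_nt = sorted({pairing[s] for s in dcn_pt_samples} - dcn_nt_samples)
    if missing_nt:
        raise ValidationError(f"paired normal DCN sample(s) absent from NT segments: {missing_nt[:5]}")

    expr_samples = set(expression_pt.columns)
    intersection = sorted(expr_samples & dcn_pt_samples)
    only_expr = sorted(expr_samples - dcn_pt_samples)
    only_dcn = sorted(dcn_pt_samples - expr_samples)
    logger.info(
        "cohort assembly: %d tumor samples with both expression and DCN "
        "(%d expression-only, %d DCN-only)",
        len(intersection), len(only_expr), len(only_dcn),
    )

    known = expr_samples | dcn_pt_samples | set(expression_nt.columns) | dcn_nt_samples
    orphan_mask = ~clinical.index.isin(known)
    orphans = clinical.loc[orphan_mask]
    if len(orphans):
        logger.warning("clinical rows for %d unknown sample(s) set aside", len(orphans))
    return CohortDataset(
        expression_pt=expression_pt,
        expression_nt=expression_nt,
        dcn_pt=dcn_pt,
        dcn_nt=dcn_nt,
        annotation=annotation,
        clinical=clinical.loc[~orphan_mask],
        pairing=dict(pairing),
        intersection_samples=intersection,
        orphan_clinical=orphans if len(orphans) else None,
    )
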