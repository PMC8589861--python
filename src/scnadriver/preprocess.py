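"""Gene-level preprocessing: segment-to-gene mapping and normalized matrices.

Turns segmented DNA copy number (DCN, linear copy ratio per segment) and raw
abundance tables into the three gene-level matrices downstream stages use:

* gene DCN — genes x samples linear copy ratio, from overlap mapping;
* DE ("deregulated expression") — per tumor sample, log2 of its abundance
  over the mean abundance of all normal samples (with a pseudocount);
* SCNA — per tumor sample, log2 of its gene DCN over the mean gene DCN of
  the normal samples.

A gene fully inside one segment inherits that segment's value; a gene
spanning several segments gets the overlap-length-weighted mean; a gene with
no overlapping segment is missing (NaN) for that sample. Genes with DCN in
fewer than half the tumor samples are dropped before association.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0


def _weighted_segment_means(
    seg_start: np.ndarray, seg_end: np.ndarray, seg_val: np.ndarray,
    gene_start: np.ndarray, gene_end: np.ndarray,
) -> np.ndarray:
    """Overlap-length-weighted mean segment value per gene interval.

    Segments must be non-overlapping and sorted by start. Uses the piecewise-
    linear integrals C(x) = sum_i v_i * |seg_i intersect [0, x)| and
    L(x) = covered length below x, evaluated at gene edges: the weighted mean
    over [gs, ge) is (C(ge) - C(gs)) / (L(ge) - L(gs)); NaN when no coverage.
    """
    knots = np.empty(seg_start.size * 2, dtype=float)
    knots[0::2] = seg_start
    knots[1::2] = seg_end
    lengths = (seg_end - seg_start).astype(float)
    cum_val = np.zeros_like(knots)
    cum_val[1::2] = lengths * seg_val
    cum_val = np.cumsum(cum_val)
    # inside a segment C rises linearly; between segments it is flat
    cum_val[0::2] = cum_val[1::2] - lengths * seg_val  # value at each start
    cum_len = np.zeros_like(knots)
    cum_len[1::2] = lengths
    cum_len = np.cumsum(cum_len)
    cum_len[0::2] = cum_len[1::2] - lengths

    c_hi = np.interp(gene_end, knots, cum_val)
    c_lo = np.interp(gene_start, knots, cum_val)
    l_hi = np.interp(gene_end, knots, cum_len)
    l_lo = np.interp(gene_start, knots, cum_len)
    covered = l_hi - l_lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(covered > 0, (c_hi - c_lo) / covered, np.nan)
    return out


def map_segments_to_genes(segments: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Map per-sample segment values onto genes.

    Parameters
    ----------
    segments : DataFrame
        Segment table (sample, chromosome, start, end, value), 0-based
        half-open, non-overlapping within each sample/chromosome.
    annotation : DataFrame
        Gene annotation indexed by gene_id with chromosome/start/end.

    Returns
    -------
    DataFrame
        genes x samples linear copy-ratio matrix; NaN where a gene has no
        overlapping segment in a sample.
    """
    samples = list(dict.fromkeys(segments["sample"]))
    genes = annotation.index
    out = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)

    ann_by_chrom = {
        chrom: grp.sort_values("start")
        for chrom, grp in annotation.groupby("chromosome", sort=False)
    }
    for (sample, chrom), grp in segments.groupby(["sample", "chromosome"], sort=False):
        ann = ann_by_chrom.get(chrom)
        if ann is None:
            continue
        g = grp.sort_values("start")
        vals = _weighted_segment_means(
            g["start"].to_numpy(float), g["end"].to_numpy(float),
            g["value"].to_numpy(float),
            ann["start"].to_numpy(float), ann["end"].to_numpy(float),
        )
        out.loc[ann.index, sample] = vals
    return out


def filter_low_coverage_genes(
    gene_dcn: pd.DataFrame, min_fraction: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes with DCN present in strictly less than ``min_fraction`` of samples.

    Returns the retained matrix and the list of removed gene ids. The boundary
    is strict: a gene covered in exactly half the samples is retained.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if gene_dcn.size == 0:
        raise ValueError("empty gene DCN matrix")
    frac = gene_dcn.notna().mean(axis=1)
    removed = gene_dcn.index[frac < min_fraction].tolist()
    kept = gene_dcn.drop(index=removed)
    logger.info("coverage filter: removed %d of %d genes (< %.0f%% coverage)",
                len(removed), len(gene_dcn), 100 * min_fraction)
    return kept, removed


def compute_de_matrix(
    expression_pt: pd.DataFrame,
    expression_nt: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2 tumor expression relative to the mean of all normal samples.

    DE[g, s] = log2((pt[g, s] + c) / (mean_nt[g] + c)). The pseudocount keeps
    zero-abundance genes finite; an all-zero gene maps to 0 everywhere.
    """
    missing = expression_pt.index.difference(expression_nt.index)
    if len(missing):
        raise ValueError(f"gene(s) absent from the normal expression table: {missing[:5].tolist()}")
    nt_mean = expression_nt.loc[expression_pt.index].mean(axis=1)
    de = np.log2(expression_pt.add(pseudocount).div(nt_mean + pseudocount, axis=0))
    return de


def compute_scna_matrix(gene_dcn_pt: pd.DataFrame, gene_dcn_nt: pd.DataFrame) -> pd.DataFrame:
    """log2 tumor gene DCN relative to the mean gene DCN over normal samples.

    The normal mean is taken over non-missing values; a gene with no
    non-missing normal value is emitted all-missing with a warning. Missing
    tumor entries propagate.
    """
    common = gene_dcn_pt.index.intersection(gene_dcn_nt.index)
    pt = gene_dcn_pt.loc[common]
    nt_mean = gene_dcn_nt.loc[common].mean(axis=1)
    no_nt = nt_mean.index[nt_mean.isna()]
    if len(no_nt):
        logger.warning("SCNA: %d gene(s) with no normal DCN values emitted as missing", len(no_nt))
    with np.errstate(invalid="ignore", divide="ignore"):
        scna = np.log2(pt.div(nt_mean, axis=0))
    return scna
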