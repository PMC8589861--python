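"""Cohort stratification, gain/loss calling and SCNA frequency landscapes.

A cohort is split on one gene's copy number (or expression) into an upper-
and lower-quartile group; per-gene gain/loss status comes from thresholding
log2 copy ratio at +-0.2; signed frequency profiles (losses plotted below
zero) are computed per group in genomic order and differenced to find the
regions that travel with the stratifying gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import sort_genomic

GAIN, NEUTRAL, LOSS = 1.0, 0.0, -1.0  # status codes; NaN = missing

DEFAULT_CALL_THRESHOLD = 0.2
DEFAULT_MIN_DIFF = 0.2


@dataclass
class StratificationResult:
    gene_id: str
    group_high: list[str]
    group_low: list[str]
    rule: str
    k: int


def quartile_group_size(n: int) -> int:
    """Quartile group size k = round-half-to-even(n / 4).

    This banker's rounding is the unique convention consistent with quartile
    groups of 94, 93 and 52 reported for cohorts of 376, 371 and 210.
    """
    return round(n / 4)


def stratify_quartiles(values: pd.Series, gene_id: str = "") -> StratificationResult:
    """Upper/lower-quartile stratification on a per-sample scalar.

    Ties are broken by ascending sample id for determinism. Requires >= 4
    samples; the two groups are disjoint and of equal size k.
    """
    values = values.dropna()
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 samples to form quartile groups")
    k = quartile_group_size(n)
    order = np.lexsort((values.index.astype(str), values.to_numpy()))
    ranked = values.index[order]
    low = ranked[:k].tolist()
    high = ranked[n - k:].tolist()
    return StratificationResult(gene_id, high, low, "quartile", k)


def stratify_median(values: pd.Series, gene_id: str = "") -> StratificationResult:
    """Median split: strictly above the median -> high; at or below -> low.

    Assigning exact-median samples to the low group makes the split
    deterministic; with an odd sample count the groups differ by one.
    """
    values = values.dropna()
    if len(values) < 2:
        raise ValueError("need at least 2 samples for a median split")
    med = values.median()
    high = sorted(values.index[values > med])
    low = sorted(values.index[values <= med])
    return StratificationResult(gene_id, list(high), list(low), "median", min(len(high), len(low)))


def call_gain_loss(scna: pd.DataFrame, threshold: float = DEFAULT_CALL_THRESHOLD) -> pd.DataFrame:
    """Per-gene, per-sample status from log2 copy ratio.

    gain iff value > threshold, loss iff value < -threshold (strict
    inequalities; a value exactly at the threshold is neutral); missing
    propagates. Status codes: +1 gain, 0 neutral, -1 loss, NaN missing.
    """
    x = scna.to_numpy(float)
    status = np.where(x > threshold, GAIN, np.where(x < -threshold, LOSS, NEUTRAL))
    status = np.where(np.isnan(x), np.nan, status)
    return pd.DataFrame(status, index=scna.index, columns=scna.columns)


def scna_frequency_profile(
    status: pd.DataFrame, group: list[str], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Signed gain/loss frequencies of one sample group, in genomic order.

    Per gene: ``freq_gain`` = #gain / #non-missing and ``freq_loss_signed`` =
    -#loss / #non-missing over the group's samples. Genes with no non-missing
    status are flagged missing. Output rows follow (chromosome order, start).
    """
    if not group:
        raise ValueError("empty sample group")
    sub = status[list(group)].to_numpy(float)
    n_ok = np.isfinite(sub).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_gain = np.nansum(sub == GAIN, axis=1) / n_ok
        freq_loss = -(np.nansum(sub == LOSS, axis=1) / n_ok)
    out = pd.DataFrame(
        {
            "freq_gain": np.where(n_ok > 0, freq_gain, np.nan),
            "freq_loss_signed": np.where(n_ok > 0, freq_loss, np.nan),
            "n_informative": n_ok.astype(int),
            "missing": n_ok == 0,
        },
        index=status.index,
    )
    ann = sort_genomic(annotation.loc[annotation.index.intersection(out.index)])
    out = out.loc[ann.index]
    out.insert(0, "chromosome", ann["chromosome"])
    out.insert(1, "start", ann["start"])
    return out


def differential_frequency(
    profile_low: pd.DataFrame,
    profile_high: pd.DataFrame,
    min_diff: float = DEFAULT_MIN_DIFF,
) -> pd.DataFrame:
    """Between-group frequency differences (low - high), gain and signed loss
    differenced separately; a gene is flagged when either |difference|
    exceeds ``min_diff``."""
    genes = profile_low.index
    out = profile_low[["chromosome", "start"]].copy()
    out["gain_low"] = profile_low["freq_gain"]
    out["gain_high"] = profile_high.loc[genes, "freq_gain"]
    out["loss_low"] = profile_low["freq_loss_signed"]
    out["loss_high"] = profile_high.loc[genes, "freq_loss_signed"]
    out["diff_gain"] = out["gain_low"] - out["gain_high"]
    out["diff_loss"] = out["loss_low"] - out["loss_high"]
    out["flagged"] = (
        (out["diff_gain"].abs() > min_diff) | (out["diff_loss"].abs() > min_diff)
    ).fillna(False)
    return out


def plot_frequency_landscape(profile: pd.DataFrame, path, title: str = "") -> None:
    """Frequency-vs-genomic-position plot with chromosome boundary lines;
    losses drawn below zero. The TSV profile is the tested artifact; this is
    a convenience rendering."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import CHROMOSOMES

    prof = profile.dropna(subset=["freq_gain"])
    offsets: dict[str, float] = {}
    pos = 0.0
    bounds = []
    for c in CHROMOSOMES:
        sub = prof[prof["chromosome"] == c]
        if sub.empty:
            continue
        offsets[c] = pos
        pos += sub["start"].max() + 1
        bounds.append(pos)
    x = prof["start"] + prof["chromosome"].map(offsets)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.fill_between(x, 0, prof["freq_gain"], color="firebrick", step="mid", label="gain")
    ax.fill_between(x, 0, prof["freq_loss_signed"], color="steelblue", step="mid", label="loss")
    for b in bounds[:-1]:
        ax.axvline(b, color="black", lw=0.6)
    ax.axhline(0, color="black", lw=0.6)
    ax.set_ylim(-1, 1)
    ax.set_ylabel("SCNA frequency")
    ax.set_xlabel("genomic position")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
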