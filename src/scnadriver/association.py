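"""Permutation differential expression and SCNA-dosage association.

The discovery rule for copy-number-driven genes combines three gates, all on
log2-scale matrices produced by :mod:`scnadriver.preprocess`:

1. differential expression between normal and tumor samples — Welch's t with
   a permutation p-value, and an average fold change beyond +-``de_fc_thresh``;
2. concordance — the mean SCNA fold change has the same sign as the mean DE
   fold change (a gained gene must be up, a lost gene down);
3. dosage correlation — Pearson r between a gene's DE and SCNA values across
   the samples carrying both assays, with r > ``r_thresh``.

Permutation p-values are add-one Monte Carlo estimates,
p = (1 + #{|t*| >= |t|}) / (B + 1), except when the label arrangements can be
enumerated exhaustively, in which case p is the exact fraction of
arrangements at least as extreme (the observed one included). Group screens
share one permutation plan across genes (the same label shuffles for every
gene) for reproducibility and speed.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_B = 9_999


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def permutation_t_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    B: int = DEFAULT_B,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test on Welch's t between two groups.

    Enumerates all label arrangements when there are at most ``B`` of them;
    otherwise draws ``B`` random shuffles and returns the add-one estimate.
    Zero variance in both groups yields (0, 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if B < 1:
        raise ValueError("B must be >= 1")
    pooled = np.concatenate([a, b])
    if pooled.var(ddof=0) == 0:
        return 0.0, 1.0
    t_obs = _welch_t(a, b)

    n, na = len(pooled), len(a)
    n_arrangements = comb(n, na)
    if n_arrangements <= B:
        count = 0
        idx_all = np.arange(n)
        for idx_a in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            t_star = _welch_t(pooled[mask], pooled[~mask])
            if abs(t_star) >= abs(t_obs) - 1e-12:
                count += 1
        return t_obs, count / n_arrangements
    rng = np.random.default_rng() if rng is None else rng
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        t_star = _welch_t(pooled[perm[:na]], pooled[perm[na:]])
        if abs(t_star) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, (1 + count) / (B + 1)


def _welch_t_matrix(x: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Welch t per row of ``x`` (genes x samples) for column groups given by
    boolean mask rows ``mask_a`` (one row per permutation). Vectorised via
    matrix products; returns an array (n_perms, n_genes)."""
    m = mask_a.astype(float)
    na = m.sum(axis=1, keepdims=True)
    nb = m.shape[1] - na
    tot = x.sum(axis=1)
    tot2 = (x * x).sum(axis=1)
    sa = m @ x.T
    sa2 = m @ (x * x).T
    sb = tot[None, :] - sa
    sb2 = tot2[None, :] - sa2
    mean_a = sa / na
    mean_b = sb / nb
    var_a = (sa2 - na * mean_a ** 2) / (na - 1)
    var_b = (sb2 - nb * mean_b ** 2) / (nb - 1)
    np.clip(var_a, 0, None, out=var_a)
    np.clip(var_b, 0, None, out=var_b)
    denom = np.sqrt(var_a / na + var_b / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / denom
    return np.where(denom == 0, 0.0, t)


def permutation_t_screen(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    B: int = DEFAULT_B,
    rng: np.random.Generator | None = None,
    block: int = 1_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise permutation Welch tests with one shared permutation plan.

    ``matrix_a``/``matrix_b`` are genes x samples blocks of the two groups.
    Returns (t, perm_p) per gene with add-one Monte Carlo p-values. The same
    ``B`` label shuffles are applied to every gene; permutations are processed
    in blocks to bound memory.
    """
    a = np.asarray(matrix_a, float)
    b = np.asarray(matrix_b, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("group matrices must share the gene axis")
    rng = np.random.default_rng() if rng is None else rng
    x = np.concatenate([a, b], axis=1)
    n, na = x.shape[1], a.shape[1]
    obs_mask = np.zeros((1, n), dtype=bool)
    obs_mask[0, :na] = True
    t_obs = _welch_t_matrix(x, obs_mask)[0]

    count = np.zeros(x.shape[0], dtype=int)
    done = 0
    while done < B:
        nb_perm = min(block, B - done)
        masks = np.zeros((nb_perm, n), dtype=bool)
        for i in range(nb_perm):
            masks[i, rng.permutation(n)[:na]] = True
        t_star = _welch_t_matrix(x, masks)
        count += (np.abs(t_star) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        done += nb_perm
    return t_obs, (1 + count) / (B + 1)


def gene_wise_correlation(
    de: pd.DataFrame, scna: pd.DataFrame, samples: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between DE and SCNA per gene across shared samples.

    Two-sided p-values come from the t transform with n - 2 degrees of
    freedom. Genes with fewer than 3 complete pairs, or zero variance on
    either axis, are reported with missing r/p (and a summary warning).
    """
    if samples is None:
        samples = sorted(set(de.columns) & set(scna.columns))
    genes = de.index.intersection(scna.index)
    x = de.loc[genes, samples].to_numpy(float)
    y = scna.loc[genes, samples].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = ok.sum(axis=1).astype(float)
    xm = np.where(ok, x, 0.0)
    ym = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xm.sum(axis=1) / n
        my = ym.sum(axis=1) / n
        dx = np.where(ok, x - mx[:, None], 0.0)
        dy = np.where(ok, y - my[:, None], 0.0)
        sxy = (dx * dy).sum(axis=1)
        sxx = (dx * dx).sum(axis=1)
        syy = (dy * dy).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)
    bad = (n < 3) | (sxx == 0) | (syy == 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isfinite(r) & (np.abs(r) == 1.0), 0.0, p)
    if bad.any():
        logger.warning("correlation: %d gene(s) with <3 pairs or zero variance", int(bad.sum()))
    return pd.DataFrame({"cor_r": r, "cor_p": p, "n_pairs": n.astype(int)}, index=genes)


def associate(
    de: pd.DataFrame,
    scna: pd.DataFrame,
    log2_expr_pt: pd.DataFrame,
    log2_expr_nt: pd.DataFrame,
    B: int = DEFAULT_B,
    rng: np.random.Generator | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Build the per-gene association table.

    Columns: ``de_fc`` (mean log2 DE over tumors), ``perm_p`` (normal-vs-tumor
    permutation Welch test on log2 expression), ``scna_fc`` (mean log2 SCNA),
    ``cor_r``/``cor_p`` (dosage correlation), plus BH-adjusted ``de_q``/
    ``cor_q`` reported as extra columns.
    """
    genes = de.index.intersection(scna.index)
    rng = np.random.default_rng() if rng is None else rng
    t_obs, perm_p = permutation_t_screen(
        log2_expr_nt.loc[genes].to_numpy(), log2_expr_pt.loc[genes].to_numpy(), B=B, rng=rng)
    cor = gene_wise_correlation(de.loc[genes], scna.loc[genes], samples)
    records = pd.DataFrame(
        {
            "de_fc": de.loc[genes].mean(axis=1),
            "t": t_obs,
            "perm_p": perm_p,
            "scna_fc": scna.loc[genes].mean(axis=1),
            "cor_r": cor["cor_r"],
            "cor_p": cor["cor_p"],
            "n_pairs": cor["n_pairs"],
        },
        index=genes,
    )
    records["de_q"] = multipletests(records["perm_p"], method="fdr_bh")[1]
    finite = records["cor_p"].notna()
    records["cor_q"] = np.nan
    if finite.any():
        records.loc[finite, "cor_q"] = multipletests(records.loc[finite, "cor_p"], method="fdr_bh")[1]
    return records


def select_scna_dependent_genes(
    records: pd.DataFrame,
    de_fc_thresh: float = 0.3,
    de_p_thresh: float = 0.005,
    r_thresh: float = 0.5,
    r_p_thresh: float = 0.005,
) -> pd.DataFrame:
    """Apply the three-gate selection rule; returns records with ``selected``
    and ``direction`` columns (direction +1 up / -1 down for selected genes).

    A gene is selected iff |de_fc| > de_fc_thresh and perm_p < de_p_thresh,
    sign(scna_fc) == sign(de_fc), and cor_r > r_thresh with cor_p < r_p_thresh.
    The correlation gate is signed (dosage dependence is positive).
    """
    out = records.copy()
    de_pass = (out["de_fc"].abs() > de_fc_thresh) & (out["perm_p"] < de_p_thresh)
    concord = np.sign(out["scna_fc"]) == np.sign(out["de_fc"])
    cor_pass = (out["cor_r"] > r_thresh) & (out["cor_p"] < r_p_thresh)
    out["selected"] = (de_pass & concord & cor_pass).fillna(False)
    out["direction"] = np.where(out["selected"], np.sign(out["de_fc"]), 0).astype(int)
    return out


def group_differential_expression(
    de: pd.DataFrame,
    group_high: list[str],
    group_low: list[str],
    B: int = DEFAULT_B,
    p_thresh: float = 0.001,
    fd_thresh: float = 0.5,
    rng: np.random.Generator | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Between-group expression screen on the DE matrix.

    ``fold_difference`` is mean(low) - mean(high) of log2 DE; significance is
    the shared-plan permutation Welch test across group labels. Genes are
    flagged ``up``/``down`` (in the low group) when |fold_difference| exceeds
    ``fd_thresh`` and perm_p < ``p_thresh``. With ``top_k``, flagged genes are
    ranked by (perm_p, -|fold_difference|) and the rank recorded.
    """
    if set(group_high) & set(group_low):
        raise ValueError("groups overlap")
    if len(group_high) < 2 or len(group_low) < 2:
        raise ValueError("each group needs at least 2 samples")
    lo = de[list(group_low)].to_numpy(float)
    hi = de[list(group_high)].to_numpy(float)
    t_obs, perm_p = permutation_t_screen(lo, hi, B=B, rng=rng)
    fold = lo.mean(axis=1) - hi.mean(axis=1)
    out = pd.DataFrame({"fold_difference": fold, "t": t_obs, "perm_p": perm_p}, index=de.index)
    flagged = (np.abs(fold) > fd_thresh) & (perm_p < p_thresh)
    out["direction"] = np.where(flagged, np.where(fold > 0, "up", "down"), "")
    if top_k is not None:
        order = out[flagged].sort_values(["perm_p", "fold_difference"],
                                         key=lambda s: s if s.name == "perm_p" else -s.abs())
        out["rank"] = np.nan
        out.loc[order.index[:top_k], "rank"] = np.arange(1, min(top_k, len(order)) + 1)
    return out
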