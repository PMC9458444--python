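"""Per-position negative-binomial differential abundance.

Counts are normalized across samples with median-of-ratios size factors, a
per-position NB dispersion is estimated by method of moments and shrunk
toward a mean-dispersion trend, and a two-group NB GLM (log link, size-factor
offsets) is fitted per position.  The Wald statistic on the condition
coefficient gives a two-sided p-value, BH-adjusted across retained positions.
This is a deliberately simplified NB stage: no Cox-Reid adjusted-profile
dispersions, no outlier refitting, no independent filtering; its operating
characteristics are established by simulation calibration instead.

The enrichment ranking score per position is ``|log2FC| * max(-log10(padj), 5)``
— a floor construction: any position with padj >= 1e-5 gets multiplier
exactly 5, so ordering among those positions is by |log2FC| alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import PositionalCountMatrix

__all__ = [
    "estimate_size_factors",
    "fit_dispersions",
    "wald_test",
    "ranking_scores",
    "sample_similarity",
    "run_differential",
]

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8
_SINGLE_REP_DISPERSION = 0.2  # fixed conservative fallback at n=1 per group
_PADJ_CLAMP = 1e-300
_BETA_CAP = 30.0  # natural-log scale; bounds group means in degenerate fits
_MIN_MU = 0.5  # fitted-mean floor: keeps the Wald SE finite for all-zero groups


def estimate_size_factors(m: PositionalCountMatrix) -> np.ndarray:
    """Median-of-ratios size factors on the retained positions.

    factor_j = median_i counts[j, i] / geomean_i over positions i with nonzero
    counts in every sample; factors are rescaled to geometric mean 1.  When no
    position is nonzero in all samples, falls back to library-size ratios with
    a warning.
    """
    counts = m.counts[:, m.retained].astype(float)
    all_pos = np.all(counts > 0, axis=0)
    if all_pos.any():
        logc = np.log(counts[:, all_pos])
        loggeo = logc.mean(axis=0)
        sf = np.exp(np.median(logc - loggeo, axis=1))
    else:
        warnings.warn(
            "no position has nonzero counts in every sample; falling back to "
            "library-size normalization",
            stacklevel=2,
        )
        lib = counts.sum(axis=1)
        if np.any(lib <= 0):
            raise ValueError("a sample has zero total counts; cannot normalize")
        sf = lib
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def _trend_curve(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit disp ~ a0 + a1/mean by trimmed least squares (both terms >= 0)."""
    ok = np.isfinite(mean) & np.isfinite(disp) & (mean > 0) & (disp > 1e-7)
    if ok.sum() < 10:
        med = float(np.median(disp[disp > 0])) if np.any(disp > 0) else _DISPERSION_FLOOR
        return max(med, _DISPERSION_FLOOR), 0.0
    x, y = mean[ok], disp[ok]
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(3):
        X = np.column_stack([np.ones_like(x), 1.0 / x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
        pred = a0 + a1 / x
        ratio = y / np.maximum(pred, _DISPERSION_FLOOR)
        keep = (ratio > 1e-4) & (ratio < 15)  # trim gross outliers, refit
        if keep.all() or keep.sum() < 10:
            break
        x, y = x[keep], y[keep]
    return max(a0, _DISPERSION_FLOOR), a1


def fit_dispersions(
    m: PositionalCountMatrix,
    sf: np.ndarray,
    prior_weight: float = 2.0,
) -> np.ndarray:
    """Per-position NB dispersions on the retained positions.

    Method-of-moments estimates from normalized counts (pooled within-group
    variance), shrunk in log space toward a fitted a0 + a1/mean trend with
    ``prior_weight`` pseudo-observations, then floored at the trend itself:
    with a handful of replicates a below-trend estimate is indistinguishable
    from sampling noise and would make the Wald test anticonservative, while
    above-trend estimates carry real signal and are kept.  Global floor 1e-8.
    Single-replicate designs get a fixed conservative dispersion.
    """
    q = m.counts[:, m.retained] / sf[:, None]
    n_pos = q.shape[1]
    if m.single_replicate:
        logger.info("single-replicate design: fixed dispersion %.3g", _SINGLE_REP_DISPERSION)
        return np.full(n_pos, _SINGLE_REP_DISPERSION)
    x = m.condition_indicator()
    groups = [x == 0, x == 1]
    var_pool = np.zeros(n_pos)
    df = 0
    mean_all = q.mean(axis=0)
    for g in groups:
        ng = int(g.sum())
        if ng >= 2:
            var_pool += q[g].var(axis=0, ddof=1) * (ng - 1)
            df += ng - 1
    var_pool /= max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (var_pool - mean_all) / mean_all**2
    mom = np.where(np.isfinite(mom), mom, _DISPERSION_FLOOR)
    mom = np.maximum(mom, _DISPERSION_FLOOR)
    a0, a1 = _trend_curve(mean_all, mom)
    trend = np.maximum(a0 + a1 / np.maximum(mean_all, 1e-8), _DISPERSION_FLOOR)
    w = df / (df + prior_weight)
    disp = np.exp(w * np.log(mom) + (1 - w) * np.log(trend))
    disp = np.maximum(disp, trend)
    return np.maximum(disp, _DISPERSION_FLOOR)


def _irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for NB GLM  log mu = b0 + b1*x + log sf, per position.

    y: (n_samples, n_pos); x: (n_samples,) 0/1; alpha: (n_pos,) dispersions.
    Returns (b0, b1, se1, converged).
    """
    o = np.log(sf)[:, None]
    n0 = (x == 0).sum()
    n1 = (x == 1).sum()
    qa = (y[x == 0] / sf[x == 0, None]).mean(axis=0) if n0 else np.zeros(y.shape[1])
    qb = (y[x == 1] / sf[x == 1, None]).mean(axis=0) if n1 else np.zeros(y.shape[1])
    eps = 1e-8
    b0 = np.log(np.maximum(qa, eps))
    b1 = np.log(np.maximum(qb, eps)) - b0
    b0 = np.clip(b0, -_BETA_CAP, 35.0)
    b1 = np.clip(b1, -_BETA_CAP, _BETA_CAP)
    xv = x[:, None]
    converged = np.zeros(y.shape[1], dtype=bool)
    a = alpha[None, :]
    for _ in range(max_iter):
        eta = b0[None, :] + xv * b1[None, :] + o
        mu = np.exp(np.clip(eta, -50, 50))
        w = mu / (1.0 + a * mu)
        z = (eta - o) + (y - mu) / mu
        a11 = w.sum(axis=0)
        a12 = (w * xv).sum(axis=0)
        a22 = (w * xv * xv).sum(axis=0)
        c1 = (w * z).sum(axis=0)
        c2 = (w * xv * z).sum(axis=0)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (a22 * c1 - a12 * c2) / det
        nb1 = (a11 * c2 - a12 * c1) / det
        nb0 = np.clip(np.where(np.isfinite(nb0), nb0, b0), -_BETA_CAP, 35.0)
        nb1 = np.clip(np.where(np.isfinite(nb1), nb1, b1), -_BETA_CAP, _BETA_CAP)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        newly = step < tol
        converged |= newly
        if converged.all():
            break
    # SE from the information matrix at the fit, with fitted means floored at
    # _MIN_MU: a boundary fit (e.g. one group all zero) then keeps a finite,
    # conservative SE instead of an infinite one
    eta = b0[None, :] + xv * b1[None, :] + o
    mu = np.maximum(np.exp(np.clip(eta, -50, 50)), _MIN_MU)
    w = mu / (1.0 + a * mu)
    a11 = w.sum(axis=0)
    a12 = (w * xv).sum(axis=0)
    a22 = (w * xv * xv).sum(axis=0)
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, a11 / det, np.nan))
    # a coefficient parked at the cap is a boundary fit, not a failure
    converged |= np.abs(b1) >= _BETA_CAP - 1e-6
    return b0, b1, se1, converged


def wald_test(
    m: PositionalCountMatrix,
    sf: np.ndarray,
    dispersions: np.ndarray,
) -> pd.DataFrame:
    """Two-group NB Wald test per retained position.

    Returns a DifferentialTable-shaped DataFrame indexed by concatenated
    position with columns rrna_id, pos, baseMean, log2FC, lfcSE, stat, pvalue,
    padj.  log2FC is condition B vs A (second vs first condition level).
    Non-converged positions get missing p and are excluded from BH.
    """
    idx = m.retained_indices()
    y = m.counts[:, idx].astype(float)
    x = m.condition_indicator()
    b0, b1, se1, conv = _irls_two_group(y, x, sf, np.asarray(dispersions))
    ln2 = np.log(2.0)
    log2fc = b1 / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = b1 / se1
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(conv & np.isfinite(stat), pvalue, np.nan)
    n_failed = int(np.sum(~(conv & np.isfinite(stat))))
    if n_failed:
        logger.info("%d position(s) did not converge; excluded from BH", n_failed)
    padj = np.full_like(pvalue, np.nan)
    ok = np.isfinite(pvalue)
    if ok.any():
        padj[ok] = multipletests(pvalue[ok], method="fdr_bh")[1]
    base_mean = (y / sf[:, None]).mean(axis=0)
    labels = [m.reference.from_concatenated(int(i)) for i in idx]
    df = pd.DataFrame(
        {
            "rrna_id": [l[0] for l in labels],
            "pos": [l[1] for l in labels],
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": se1 / ln2,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=pd.Index(idx, name="concat_index"),
    )
    return df


def ranking_scores(dt: pd.DataFrame, semantics: str = "floor") -> pd.DataFrame:
    """Attach the enrichment ranking score |log2FC| * max(-log10(padj), 5).

    Missing padj is treated as 1; padj is clamped at 1e-300 before the log so
    the score stays finite.  ``semantics="floor"`` is the printed formula (the
    multiplier never drops below 5, so weakly significant positions are
    ordered by |log2FC| alone); ``"cap"`` uses min() instead for users who
    prefer significance never to dominate the ranking.
    """
    if semantics not in ("floor", "cap"):
        raise ValueError(f"semantics must be 'floor' or 'cap', got {semantics!r}")
    padj = dt["padj"].fillna(1.0).clip(lower=_PADJ_CLAMP)
    neglog = -np.log10(padj)
    mult = np.maximum(neglog, 5.0) if semantics == "floor" else np.minimum(neglog, 5.0)
    out = dt.copy()
    out["rank_score"] = np.abs(dt["log2FC"]) * mult
    return out


def sample_similarity(
    m: PositionalCountMatrix, sf: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of log2(normalized count + 1) over retained positions.

    Returns (coordinates DataFrame indexed by sample with PC columns,
    explained-variance fractions).
    """
    if len(m.sample_ids) < 2:
        raise ValueError("PCA requires at least 2 samples")
    q = m.counts[:, m.retained] / sf[:, None]
    yl = np.log2(q + 1.0)
    yc = yl - yl.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    coords = u * s
    total = (yc**2).sum()
    explained = (s**2) / total if total > 0 else np.zeros_like(s)
    k = min(len(m.sample_ids), coords.shape[1])
    df = pd.DataFrame(
        coords[:, :k],
        index=pd.Index(m.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    df.insert(0, "condition", m.conditions)
    return df, explained[:k]


def plot_sample_similarity(
    coords: pd.DataFrame, explained: np.ndarray, path: str | Path
) -> None:
    """PC1/PC2 scatter of the sample-similarity PCA, coloured by condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, chunk in coords.groupby("condition"):
        ax.scatter(chunk["PC1"], chunk["PC2"], label=str(cond))
        for sid, row in chunk.iterrows():
            ax.annotate(str(sid), (row["PC1"], row["PC2"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel(f"PC1 ({explained[0]:.0%})")
    ax.set_ylabel(f"PC2 ({explained[1]:.0%})")
    ax.legend(frameon=False, fontsize=8, title="condition")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class DifferentialResult:
    """Bundle of the differential stage outputs."""

    table: pd.DataFrame
    size_factors: np.ndarray
    dispersions: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def read_differential(path: str | Path) -> pd.DataFrame:
    """Read back a differential TSV written by :meth:`DifferentialResult.to_tsv`."""
    return pd.read_csv(path, sep="\t", index_col="concat_index")


def run_differential(m: PositionalCountMatrix) -> DifferentialResult:
    """Size factors -> dispersions -> Wald test -> ranking scores."""
    sf = estimate_size_factors(m)
    disp = fit_dispersions(m, sf)
    table = ranking_scores(wald_test(m, sf, disp))
    return DifferentialResult(table=table, size_factors=sf, dispersions=disp)
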