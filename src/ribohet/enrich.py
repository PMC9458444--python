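"""Contact-set enrichment: do abundance changes concentrate at an RP's contacts?

Three tests per RP, on positions ranked by the differential score:

* a pre-ranked, GSEA-style weighted Kolmogorov-Smirnov test over the RP's
  contact set; its normalized enrichment score (NES) is reported as ES1 with
  a permutation p-value from random same-size position sets;
* ES2: the z-score of the RP's NES against the NES distribution of its
  circular-shift background sets, which corrects the set-size bias of ES1
  and supports a single candidate threshold (default 1, inclusive);
* an overrepresentation (hypergeometric) test of significantly changed
  positions (padj < 0.05 and |log2FC| > 0.5 by default) within the set.

Candidate RPs are called on ES2 alone; ES1 and ORA provide the triage axes.
No directionality of RP incorporation is inferred.
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

from .contacts import ContactSetCollection

__all__ = [
    "rank_positions",
    "enrichment_score",
    "normalized_es",
    "es2_zscore",
    "ora_test",
    "predict_rps",
    "EnrichmentReport",
]

logger = logging.getLogger(__name__)


def rank_positions(dt: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Order positions by descending rank_score; ties by ascending position.

    Returns (concatenated positions, scores), both in rank order.
    """
    if dt.empty:
        raise ValueError("differential table is empty")
    pos = dt.index.to_numpy(dtype=np.int64)
    score = dt["rank_score"].to_numpy(dtype=float)
    order = np.lexsort((pos, -score))
    return pos[order], score[order]


def _es_from_hit_ranks(scores_ranked: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Weighted-KS enrichment scores for rows of sorted hit-rank indices.

    ``hits``: (n_sets, k) matrix, each row ascending rank positions of a set's
    members within the ranked list.  Weight exponent 1: hit steps are
    proportional to |score|; all-zero sets fall back to uniform hit steps.
    """
    n = scores_ranked.size
    hits = np.atleast_2d(hits)
    k = hits.shape[1]
    if k == 0 or n == k:
        return np.full(hits.shape[0], np.nan)
    w = np.abs(scores_ranked)[hits]
    nr = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    uniform = np.tile(np.arange(1, k + 1, dtype=float) / k, (hits.shape[0], 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        phit = np.where(nr > 0, cum / np.where(nr > 0, nr, 1.0), uniform)
    steps = np.arange(k, dtype=float)
    miss_den = float(n - k)
    dev_after = phit - (hits + 1 - (steps + 1)) / miss_den
    phit_before = np.concatenate(
        [np.zeros((hits.shape[0], 1)), phit[:, :-1]], axis=1
    )
    dev_before = phit_before - (hits - steps) / miss_den
    max_dev = dev_after.max(axis=1)
    min_dev = dev_before.min(axis=1)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def enrichment_score(
    scores_ranked: np.ndarray, hit_ranks: np.ndarray
) -> float:
    """ES of one set given its (ascending) rank indices in the ranked list."""
    hit_ranks = np.sort(np.asarray(hit_ranks, dtype=np.int64))
    if hit_ranks.size == 0:
        return float("nan")
    return float(_es_from_hit_ranks(np.asarray(scores_ranked, float), hit_ranks[None, :])[0])


def _null_pool(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) random permutations of rank indices, one per permutation."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


class _NullCache:
    """Null ES distributions per set size, sharing one permutation pool."""

    def __init__(self, scores_ranked: np.ndarray, n_perm: int, rng: np.random.Generator):
        self.scores = np.asarray(scores_ranked, float)
        self.perms = _null_pool(self.scores.size, n_perm, rng)
        self._by_size: dict[int, np.ndarray] = {}

    def __call__(self, k: int) -> np.ndarray:
        if k not in self._by_size:
            hits = np.sort(self.perms[:, :k], axis=1)
            self._by_size[k] = _es_from_hit_ranks(self.scores, hits)
        return self._by_size[k]


def _nes_and_p(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """Sign-aware NES and permutation p with +1 smoothing."""
    if not np.isfinite(es):
        return float("nan"), float("nan")
    same = null_es >= 0 if es >= 0 else null_es < 0
    pool = np.abs(null_es[same])
    pool = pool[pool > 0]
    if pool.size == 0:
        warnings.warn("degenerate null: no same-sign enrichment scores", stacklevel=2)
        return float("nan"), float("nan")
    nes = es / pool.mean() if es >= 0 else -abs(es) / pool.mean()
    p = (1.0 + float(np.sum(pool >= abs(es)))) / (1.0 + pool.size)
    return float(nes), float(p)


def normalized_es(
    scores_ranked: np.ndarray,
    hit_ranks: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """NES and permutation p for one set against random same-size sets."""
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    hit_ranks = np.sort(np.asarray(hit_ranks, dtype=np.int64))
    es = enrichment_score(scores_ranked, hit_ranks)
    cache = _NullCache(scores_ranked, n_perm, np.random.default_rng(seed))
    return _nes_and_p(es, cache(hit_ranks.size))


def es2_zscore(nes_rp: float, nes_backgrounds: np.ndarray) -> float:
    """z-score of the RP's NES against its background NES distribution."""
    bg = np.asarray(nes_backgrounds, float)
    n_missing = int(np.sum(~np.isfinite(bg)))
    bg = bg[np.isfinite(bg)]
    if n_missing:
        logger.info("dropped %d missing background NES value(s)", n_missing)
    if bg.size < 2:
        raise ValueError("need at least 2 background NES values")
    sd = bg.std(ddof=1)
    if sd == 0:
        warnings.warn("background NES values are constant; ES2 undefined", stacklevel=2)
        return float("nan")
    return float((nes_rp - bg.mean()) / sd)


def ora_test(
    dt: pd.DataFrame,
    set_positions: np.ndarray,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> tuple[float, int, int, int, int]:
    """Upper-tail hypergeometric test of significant positions in a set.

    Universe = retained positions (rows of the differential table); the set is
    intersected with the universe.  Returns (p, overlap_k, set_size,
    universe_size, sig_size).
    """
    universe = dt.index.to_numpy(dtype=np.int64)
    if universe.size == 0:
        raise ValueError("empty universe")
    sig_mask = (dt["padj"].fillna(1.0) < padj_threshold) & (
        dt["log2FC"].abs() > lfc_threshold
    )
    sig = set(universe[sig_mask.to_numpy()])
    inset = np.intersect1d(np.asarray(set_positions, np.int64), universe)
    k = sum(1 for p in inset if p in sig)
    M, n_sig, n_set = universe.size, len(sig), inset.size
    p = float(stats.hypergeom.sf(k - 1, M, n_sig, n_set))
    return p, k, n_set, M, n_sig


@dataclass
class EnrichmentReport:
    """Per-RP enrichment results, sorted by ES2 descending."""

    table: pd.DataFrame
    es2_threshold: float
    n_perm: int
    seed: int

    def candidates(self) -> list[str]:
        return list(self.table.loc[self.table["candidate"], "rp_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot_scores(self, path: str | Path) -> None:
        """ES1-vs-ES2 triage scatter: top predictions sit top-right.

        Colour encodes ORA significance (BH-adjusted), the dashed line the
        ES2 candidate threshold.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.table.dropna(subset=["es1", "es2"])
        sig = t["ora_padj"].fillna(1.0) < 0.05
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(t.loc[~sig, "es1"], t.loc[~sig, "es2"], c="grey", label="ORA n.s.")
        ax.scatter(t.loc[sig, "es1"], t.loc[sig, "es2"], c="tab:blue",
                   label="ORA padj < 0.05")
        for _, row in t[t["candidate"]].iterrows():
            ax.annotate(row["rp_id"], (row["es1"], row["es2"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
        ax.axhline(self.es2_threshold, ls="--", c="k", lw=0.8)
        ax.set_xlabel("ES1 (NES of contact set)")
        ax.set_ylabel("ES2 (z vs backgrounds)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def predict_rps(
    dt: pd.DataFrame,
    collection: ContactSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    es2_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> EnrichmentReport:
    """Run all three enrichment tests for every RP and call candidates.

    Contact and background sets are intersected with the retained-position
    universe.  BH adjustment of the set-enrichment and ORA p-values runs
    across the RP sets only; background sets never enter multiple testing.
    Candidates satisfy ES2 >= ``es2_threshold`` (inclusive).
    """
    positions, scores = rank_positions(dt)
    n = positions.size
    rank_of = {int(p): r for r, p in enumerate(positions)}
    cache = _NullCache(scores, n_perm, np.random.default_rng(seed))

    def hit_ranks(pos_set: np.ndarray) -> np.ndarray:
        return np.sort(
            np.asarray(
                [rank_of[int(p)] for p in pos_set if int(p) in rank_of],
                dtype=np.int64,
            )
        )

    rows = []
    for rp in collection.rp_ids:
        hr = hit_ranks(collection.sets[rp])
        if hr.size == 0 or hr.size == n:
            logger.warning("contact set of %s has no usable universe overlap", rp)
            rows.append(
                dict(rp_id=rp, es=np.nan, es1=np.nan, es2=np.nan, gsea_p=np.nan,
                     ora_p=np.nan, overlap_k=0, set_size=0, universe_size=n,
                     sig_size=0)
            )
            continue
        es = float(_es_from_hit_ranks(scores, hr[None, :])[0])
        nes, gsea_p = _nes_and_p(es, cache(hr.size))
        bg_nes = []
        for bg in collection.backgrounds.get(rp, []):
            bhr = hit_ranks(bg)
            if bhr.size == 0 or bhr.size == n:
                bg_nes.append(np.nan)
                continue
            bes = float(_es_from_hit_ranks(scores, bhr[None, :])[0])
            bnes, _ = _nes_and_p(bes, cache(bhr.size))
            bg_nes.append(bnes)
        finite_bg = np.asarray(bg_nes, float)
        finite_bg = finite_bg[np.isfinite(finite_bg)]
        if np.isfinite(nes) and finite_bg.size >= 2 and finite_bg.std(ddof=1) > 0:
            es2 = es2_zscore(nes, finite_bg)
        else:
            es2 = np.nan
        ora_p, k, n_set, m_uni, n_sig = ora_test(
            dt, collection.sets[rp], padj_threshold, lfc_threshold
        )
        rows.append(
            dict(rp_id=rp, es=es, es1=nes, es2=es2, gsea_p=gsea_p, ora_p=ora_p,
                 overlap_k=k, set_size=n_set, universe_size=m_uni, sig_size=n_sig)
        )
    table = pd.DataFrame(rows)
    for col, adj in (("gsea_p", "gsea_padj"), ("ora_p", "ora_padj")):
        vals = table[col].to_numpy(float)
        out = np.full_like(vals, np.nan)
        ok = np.isfinite(vals)
        if ok.any():
            out[ok] = multipletests(vals[ok], method="fdr_bh")[1]
        table[adj] = out
    table["candidate"] = table["es2"] >= es2_threshold
    table = table.sort_values(
        "es2", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    table = table[
        ["rp_id", "es", "es1", "es2", "gsea_p", "gsea_padj", "ora_p", "ora_padj",
         "overlap_k", "set_size", "universe_size", "sig_size", "candidate"]
    ]
    return EnrichmentReport(
        table=table, es2_threshold=es2_threshold, n_perm=n_perm, seed=seed
    )
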