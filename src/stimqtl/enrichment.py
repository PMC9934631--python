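"""Enrichment statistics for responsive peaks and QTL peaks.

* motif enrichment: per-motif logistic regression of binding-site presence
  on peak class, adjusting for peak width and the fraction of conserved
  bases; Wald test on the class coefficient, BH across motifs.  Complete
  separation falls back to a Firth-penalized fit.
* interval overlap: one-sided exact binomial test of the query overlap rate
  against the background rate; differences between two enrichments by
  two-sided Fisher exact test.
* response-QTL positional bias: Wilcoxon rank-sum comparison of absolute
  variant-to-TSS distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "logistic_fit",
    "motif_glm",
    "select_top_peaks",
    "overlap_binomial",
    "enrichment_difference",
    "tss_distance_compare",
    "EnrichmentRecord",
]


@dataclass
class EnrichmentRecord:
    unit: str
    effect: float     # log-odds (motif GLM) or fold (overlap)
    p: float
    k: int = 0
    n: int = 0
    expected: float = float("nan")
    flag: str = ""


# ---------------------------------------------------------------------------
# logistic regression by IRLS (+ Firth fallback)

def logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-8, firth: bool = False,
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS logistic regression; returns (beta, se, converged).

    With ``firth=True`` the score is Firth-penalized
    (U* = X'(y - p + h(1/2 - p)) with h the hat-matrix diagonal), which
    keeps estimates finite under complete separation.
    """
    n, q = X.shape
    beta = np.zeros(q)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        H = XtW @ X
        if firth:
            # hat diagonal of the weighted design
            try:
                Hinv = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                break
            h = np.einsum("ij,jk,ik->i", X * w[:, None], Hinv, X)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-12)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(q, np.nan)
    return beta, se, converged


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else col - col.mean()


def motif_glm(motif_table: pd.DataFrame, labels: pd.Series,
              fdr: float = 0.1) -> pd.DataFrame:
    """Per-motif logistic regression: presence ~ class + width + conserved.

    ``motif_table`` is indexed by peak id with ``width`` and
    ``conserved_pct`` columns plus one 0/1 column per motif; ``labels`` is a
    boolean/0-1 Series over the same peaks (e.g. opened vs closed, response
    vs non-response).  Motifs with zero occurrences are skipped.  On
    non-convergence or separation the Firth fit is used and flagged.
    """
    peaks = motif_table.index
    lab = labels.loc[peaks].to_numpy(float)
    if len(np.unique(lab)) < 2:
        raise ValueError("need two peak classes")
    width = _standardize(motif_table["width"].to_numpy(float))
    cons = _standardize(motif_table["conserved_pct"].to_numpy(float))
    X = np.column_stack([np.ones(len(peaks)), lab, width, cons])
    motifs = [c for c in motif_table.columns
              if c not in ("width", "conserved_pct")]
    rows = []
    for m in motifs:
        y = motif_table[m].to_numpy(float)
        if y.sum() == 0 or y.sum() == len(y):
            continue
        beta, se, converged = logistic_fit(X, y)
        flag = ""
        if not converged or not np.isfinite(se[1]) or np.abs(beta[1]) > 15:
            beta, se, converged = logistic_fit(X, y, firth=True)
            flag = "firth"
            if not converged:
                logger.warning("motif %s: no convergence even with Firth "
                               "penalty; skipped", m)
                continue
        z = beta[1] / se[1] if se[1] > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"unit": m, "effect": beta[1], "se": se[1],
                     "p": max(p, np.finfo(float).tiny), "flag": flag})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr
    return out


def select_top_peaks(diff_table: pd.DataFrame, direction: str,
                     top_n: int = 2000, fdr: float = 0.1,
                     lfc_col: str = "lfc_shrunk") -> list[str]:
    """Top responsive peaks of one direction ranked by |shrunken LFC|.

    Restricted to peaks passing the responsiveness gate, then the
    ``top_n`` largest absolute fold changes (all available if fewer),
    balancing class sizes across conditions.
    """
    sub = diff_table[diff_table["direction"] == direction]
    sub = sub.reindex(sub[lfc_col].abs().sort_values(ascending=False).index)
    return sub["feature"].head(top_n).tolist()


# ---------------------------------------------------------------------------
# interval-overlap enrichment

def _overlap_flags(peaks: list[GenomicInterval],
                   annotations: list[GenomicInterval]) -> np.ndarray:
    """Any-bp overlap (half-open arithmetic) of each peak with the track."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in annotations:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        ms, me = [], []
        for s, e in spans:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    flags = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        if p.chrom not in merged:
            continue
        ms, me = merged[p.chrom]
        j = np.searchsorted(ms, p.end) - 1  # last interval starting < p.end
        flags[i] = j >= 0 and me[j] > p.start
    return flags


def overlap_binomial(query: list[GenomicInterval],
                     annotations: list[GenomicInterval],
                     background: list[GenomicInterval],
                     name: str = "") -> EnrichmentRecord:
    """One-sided binomial enrichment of query-peak overlaps vs background.

    k = query peaks touching >= 1 annotation interval; p0 = background
    overlap proportion; p = P[Bin(n, p0) >= k].
    """
    if not query:
        raise ValueError("empty query set")
    k = int(_overlap_flags(query, annotations).sum())
    n = len(query)
    bg = _overlap_flags(background, annotations)
    p0 = float(bg.mean()) if len(bg) else 0.0
    if p0 == 0.0:
        if k > 0:
            logger.warning("background overlap rate is zero with k=%d; "
                           "background unrepresentative", k)
            p = np.finfo(float).tiny
        else:
            p = 1.0
        fold = np.inf if k else np.nan
    else:
        p = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
        fold = (k / n) / p0
    return EnrichmentRecord(unit=name, effect=fold, p=p, k=k, n=n,
                            expected=n * p0)


def enrichment_difference(a: EnrichmentRecord,
                          b: EnrichmentRecord) -> float:
    """Two-sided Fisher exact p for a difference between two enrichments.

    Builds the 2x2 table (overlap yes/no x class A/B); empty margins give
    p = 1.
    """
    table = np.array([[a.k, a.n - a.k], [b.k, b.n - b.k]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# TSS distance comparison

def tss_distance_compare(r_distances: np.ndarray,
                         nonr_distances: np.ndarray) -> dict:
    """Compare |variant - TSS| distributions of response vs non-response QTLs.

    Returns group medians and a two-sided Wilcoxon rank-sum p (omitted when
    either group has fewer than 3 members).
    """
    r = np.abs(np.asarray(r_distances, float))
    nr = np.abs(np.asarray(nonr_distances, float))
    out = {
        "n_response": len(r), "n_other": len(nr),
        "median_response": float(np.median(r)) if len(r) else np.nan,
        "median_other": float(np.median(nr)) if len(nr) else np.nan,
    }
    if len(r) >= 3 and len(nr) >= 3:
        if np.array_equal(np.sort(r), np.sort(nr)):
            out["p"] = 1.0
        else:
            out["p"] = float(stats.mannwhitneyu(
                r, nr, alternative="two-sided").pvalue)
    return out
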