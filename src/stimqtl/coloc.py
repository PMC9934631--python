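"""GWAS-QTL sharing via a three-step colocalization procedure.

1. Candidate extraction: genome-wide-significant GWAS SNPs (p < 5e-8)
   within 1 Mb of a QTL index SNP.
2. LD filtering: keep pairs whose index SNPs are in LD r² > 0.6, or where
   any genome-wide-significant SNP at the locus is in LD r² > 0.6 with the
   QTL index (allows undefined secondary GWAS signals).
3. Colocalization evidence, two routes, reported if either fires:
   (a) approximate conditional analysis - conditioning the GWAS statistics
       on the QTL index SNP with an external LD reference abolishes the
       signal (all conditional p above a floor);
   (b) single-causal-variant colocalization - per-study Wakefield
       approximate Bayes factors give each SNP a posterior causal
       probability; the SNP-level colocalization posterior probability
       (CLPP) is the product across studies.  Verdict: CLPP > 1% and the
       CLPP SNP in LD r² > 0.8 with a genome-wide-significant SNP.

A salvage pass re-tests features that colocalized in one condition and
narrowly missed the QTL FDR gate in another (best nominal p < 1e-6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import _impute_mean
from .types import GenotypeMatrix, GwasSumstats

logger = logging.getLogger(__name__)

__all__ = [
    "ColocCandidate",
    "ColocResult",
    "find_candidates",
    "approx_conditional",
    "clpp",
    "colocalize",
    "salvage_condition_specific",
]

GW_SIG = 5e-8


@dataclass
class ColocCandidate:
    feature: str
    qtl_index: str
    gwas_index: str
    distance: int
    index_r2: float
    best_gw_r2: float


@dataclass
class ColocResult:
    candidate: ColocCandidate
    clpp_max: float = np.nan
    clpp_snp: str = ""
    r2_to_gw_snp: float = np.nan
    conditional_pass: bool = False
    verdict: str = "not_colocalized"
    salvage: bool = False
    reason: str = ""


def _r2_matrix(D: np.ndarray) -> np.ndarray:
    Dc = D - D.mean(axis=1, keepdims=True)
    sd = np.sqrt((Dc ** 2).sum(axis=1))
    sd = np.where(sd > 0, sd, 1.0)
    R = (Dc @ Dc.T) / np.outer(sd, sd)
    return R ** 2


def find_candidates(gwas: GwasSumstats, qtl_indexes: pd.DataFrame,
                    gm: GenotypeMatrix, max_dist: int = 1_000_000,
                    r2_min: float = 0.6) -> list[ColocCandidate]:
    """Steps 1-2: positional extraction plus LD-overlap filtering.

    ``qtl_indexes`` needs columns feature, variant.  The GWAS index at a
    locus is its most significant genome-wide SNP within ``max_dist``
    (inclusive) of the QTL index.
    """
    gt = gwas.table
    shared_ids = set(gt["id"]) & set(gm.variants["id"])
    if not shared_ids:
        raise ValueError("no shared variants between GWAS and QTL panels")
    gw = gt[(gt["p"] < GW_SIG) & gt["id"].isin(shared_ids)]
    if len(gw) == 0:
        return []
    var_row = {v: i for i, v in enumerate(gm.variants["id"])}
    pos_of = dict(zip(gm.variants["id"], gm.variants["pos"]))
    D = _impute_mean(gm.dosage)
    out = []
    for rec in qtl_indexes.itertuples():
        if rec.variant not in var_row:
            continue
        qpos = pos_of[rec.variant]
        near = gw[(gw["pos"] - qpos).abs() <= max_dist]
        if len(near) == 0:
            continue
        qvec = D[var_row[rec.variant]]
        r2s = np.array([
            _pair_r2(D[var_row[v]], qvec) for v in near["id"]])
        gwas_index = near.loc[near["p"].idxmin(), "id"]
        index_r2 = float(r2s[near["id"].tolist().index(gwas_index)])
        best_gw_r2 = float(r2s.max())
        if max(index_r2, best_gw_r2) > r2_min:
            out.append(ColocCandidate(
                feature=rec.feature, qtl_index=rec.variant,
                gwas_index=str(gwas_index),
                distance=int(abs(pos_of[gwas_index] - qpos)),
                index_r2=index_r2, best_gw_r2=best_gw_r2))
    return out


def _pair_r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def approx_conditional(sumstats: pd.DataFrame, ref_dosage: np.ndarray,
                       ref_freq: np.ndarray, conditioning: list[int],
                       freq_diff_max: float = 0.2,
                       collinearity_r2: float = 0.9) -> pd.DataFrame:
    """COJO-style conditional betas/se/p from marginal statistics + LD.

    ``sumstats`` rows (columns beta, se, freq, n, id) align with the rows of
    ``ref_dosage``; ``conditioning`` indexes rows to condition on.  With
    D_j = 2 f_j (1-f_j) n_j and B the LD-scaled cross-product, the
    conditional effect of target t is b_t - B_tC B_CC^-1 b_C with deflated
    variance.  Variants whose sumstats frequency differs from the reference
    by more than ``freq_diff_max`` are excluded; targets with r² above the
    collinearity threshold to a conditioning SNP are masked (NaN).
    """
    ss = sumstats.reset_index(drop=True)
    m = len(ss)
    if ref_dosage.shape[0] != m:
        raise ValueError("reference dosage rows must align with sumstats")
    f = ss["freq"].to_numpy(float)
    n = ss["n"].to_numpy(float)
    b = ss["beta"].to_numpy(float)
    se = ss["se"].to_numpy(float)
    out = ss.copy()
    out["beta_cond"], out["se_cond"], out["p_cond"] = b.copy(), se.copy(), \
        np.clip(2 * stats.norm.sf(np.abs(b / se)), np.finfo(float).tiny, 1.0)
    out["masked"] = False
    out["excluded"] = np.abs(f - ref_freq) > freq_diff_max
    if not conditioning:
        return out

    R = np.corrcoef(_impute_mean(ref_dosage))
    R = np.atleast_2d(np.nan_to_num(R))
    Dj = 2.0 * f * (1.0 - f) * n
    sqrtD = np.sqrt(Dj)
    B = R * np.outer(sqrtD, sqrtD)
    C = list(conditioning)
    BCC = B[np.ix_(C, C)]
    try:
        BCC_inv = np.linalg.inv(BCC)
    except np.linalg.LinAlgError:
        bad = ss["id"].iloc[C].tolist()
        raise ValueError(f"singular conditioning matrix for variants {bad}")
    bC = b[C]
    # per-SNP residual variance implied by the marginal fit
    sigma2 = np.median(Dj * se ** 2)
    for t in range(m):
        if t in C or out.at[t, "excluded"]:
            continue
        r2_to_cond = max(R[t, c] ** 2 for c in C)
        if r2_to_cond > collinearity_r2:
            out.at[t, "masked"] = True
            out.at[t, "beta_cond"] = np.nan
            out.at[t, "se_cond"] = np.nan
            out.at[t, "p_cond"] = np.nan
            continue
        BtC = B[t, C]
        bcond = b[t] - BtC @ BCC_inv @ bC
        denom = B[t, t] - BtC @ BCC_inv @ BtC
        if denom <= 0:
            out.at[t, "masked"] = True
            out.at[t, "beta_cond"] = np.nan
            out.at[t, "se_cond"] = np.nan
            out.at[t, "p_cond"] = np.nan
            continue
        secnd = np.sqrt(sigma2 / denom)
        out.at[t, "beta_cond"] = bcond
        out.at[t, "se_cond"] = secnd
        out.at[t, "p_cond"] = max(2 * stats.norm.sf(abs(bcond / secnd)),
                                  np.finfo(float).tiny)
    for c in C:
        out.at[c, "beta_cond"] = np.nan
        out.at[c, "se_cond"] = np.nan
        out.at[c, "p_cond"] = np.nan
    return out


def _abf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield approximate Bayes factor under a N(0, prior_sd²) effect."""
    W = prior_sd ** 2
    z2 = (beta / se) ** 2
    log_abf = 0.5 * np.log(se ** 2 / (se ** 2 + W)) \
        + z2 * W / (2 * (se ** 2 + W))
    log_abf -= log_abf.max()
    return np.exp(log_abf)


def clpp(gwas_locus: pd.DataFrame, qtl_locus: pd.DataFrame,
         ref_dosage_by_id: dict[str, np.ndarray],
         prior_sd: float = 0.15, p_include: float = 0.05,
         ) -> tuple[float, str, float]:
    """Single-causal-variant CLPP over jointly nominal SNPs.

    Both frames need id/beta/se/p columns.  SNPs at p < 0.05 in both
    studies enter; each study's ABFs are normalized to causal posteriors
    over that set and CLPP_j is their product.  Returns (clpp_max, snp,
    r² of that SNP to the best-linked genome-wide-significant GWAS SNP).
    """
    g = gwas_locus.set_index("id")
    q = qtl_locus.set_index("id")
    joint = [v for v in g.index if v in q.index
             and g.at[v, "p"] < p_include and q.at[v, "p"] < p_include]
    if not joint:
        return np.nan, "", np.nan
    pg = _abf(g.loc[joint, "beta"].to_numpy(),
              g.loc[joint, "se"].to_numpy(), prior_sd)
    pq = _abf(q.loc[joint, "beta"].to_numpy(),
              q.loc[joint, "se"].to_numpy(), prior_sd)
    pg /= pg.sum()
    pq /= pq.sum()
    cl = pg * pq
    best = int(np.argmax(cl))
    snp = joint[best]
    gw = g[g["p"] < GW_SIG]
    r2 = 0.0
    if len(gw) and snp in ref_dosage_by_id:
        for v in gw.index:
            if v in ref_dosage_by_id:
                r2 = max(r2, _pair_r2(ref_dosage_by_id[snp],
                                      ref_dosage_by_id[v]))
    return float(cl[best]), str(snp), float(r2)


def colocalize(candidate: ColocCandidate, gwas: GwasSumstats,
               qtl_locus: pd.DataFrame, gm: GenotypeMatrix,
               window: int = 1_000_000, prior_sd: float = 0.15,
               cond_p_floor: float = 1e-4, clpp_min: float = 0.01,
               r2_gw_min: float = 0.8) -> ColocResult:
    """Both colocalization routes for one candidate locus; either may fire."""
    var_row = {v: i for i, v in enumerate(gm.variants["id"])}
    pos_of = dict(zip(gm.variants["id"], gm.variants["pos"]))
    center = pos_of[candidate.qtl_index]
    gt = gwas.table
    locus = gt[(gt["pos"] - center).abs() <= window].reset_index(drop=True)
    locus = locus[locus["id"].isin(var_row)].reset_index(drop=True)
    D = _impute_mean(gm.dosage)
    rows = [var_row[v] for v in locus["id"]]
    ref = D[rows]
    ref_freq = ref.mean(axis=1) / 2.0

    res = ColocResult(candidate=candidate)

    # route 1: approximate conditional on the QTL index
    if candidate.qtl_index in set(locus["id"]):
        cond_idx = [locus["id"].tolist().index(candidate.qtl_index)]
        cond = approx_conditional(locus, ref, ref_freq, cond_idx)
        gw_rows = cond[(cond["p"] < GW_SIG) & (~cond["masked"])
                       & (~cond["excluded"])]
        pc = gw_rows["p_cond"].dropna()
        if len(pc):
            res.conditional_pass = bool((pc > cond_p_floor).all())
        else:
            # every genome-wide SNP collinear with (explained by) the index
            res.conditional_pass = bool(
                (cond["p"] < GW_SIG).any())

    # route 2: CLPP
    ref_by_id = {v: D[var_row[v]] for v in locus["id"]}
    cl, snp, r2 = clpp(locus, qtl_locus, ref_by_id, prior_sd=prior_sd)
    if np.isnan(cl):
        res.reason = "no jointly nominal SNPs"
    res.clpp_max, res.clpp_snp, res.r2_to_gw_snp = cl, snp, r2
    clpp_pass = (not np.isnan(cl)) and cl > clpp_min and r2 > r2_gw_min
    res.verdict = ("colocalized"
                   if clpp_pass or res.conditional_pass
                   else "not_colocalized")
    return res


def salvage_condition_specific(results_by_condition: dict[str, ColocResult],
                               best_nominal_p: dict[str, float],
                               retest, threshold: float = 1e-6,
                               ) -> dict[str, ColocResult]:
    """Re-test near-miss conditions for a feature colocalized elsewhere.

    ``results_by_condition`` holds the per-condition verdicts for one
    feature (conditions missing a significant QTL are absent);
    ``best_nominal_p`` gives the feature's best nominal QTL p per condition;
    ``retest(condition)`` runs the CLPP route and returns a ColocResult.
    Conditions whose best p < 1e-6 are re-tested and flagged salvage.
    """
    colocalized = any(r.verdict == "colocalized"
                      for r in results_by_condition.values())
    out: dict[str, ColocResult] = {}
    if not colocalized:
        return out
    for cond, p in best_nominal_p.items():
        if cond in results_by_condition:
            continue
        if p < threshold:
            res = retest(cond)
            res.salvage = True
            out[cond] = res
    return out
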