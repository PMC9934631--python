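"""Genotype x condition interaction tests and enhancer-priming calls.

Response QTLs are detected by a likelihood-ratio test between nested linear
mixed models with a per-donor random intercept:

    value ~ SNP + condition + condition:SNP + covariates + (1 | donor)

fitted by maximum likelihood.  For a fixed variance ratio
``lambda = sigma_donor^2 / sigma_resid^2`` the GLS solution is closed-form
after per-donor whitening, so the fit reduces to a bounded 1-D search on
``log lambda``.  The LRT statistic (full vs. no-interaction model) is
compared to chi-square with 1 df.

Priming: a caPeak and an eGene within 1 Mb are "linked" when at least one
significant caSNP and one significant eSNP are in LD r² >= 0.8.  A linked
pair is ``primed`` when the caPeak is genetically regulated in both vehicle
and stimulated conditions but the eGene only under stimulation;
``stimulus_specific`` when both are stimulation-only; ``shared`` when both
are significant in both conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix
from .qtl import QTLResult, _impute_mean
from .types import GenotypeMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "fit_interaction_lmm",
    "interaction_scan",
    "call_response_qtls",
    "classify_sharing",
    "link_and_classify_priming",
    "PrimingCall",
]


# ---------------------------------------------------------------------------
# random-intercept LMM by profiled ML

def _group_whiten(M: np.ndarray, groups: np.ndarray, lam: float,
                  group_sizes: np.ndarray) -> np.ndarray:
    """Multiply rows by (I + lam * J_group)^(-1/2) blockwise.

    For a group of size n_d the transform is
    x -> x + ((1 + n_d lam)^(-1/2) - 1) * group_mean(x).
    """
    shrink = 1.0 / np.sqrt(1.0 + group_sizes * lam) - 1.0
    n_groups = len(group_sizes)
    sums = np.zeros((n_groups,) + M.shape[1:])
    np.add.at(sums, groups, M)
    means = sums / group_sizes.reshape((-1,) + (1,) * (M.ndim - 1))
    return M + shrink.reshape((-1,) + (1,) * (M.ndim - 1))[groups] * means[groups]


def _ml_loglik(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
               group_sizes: np.ndarray, log_lam: float,
               ) -> tuple[float, np.ndarray, float]:
    lam = float(np.exp(log_lam))
    Xw = _group_whiten(X, groups, lam, group_sizes)
    yw = _group_whiten(y, groups, lam, group_sizes)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = len(y)
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    logdet = float(np.sum(np.log1p(group_sizes * lam)))
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2


def _fit_ml(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
            group_sizes: np.ndarray,
            bounds: tuple[float, float] = (-10.0, 10.0),
            ) -> tuple[float, np.ndarray, float]:
    def neg(log_lam: float) -> float:
        return -_ml_loglik(X, y, groups, group_sizes, log_lam)[0]

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    ll, beta, _ = _ml_loglik(X, y, groups, group_sizes, float(res.x))
    return ll, beta, float(res.x)


def fit_interaction_lmm(y: np.ndarray, dosage: np.ndarray,
                        condition: np.ndarray, donor: np.ndarray,
                        covariates: np.ndarray | None = None,
                        random_effect: bool = True,
                        bartlett: bool = True) -> dict:
    """LRT for a genotype x condition interaction with donor random intercept.

    ``condition`` is 0 (vehicle) / 1 (stimulated) per sample; ``donor`` is a
    per-sample group label; ``dosage`` is the donor's allele dosage repeated
    per sample.  With ``random_effect=False`` the model drops the random
    intercept (plain OLS LRT), matching engines that ignore the pairing.

    ``bartlett`` applies the standard small-sample correction for Gaussian
    likelihood-ratio statistics, dividing the LRT by 1 + (p + 1)/n (p fixed
    parameters of the full model): the uncorrected chi-square reference is
    analytically liberal at a few hundred samples.
    """
    y = np.asarray(y, float)
    g = np.asarray(dosage, float)
    c = np.asarray(condition, float)
    n = len(y)
    for arm in (0.0, 1.0):
        if np.std(g[c == arm]) == 0:
            return {"skip_reason": f"constant genotype in condition {arm:.0f}",
                    "p_interaction": np.nan}
    cols = [np.ones(n), g, c, g * c]
    if covariates is not None and covariates.size:
        cols.append(np.asarray(covariates, float))
    X_full = np.column_stack(cols)
    X_red = np.delete(X_full, 3, axis=1)

    codes, _ = pd.factorize(donor)
    sizes = np.bincount(codes).astype(float)

    if random_effect:
        ll_full, beta, loglam = _fit_ml(X_full, y, codes, sizes)
        ll_red, _, _ = _fit_ml(X_red, y, codes, sizes)
        converged = True
    else:
        ll_full, beta, _ = _ml_loglik(X_full, y, codes, sizes, -np.inf)
        ll_red, _, _ = _ml_loglik(X_red, y, codes, sizes, -np.inf)
        loglam = -np.inf
        converged = True
    lrt = 2.0 * (ll_full - ll_red)
    if lrt < 0:
        if lrt < -1e-6:
            logger.debug("negative LRT %.3g clipped to 0", lrt)
        lrt = 0.0
    if bartlett:
        lrt = lrt / (1.0 + (X_full.shape[1] + 1.0) / n)
    p = float(stats.chi2.sf(lrt, df=1))
    return {
        "beta_vehicle": float(beta[1]),
        "beta_interaction": float(beta[3]),
        "beta_stim": float(beta[1] + beta[3]),
        "lrt_chi2": float(lrt),
        "p_interaction": max(p, np.finfo(float).tiny),
        "log_lambda": float(loglam),
        "converged": converged,
        "skip_reason": "",
    }


def interaction_scan(norm: NormalizedMatrix, gm: GenotypeMatrix,
                     sheet: SampleSheet,
                     index_qtls: pd.DataFrame,
                     condition_pair: tuple[str, str],
                     covariates: pd.DataFrame | None = None,
                     random_effect: bool = True) -> pd.DataFrame:
    """Interaction LMM for every (feature, variant) index QTL row.

    ``condition_pair`` is (stimulated, vehicle); only samples from the two
    conditions enter, and unpaired donors are retained (the random intercept
    absorbs the imbalance).
    """
    stim, veh = condition_pair
    t = sheet.table
    use = t[t["condition"].isin([stim, veh])]
    use = use[use["sample_id"].isin(set(norm.samples))]
    use = use[use["donor_id"].isin(set(gm.samples))]
    paired = use.groupby("donor_id")["condition"].nunique()
    if (paired == 2).sum() < 4:
        raise ValueError("need >= 4 donors observed in both conditions")
    samples = use["sample_id"].tolist()
    cvec = (use["condition"] == stim).to_numpy(float)
    donors = use["donor_id"].to_numpy()
    sub = norm.subset_samples(samples)
    donor_col = {d: i for i, d in enumerate(gm.samples)}
    dcols = np.array([donor_col[d] for d in donors])
    feat_row = {f: i for i, f in enumerate(sub.features)}
    var_row = {v: i for i, v in enumerate(gm.variants["id"])}
    cov = None
    if covariates is not None:
        cov = covariates.loc[samples].to_numpy(float)
    rows = []
    D = _impute_mean(gm.dosage)
    for rec in index_qtls.itertuples():
        if rec.feature not in feat_row or rec.variant not in var_row:
            continue
        y = sub.values[feat_row[rec.feature]]
        g = D[var_row[rec.variant]][dcols]
        fit = fit_interaction_lmm(y, g, cvec, donors, covariates=cov,
                                  random_effect=random_effect)
        fit.update(feature=rec.feature, variant=rec.variant)
        rows.append(fit)
    out = pd.DataFrame(rows)
    if len(out):
        out = out[out["skip_reason"] == ""].reset_index(drop=True)
    return out


def call_response_qtls(records: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """BH over tested index QTLs; ``is_response`` = FDR < threshold."""
    out = records.copy()
    if len(out) == 0:
        out["fdr"] = pd.Series(dtype=float)
        out["is_response"] = pd.Series(dtype=bool)
        return out
    out["fdr"] = multipletests(out["p_interaction"], method="fdr_bh")[1]
    out["is_response"] = out["fdr"] < fdr
    return out


# ---------------------------------------------------------------------------
# sharing across conditions

def classify_sharing(sig_sets: dict[str, set[str]],
                     reference: str) -> tuple[pd.DataFrame, float]:
    """Condition-membership table and the stimulated-only increment.

    The increment statistic is (# features significant in at least one
    stimulated condition but not in the reference) / (# significant in the
    reference) x 100%.
    """
    if reference not in sig_sets:
        raise ValueError(f"reference condition {reference!r} missing")
    all_feats = sorted(set().union(*sig_sets.values()))
    conds = list(sig_sets)
    rows = [{"feature": f, **{c: f in sig_sets[c] for c in conds}}
            for f in all_feats]
    table = pd.DataFrame(rows, columns=["feature"] + conds)
    stim_only = [f for f in all_feats
                 if f not in sig_sets[reference]]
    n_ref = len(sig_sets[reference])
    increment = 100.0 * len(stim_only) / n_ref if n_ref else np.nan
    return table, increment


# ---------------------------------------------------------------------------
# priming

@dataclass
class PrimingCall:
    peak: str
    gene: str
    condition_pair: tuple[str, str]
    ca_snp: str
    e_snp: str
    r2: float
    label: str  # primed | stimulus_specific | shared | unlinked


def _sig_snps(result: QTLResult, feature: str,
              indexes_only: bool = False) -> pd.DataFrame:
    src = result.signals if indexes_only else result.significant_pairs
    if len(src) == 0:
        return src
    return src[src["feature"] == feature]


def link_and_classify_priming(ca: dict[str, QTLResult],
                              eq: dict[str, QTLResult],
                              gm: GenotypeMatrix,
                              peaks: pd.DataFrame, genes: pd.DataFrame,
                              condition_pair: tuple[str, str],
                              r2_min: float = 0.8,
                              max_dist: int = 1_000_000,
                              indexes_only: bool = False,
                              ) -> list[PrimingCall]:
    """Classify caPeak-eGene pairs as primed / stimulus-specific / shared.

    ``ca`` and ``eq`` map condition -> QTLResult for the accessibility and
    expression assays; ``condition_pair`` is (stimulated, vehicle).
    Candidate pairs have the peak within ``max_dist`` of the gene TSS; the
    LD link requires one significant SNP from each assay with r² >= 0.8
    (all variants below the feature's nominal threshold by default, index
    SNPs only with ``indexes_only``).
    """
    stim, veh = condition_pair
    ca_sig = {c: ca[c].significant_features for c in (stim, veh)}
    eq_sig = {c: eq[c].significant_features for c in (stim, veh)}
    ca_any = ca_sig[stim] | ca_sig[veh]
    eq_any = eq_sig[stim] | eq_sig[veh]
    if not ca_any or not eq_any:
        return []

    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"],
                            genes["start"] + 1)
    D = _impute_mean(gm.dosage)
    var_row = {v: i for i, v in enumerate(gm.variants["id"])}

    calls: list[PrimingCall] = []
    psub = peaks[peaks["feature_id"].isin(ca_any)]
    gsub = genes[genes["gene_id"].isin(eq_any)]
    for p in psub.itertuples():
        for g in gsub.itertuples():
            if g.chrom != p.chrom:
                continue
            if p.start < g.tss <= p.end:
                dist = 0
            else:
                dist = min(abs(g.tss - p.end), abs(g.tss - (p.start + 1)))
            if dist > max_dist:
                continue
            ca_parts = [s for c in (stim, veh)
                        if len(s := _sig_snps(ca[c], p.feature_id,
                                              indexes_only))]
            e_parts = [s for c in (stim, veh)
                       if len(s := _sig_snps(eq[c], g.gene_id,
                                             indexes_only))]
            if not ca_parts or not e_parts:
                continue
            ca_snps = pd.concat(ca_parts, ignore_index=True)
            e_snps = pd.concat(e_parts, ignore_index=True)
            ca_ids = ca_snps["variant"].unique()
            e_ids = e_snps["variant"].unique()
            Ca = D[[var_row[v] for v in ca_ids]]
            Ea = D[[var_row[v] for v in e_ids]]
            Ca_c = Ca - Ca.mean(axis=1, keepdims=True)
            Ea_c = Ea - Ea.mean(axis=1, keepdims=True)
            sc = np.sqrt((Ca_c ** 2).sum(axis=1))
            se_ = np.sqrt((Ea_c ** 2).sum(axis=1))
            ok = np.outer(sc > 0, se_ > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                R = (Ca_c @ Ea_c.T) / np.outer(np.where(sc > 0, sc, 1),
                                               np.where(se_ > 0, se_, 1))
            R2 = np.where(ok, R ** 2, 0.0)
            best = np.unravel_index(np.argmax(R2), R2.shape)
            best_r2 = float(R2[best])
            ca_best, e_best = str(ca_ids[best[0]]), str(e_ids[best[1]])

            ca_both = (p.feature_id in ca_sig[stim]
                       and p.feature_id in ca_sig[veh])
            ca_stim_only = (p.feature_id in ca_sig[stim]
                            and p.feature_id not in ca_sig[veh])
            e_both = g.gene_id in eq_sig[stim] and g.gene_id in eq_sig[veh]
            e_stim_only = (g.gene_id in eq_sig[stim]
                           and g.gene_id not in eq_sig[veh])
            if best_r2 < r2_min:
                label = "unlinked"
            elif ca_both and e_stim_only:
                label = "primed"
            elif ca_stim_only and e_stim_only:
                label = "stimulus_specific"
            elif ca_both and e_both:
                label = "shared"
            else:
                label = "unlinked"
            calls.append(PrimingCall(p.feature_id, g.gene_id,
                                     (stim, veh), ca_best, e_best,
                                     best_r2, label))
    return calls
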