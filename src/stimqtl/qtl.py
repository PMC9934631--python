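"""Per-condition cis QTL mapping with hierarchical multiple-testing control.

The scan regresses PC-residualized normalized counts on allele dosage for
every feature-variant pair inside the cis window (peak ±25 kb for
accessibility, gene body ±1 Mb for expression; boundaries inclusive).
Variants are pre-filtered on MAF >= 1%, Hardy-Weinberg exact p >= 1e-6 and
at least two minor-allele carriers, all computed on the condition's sample
subset.

Multiple testing is corrected hierarchically: (1) nominal p-values within
each feature are adjusted by the effective number of independent tests
(eigenvalue decomposition of the cis genotype correlation matrix, eigenMT
style) or by permutation of the phenotype with a Beta-distribution tail
approximation; (2) Benjamini-Hochberg across features on the locally
adjusted p-values; (3) the global cutoff is back-transformed into a
per-feature nominal threshold so every variant, not only the minimum, can
be flagged.  Secondary signals come from iterative LD pruning (r² < 0.2) or
conditional re-scans with the index dosage as covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix, hwe_exact_test
from .types import GenotypeMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "variant_filter_mask",
    "expressed_features",
    "build_cis_pairs",
    "assoc_scan",
    "eigenmt_local",
    "permutation_local",
    "global_correct",
    "independent_signals",
    "map_qtls",
    "QTLResult",
]


# ---------------------------------------------------------------------------
# filters and cis pairing

def variant_filter_mask(gm: GenotypeMatrix, min_maf: float = 0.01,
                        hwe_p_min: float = 1e-6, min_carriers: int = 2,
                        min_impute_r2: float | None = 0.3,
                        r2_key: str = "R2") -> np.ndarray:
    """Boolean mask of variants passing the QTL-testing filters.

    Computed on the matrix's current sample subset.  The imputation-quality
    filter applies only to variants carrying the INFO key (directly
    genotyped / simulated variants have none).
    """
    maf = gm.maf()
    mask = maf >= min_maf
    hard = np.round(np.nan_to_num(gm.dosage, nan=-9)).astype(int)
    for i in np.flatnonzero(mask):
        row = hard[i][hard[i] >= 0]
        counts = [(row == g).sum() for g in (0, 1, 2)]
        minor_is_alt = counts[2] <= counts[0]
        carriers = counts[1] + (counts[2] if minor_is_alt else counts[0])
        if carriers < min_carriers:
            mask[i] = False
            continue
        if hwe_exact_test(*counts) < hwe_p_min:
            mask[i] = False
    if min_impute_r2 is not None and "info" in gm.variants.columns:
        for i in np.flatnonzero(mask):
            info = gm.variants["info"].iloc[i]
            if isinstance(info, dict) and r2_key in info:
                if info[r2_key] < min_impute_r2:
                    mask[i] = False
    return mask


def expressed_features(counts: np.ndarray, factors: np.ndarray,
                       min_count: float = 10.0,
                       min_frac: float = 0.01) -> np.ndarray:
    """Features where >= ``min_frac`` of samples have >= ``min_count``
    normalized (size-factor-scaled) counts."""
    norm = counts / factors[None, :]
    frac = (norm >= min_count).mean(axis=1)
    return frac >= min_frac


def build_cis_pairs(features: pd.DataFrame, gm: GenotypeMatrix,
                    window: int, variant_mask: np.ndarray | None = None,
                    ) -> pd.DataFrame:
    """Feature-variant cis pairs.

    ``features`` needs columns feature_id, chrom, start, end (0-based
    half-open) and optionally strand.  A variant at 1-based ``pos`` pairs
    with a feature iff ``start - window < pos <= end + window`` (window
    boundaries inclusive on both sides).  Distance is signed relative to the
    strand-aware TSS anchor (start+1 for +/unstranded, end for -).
    """
    if variant_mask is None:
        variant_mask = np.ones(gm.n_variants, dtype=bool)
    rows = []
    vt = gm.variants
    for chrom, vsub in vt.groupby("chrom", sort=False):
        pos = vsub["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        vrows = vsub.index.to_numpy()[order]
        fsub = features[features["chrom"] == chrom]
        for f in fsub.itertuples():
            lo, hi = f.start - window, f.end + window
            i0 = np.searchsorted(pos_sorted, lo, side="right")
            i1 = np.searchsorted(pos_sorted, hi, side="right")
            sel = vrows[i0:i1]
            sel = sel[variant_mask[sel]]
            if len(sel) == 0:
                continue
            strand = getattr(f, "strand", ".")
            tss = f.end if strand == "-" else f.start + 1
            for r in sel:
                rows.append((f.feature_id, int(r), vt["id"].iloc[r],
                             int(vt["pos"].iloc[r]) - tss))
    return pd.DataFrame(rows, columns=["feature", "variant_row", "variant",
                                       "tss_distance"])


# ---------------------------------------------------------------------------
# association scan

def _impute_mean(G: np.ndarray) -> np.ndarray:
    G = G.copy()
    nan = np.isnan(G)
    if nan.any():
        means = np.where(np.all(nan, axis=1), 0.0, np.nanmean(G, axis=1))
        G[nan] = np.broadcast_to(means[:, None], G.shape)[nan]
    return G


def _residualize(M: np.ndarray, Z: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Project rows of M off the column space of [1, Z]; returns (resid, q)."""
    n = M.shape[-1]
    if Z is None or Z.shape[1] == 0:
        return M - M.mean(axis=-1, keepdims=True), 1
    X = np.column_stack([np.ones(n), Z])
    Q, _ = np.linalg.qr(X)
    return M - (M @ Q) @ Q.T, X.shape[1]


def assoc_scan(norm: NormalizedMatrix, gm: GenotypeMatrix,
               pairs: pd.DataFrame,
               covariates: np.ndarray | None = None) -> pd.DataFrame:
    """OLS of phenotype on dosage for every cis pair.

    Phenotypes are assumed pre-residualized; additional fixed covariates
    (samples x q) may be supplied and are projected out of both phenotype
    and genotype (Frisch-Waugh), with degrees of freedom adjusted.
    Constant-dosage pairs are skipped with a reason column.
    """
    feat_row = {f: i for i, f in enumerate(norm.features)}
    sample_cols = [gm.samples.index(s) for s in norm.samples]
    D = _impute_mean(gm.dosage[:, sample_cols])
    n = len(norm.samples)
    Y, q = _residualize(norm.values, covariates)
    G, _ = _residualize(D, covariates)
    df = n - 1 - q
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    out = []
    for feature, sub in pairs.groupby("feature", sort=False):
        if feature not in feat_row:
            continue
        y = Y[feat_row[feature]]
        rows = sub["variant_row"].to_numpy()
        g = G[rows]
        ssx = (g ** 2).sum(axis=1)
        ok = ssx > 1e-12
        beta = np.where(ok, g @ y / np.where(ok, ssx, 1.0), np.nan)
        rss = np.maximum(y @ y - beta ** 2 * ssx, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.where(ok, sigma2 / np.where(ok, ssx, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = np.clip(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
        chunk = sub.copy()
        chunk["beta"], chunk["se"], chunk["t"], chunk["p"] = beta, se, t, p
        chunk["skip_reason"] = np.where(ok, "", "constant_genotype")
        out.append(chunk)
    if not out:
        return pairs.iloc[0:0].assign(beta=[], se=[], t=[], p=[],
                                      skip_reason=[])
    res = pd.concat(out, ignore_index=True)
    return res[res["skip_reason"] == ""].drop(columns="skip_reason")


# ---------------------------------------------------------------------------
# local (per-feature) correction

def eigenmt_local(p_nominal: np.ndarray, dosages: np.ndarray,
                  positions: np.ndarray, window: int = 200,
                  var_explained: float = 0.99) -> dict:
    """Effective number of tests from the cis genotype correlation spectrum.

    Variants are ordered by position and chunked into windows of <= 200;
    each window contributes the smallest k whose top-k eigenvalues of the
    correlation matrix reach ``var_explained`` of the trace.
    """
    order = np.argsort(positions)
    D = _impute_mean(dosages[order])
    m = len(D)
    m_eff = 0
    for s in range(0, m, window):
        block = D[s:s + window]
        sd = block.std(axis=1)
        keep = sd > 0
        nz = int((~keep).sum())
        block = block[keep]
        if len(block) == 0:
            m_eff += nz  # constant variants count as themselves
            continue
        C = np.corrcoef(block)
        C = np.atleast_2d(C)
        w = np.linalg.eigvalsh(C)[::-1]
        w = np.maximum(w, 0.0)
        cum = np.cumsum(w)
        k = int(np.searchsorted(cum, var_explained * cum[-1]) + 1)
        m_eff += min(k, len(block)) + nz
    m_eff = min(m_eff, m)
    p_min = float(np.min(p_nominal))
    return {"p_min_nominal": p_min, "m_eff": int(m_eff),
            "p_local": min(1.0, p_min * m_eff), "method": "eigenmt"}


def permutation_local(y: np.ndarray, dosages: np.ndarray,
                      n_perm: int = 1000, beta_approx: bool = True,
                      rng: np.random.Generator | None = None,
                      covariates: np.ndarray | None = None) -> dict:
    """Permutation-based feature-level p-value with Beta tail approximation.

    The phenotype is permuted across samples; the empirical p-value is
    (1 + #{perm min-p <= observed}) / (1 + n_perm).  With ``beta_approx`` a
    Beta(a, b) is fitted to the permutation minimum p-values by method of
    moments and its CDF at the observed minimum is reported instead.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: permutation tail unreliable", n_perm)
    rng = rng or np.random.default_rng()
    n = len(y)
    G, q = _residualize(_impute_mean(dosages), covariates)
    yr, _ = _residualize(y[None, :], covariates)
    yr = yr[0]
    df = n - 1 - q
    sd = np.sqrt((G ** 2).sum(axis=1))
    ok = sd > 1e-12
    G = G[ok] / sd[ok][:, None]

    def min_p(Y: np.ndarray) -> np.ndarray:
        """Minimum two-sided p over variants for each column of Y."""
        vv = (Y ** 2).sum(axis=0)
        vv = np.where(vv > 0, vv, np.inf)
        r = (G @ Y) / np.sqrt(vv)[None, :]
        rmax = np.clip(np.abs(r).max(axis=0), 0.0, 1 - 1e-15)
        tstat = rmax * np.sqrt(df / (1 - rmax ** 2))
        return 2 * stats.t.sf(tstat, df)

    obs = float(min_p(yr[:, None])[0])
    perms = np.empty(n_perm)
    block = 256
    for s in range(0, n_perm, block):
        b = min(block, n_perm - s)
        P = np.empty((n, b))
        for j in range(b):
            P[:, j] = yr[rng.permutation(n)]
        perms[s:s + b] = min_p(P)
    emp = (1.0 + np.sum(perms <= obs)) / (1.0 + n_perm)
    out = {"p_min_nominal": obs, "p_empirical": float(emp),
           "method": "permutation", "m_eff": len(G)}
    if beta_approx:
        m, v = float(perms.mean()), float(perms.var(ddof=1))
        if v <= 0:
            a = b_ = np.nan
            p_local = emp
        else:
            common = m * (1 - m) / v - 1
            a, b_ = max(m * common, 1e-6), max((1 - m) * common, 1e-6)
            p_local = float(stats.beta.cdf(obs, a, b_))
            p_local = max(p_local, np.finfo(float).tiny)
        out.update({"beta_a": a, "beta_b": b_, "p_local": p_local})
    else:
        out["p_local"] = float(emp)
    return out


def global_correct(corrections: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """BH across features on locally adjusted p-values + threshold back-calc.

    Adds ``p_global``, ``significant`` and ``nominal_threshold``: the global
    cutoff p* (largest p_local passing BH) mapped back to the nominal scale,
    p*/m_eff for the eigenMT method or the inverse Beta CDF at p* for the
    permutation method.
    """
    out = corrections.copy()
    if len(out) == 0:
        for col in ("p_global", "nominal_threshold"):
            out[col] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    rej, p_global, *_ = multipletests(out["p_local"], alpha=fdr,
                                      method="fdr_bh")
    out["p_global"] = p_global
    out["significant"] = rej
    if rej.any():
        p_star = float(out.loc[rej, "p_local"].max())
    else:
        p_star = np.nan
    thr = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples()):
        if not rej[i] or np.isnan(p_star):
            continue
        if row.method == "eigenmt":
            thr[i] = p_star / row.m_eff
        else:
            if np.isfinite(getattr(row, "beta_a", np.nan)):
                thr[i] = float(stats.beta.ppf(p_star, row.beta_a, row.beta_b))
            else:
                thr[i] = row.p_min_nominal
        # the feature's own minimum always passes its threshold
        thr[i] = max(thr[i], row.p_min_nominal)
    out["nominal_threshold"] = thr
    return out


# ---------------------------------------------------------------------------
# secondary signals

def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of mean-imputed dosages; NaN-variance
    pairs are treated as perfectly correlated (r² = 1)."""
    a, b = _impute_mean(a[None, :])[0], _impute_mean(b[None, :])[0]
    if a.std() == 0 or b.std() == 0:
        return 1.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def independent_signals(records: pd.DataFrame, gm: GenotypeMatrix,
                        sample_cols: list[int], mode: str = "prune",
                        r2_max: float = 0.2,
                        nominal_threshold: float | None = None,
                        phenotype: np.ndarray | None = None,
                        covariates: np.ndarray | None = None,
                        max_iter: int = 10) -> pd.DataFrame:
    """Index and secondary association signals for one feature.

    ``prune``: sort significant variants by (p asc, |beta| desc, position
    asc), take the head as index, drop everything with r² >= ``r2_max`` to
    any chosen index, repeat.  ``conditional``: re-scan with each chosen
    index dosage appended to the covariates; a secondary signal is called
    while the minimum conditional p stays at or below ``nominal_threshold``.
    """
    D = gm.dosage[:, sample_cols]
    pos = gm.variants["pos"]
    if mode == "prune":
        sub = records.copy()
        sub["_pos"] = [pos.iloc[r] for r in sub["variant_row"]]
        sub = sub.sort_values(["p", "beta", "_pos"], key=lambda s: (
            s if s.name != "beta" else -s.abs()))
        chosen: list[int] = []
        out = []
        remaining = sub
        rank = 0
        while len(remaining):
            head = remaining.iloc[0]
            chosen.append(int(head["variant_row"]))
            rec = head.drop(labels="_pos").to_dict()
            rec["tier"] = "independent_index"
            rec["signal_rank"] = rank
            out.append(rec)
            rank += 1
            keep = []
            for _, row in remaining.iloc[1:].iterrows():
                r2s = [ld_r2(D[int(row["variant_row"])], D[c])
                       for c in chosen]
                if max(r2s) < r2_max:
                    keep.append(row)
            remaining = pd.DataFrame(keep)
        return pd.DataFrame(out)
    if mode == "conditional":
        if phenotype is None or nominal_threshold is None:
            raise ValueError("conditional mode needs phenotype and threshold")
        head = records.sort_values("p").iloc[0]
        out = [dict(head, tier="independent_index", signal_rank=0)]
        chosen = [int(head["variant_row"])]
        rows = records["variant_row"].to_numpy()
        for it in range(1, max_iter):
            cond = _impute_mean(D[chosen]).T
            Z = cond if covariates is None else np.column_stack(
                [covariates, cond])
            G, q = _residualize(_impute_mean(D[rows]), Z)
            yr, _ = _residualize(phenotype[None, :], Z)
            yr = yr[0]
            df = len(phenotype) - 1 - q
            if df < 2:
                break
            ssx = (G ** 2).sum(axis=1)
            ok = ssx > 1e-12
            beta = np.where(ok, G @ yr / np.where(ok, ssx, 1.0), 0.0)
            rss = np.maximum(yr @ yr - beta ** 2 * ssx, 0.0)
            se = np.sqrt(rss / df / np.where(ok, ssx, 1.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(ok, beta / se, 0.0)
            p = np.clip(2 * stats.t.sf(np.abs(t), df),
                        np.finfo(float).tiny, 1.0)
            p[~ok] = 1.0
            p[[int(np.flatnonzero(rows == c)[0]) for c in chosen]] = 1.0
            best = int(np.argmin(p))
            if p[best] > nominal_threshold:
                break
            rec = records.iloc[best].to_dict()
            rec.update(beta=float(beta[best]), se=float(se[best]),
                       t=float(t[best]), p=float(p[best]),
                       tier="conditional_secondary", signal_rank=it)
            out.append(rec)
            chosen.append(int(rows[best]))
        return pd.DataFrame(out)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class QTLResult:
    """One condition x assay cis-QTL run."""

    condition: str
    assay: str
    scan: pd.DataFrame          # all tested pairs with beta/se/t/p
    corrections: pd.DataFrame   # per feature, incl. global BH + thresholds
    significant_pairs: pd.DataFrame  # variants below per-feature threshold
    signals: pd.DataFrame       # index + secondary signals per feature
    samples: list[str] = field(default_factory=list)

    @property
    def significant_features(self) -> set[str]:
        if len(self.corrections) == 0:
            return set()
        sig = self.corrections["significant"]
        return set(self.corrections.loc[sig, "feature"])


def map_qtls(norm: NormalizedMatrix, gm: GenotypeMatrix,
             features: pd.DataFrame, sheet: SampleSheet, condition: str,
             assay: str, window: int, local_method: str = "eigenmt",
             fdr: float = 0.1, n_perm: int = 1000,
             secondary_mode: str | None = None,
             covariates: np.ndarray | None = None,
             min_maf: float = 0.01, seed: int = 0) -> QTLResult:
    """Full per-condition scan -> local correction -> global BH -> signals.

    ``norm`` may contain samples from every condition; the condition subset
    is fixed first and all variant filters are computed on it.  The default
    local method follows the assay convention: eigenMT for accessibility,
    permutations for expression (pass explicitly to override).
    """
    cond_samples = [s for s in sheet.condition_samples(condition)
                    if s in set(norm.samples)]
    donor_of = sheet.donor_of()
    donors = [donor_of[s] for s in cond_samples]
    keep = [i for i, d in enumerate(donors) if d in set(gm.samples)]
    cond_samples = [cond_samples[i] for i in keep]
    donors = [donors[i] for i in keep]
    sub_norm = norm.subset_samples(cond_samples)
    sub_gm = gm.subset_samples(donors)
    # relabel genotype columns with the matched sample ids (one per donor)
    sub_gm = GenotypeMatrix(sub_gm.variants, cond_samples, sub_gm.dosage)

    vmask = variant_filter_mask(sub_gm, min_maf=min_maf)
    pairs = build_cis_pairs(features, sub_gm, window, vmask)
    scan = assoc_scan(sub_norm, sub_gm, pairs, covariates=covariates)

    rng = np.random.default_rng(np.random.SeedSequence([97, seed]))
    feat_row = {f: i for i, f in enumerate(sub_norm.features)}
    corr_rows = []
    for feature, subp in scan.groupby("feature", sort=False):
        rows = subp["variant_row"].to_numpy()
        dosages = sub_gm.dosage[rows]
        if local_method == "eigenmt":
            rec = eigenmt_local(subp["p"].to_numpy(), dosages,
                                sub_gm.variants["pos"].to_numpy()[rows])
        else:
            y = sub_norm.values[feat_row[feature]]
            rec = permutation_local(y, dosages, n_perm=n_perm, rng=rng,
                                    covariates=covariates)
        rec["feature"] = feature
        corr_rows.append(rec)
    corrections = pd.DataFrame(corr_rows)
    corrections = global_correct(corrections, fdr=fdr)

    sig_pairs = []
    signals = []
    if len(corrections):
        thr_of = dict(zip(corrections["feature"],
                          corrections["nominal_threshold"]))
        if secondary_mode is None:
            secondary_mode = "prune" if local_method == "eigenmt" \
                else "conditional"
        sample_cols = list(range(sub_gm.n_samples))
        for feature in corrections.loc[corrections["significant"], "feature"]:
            thr = thr_of[feature]
            subp = scan[scan["feature"] == feature]
            hits = subp[subp["p"] <= thr]
            sig_pairs.append(hits)
            if len(hits) == 0:
                continue
            kwargs = {}
            if secondary_mode == "conditional":
                kwargs = {"phenotype": sub_norm.values[feat_row[feature]],
                          "nominal_threshold": thr,
                          "covariates": covariates}
            sig = independent_signals(hits, sub_gm, sample_cols,
                                      mode=secondary_mode, **kwargs)
            signals.append(sig)
    sig_pairs = (pd.concat(sig_pairs, ignore_index=True) if sig_pairs
                 else scan.iloc[0:0])
    signals = (pd.concat(signals, ignore_index=True) if signals
               else pd.DataFrame(columns=list(scan.columns)
                                 + ["tier", "signal_rank"]))
    return QTLResult(condition=condition, assay=assay, scan=scan,
                     corrections=corrections, significant_pairs=sig_pairs,
                     signals=signals, samples=cond_samples)
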